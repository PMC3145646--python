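"""Community statistics: normalization, Bray-Curtis, clustering,
rarefaction, Shannon diversity and sequential PERMANOVA.

The variance decomposition follows the adonis approach: the squared
distance matrix is Gower-centered into an inner-product matrix G whose
trace is the total sum of squares; each design term, entered in order,
claims the trace of G under the orthogonal projector its columns add
beyond the preceding terms; significance comes from free permutation of
library labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from ._rng import rng_for
from .synthetic import ACTIVE_FRACTIONS


# ---------------------------------------------------------------------------
# normalization & distances
# ---------------------------------------------------------------------------

def normalize_percent(table: pd.DataFrame) -> pd.DataFrame:
    """Scale every library column to sum to 100 (a percentage table)."""
    sums = table.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero column sum for library {zero.index[0]!r}")
    return table / sums * 100.0


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    return float(np.abs(x - y).sum() / denom)


def distance_matrix(table: pd.DataFrame, metric: str = "braycurtis") -> pd.DataFrame:
    """Pairwise library dissimilarities over a (taxa x libraries) table."""
    labels = list(table.columns)
    d = squareform(pdist(table.T.to_numpy(dtype=float), metric=metric))
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# complete-linkage clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merges`` lists (left, right, height) where left/right are leaf labels
    for singletons or earlier merge indices offset by the leaf count.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        n = len(self.labels)

        def node(i: int, parent_h: float) -> str:
            if i < n:
                return f"{self.labels[i]}:{parent_h:.6g}"
            l, r, h = self.merges[i - n]
            return f"({node(l, h)},{node(r, h)}):{max(parent_h - h, 0.0):.6g}"

        l, r, h = self.merges[-1]
        return f"({node(l, h)},{node(r, h)});"


def cluster_complete(dist: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    At each step the pair of clusters with the smallest maximum pairwise
    distance merges; ties break on the lowest (i, j) index pair so the
    dendrogram is deterministic.
    """
    labels = list(dist.columns)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two libraries to cluster")
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12) or not np.allclose(np.diag(d), 0, atol=1e-12):
        raise ValueError("not a valid distance matrix")

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(members)
    merges: list[tuple[int, int, float]] = []
    next_id = n
    ids = {i: i for i in range(n)}  # cluster key -> dendrogram node id
    while len(active) > 1:
        best = None
        for a_pos, a in enumerate(active):
            for b in active[a_pos + 1:]:
                h = max(d[i, j] for i in members[a] for j in members[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        merges.append((ids[a], ids[b], float(h)))
        members[a] = members[a] + members[b]
        del members[b]
        ids[a] = next_id
        next_id += 1
        active = sorted(members)
    return Dendrogram(labels, merges)


# ---------------------------------------------------------------------------
# rarefaction & diversity
# ---------------------------------------------------------------------------

def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction(
    counts,
    depths: list[int],
    mode: str = "analytic",
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected taxon richness at each subsampling depth.

    Analytic mode evaluates the hypergeometric expectation
    E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)); resample mode averages
    observed richness over seeded subsamples without replacement.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    total = c.sum()
    rows = []
    rng = rng_for(seed, "rarefaction")
    expanded = None
    for n in depths:
        if n > total:
            raise ValueError(f"depth {n} exceeds total count {int(total)}")
        if n == 0:
            rows.append((n, 0.0))
            continue
        if mode == "analytic":
            keep = total - c >= n
            miss = np.zeros_like(c)
            miss[keep] = np.exp(_log_choose(total - c[keep], n) - _log_choose(np.array([total]), n))
            rows.append((n, float(np.sum(1.0 - miss))))
        elif mode == "resample":
            if expanded is None:
                expanded = np.repeat(np.arange(len(c)), c.astype(int))
            rich = [
                len(np.unique(rng.choice(expanded, size=n, replace=False)))
                for _ in range(n_reps)
            ]
            rows.append((n, float(np.mean(rich))))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows, columns=["depth", "expected_richness"])


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i (natural log) over nonzero taxa."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-library Shannon index and observed richness."""
    rows = [
        (lib, shannon(counts[lib]), int((counts[lib] > 0).sum()))
        for lib in counts.columns
    ]
    return pd.DataFrame(rows, columns=["library", "shannon", "richness"])


# ---------------------------------------------------------------------------
# sequential PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    """Sequential decomposition table mirroring the adonis layout."""

    table: pd.DataFrame  # rows: terms..., Residuals, Total
    n_perm: int
    seed: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")


def _dummy(values: list[str]) -> np.ndarray:
    levels = sorted(set(values))
    out = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        out[i, levels.index(v)] = 1.0
    return out


def build_terms(design: pd.DataFrame) -> dict[str, np.ndarray]:
    """Design-matrix columns for the standard three grouping factors.

    ``actives_vs_totals`` contrasts {PA, LC, HC} against {FS, R};
    ``samples`` and ``fractions`` are the subject and fraction factors.
    """
    active = ["active" if f in ACTIVE_FRACTIONS else "total" for f in design["fraction"]]
    return {
        "actives_vs_totals": _dummy(active),
        "samples": _dummy(list(design["sample"])),
        "fractions": _dummy(list(design["fraction"])),
    }


def _projector(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank, via SVD."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > 1e-9 * s.max()
    uk = u[:, keep]
    return uk @ uk.T, int(keep.sum())


def permanova(
    dist: pd.DataFrame,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> VarianceDecomposition:
    """Sequential permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    dist
        Symmetric dissimilarity matrix over libraries.
    design
        Frame with columns library_id, sample, fraction covering every
        library in ``dist``.
    terms
        Ordered term names among {actives_vs_totals, samples, fractions};
        defaults to that order. Order matters: sums of squares are
        sequential, each term claiming only variance beyond its
        predecessors (the fractions factor loses one df to the
        actives-vs-totals contrast).
    n_perm
        Permutations for the p-values; free permutation of library labels.

    Returns a table with Df, SumsOfSqs, MeanSqs, F.Model, R2 and Pr(>F)
    rows for each term plus Residuals and Total.
    """
    terms = list(terms or ["actives_vs_totals", "samples", "fractions"])
    design = design.set_index("library_id").loc[list(dist.columns)].reset_index()
    n = len(dist)
    if n != len(design):
        raise ValueError("design does not cover the distance matrix")

    D = dist.to_numpy(dtype=float)
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = float(np.trace(G))

    blocks = build_terms(design)
    for t in terms:
        if t not in blocks:
            raise ValueError(f"unknown term {t!r}")

    X = np.ones((n, 1))
    P_prev, rank_prev = _projector(X)
    projectors, dfs = [], []
    for t in terms:
        X = np.hstack([X, blocks[t]])
        P, rank = _projector(X)
        df = rank - rank_prev
        # a term fully aliased by its predecessors keeps df 0 and gets no test
        projectors.append(P - P_prev)
        dfs.append(df)
        P_prev, rank_prev = P, rank

    P_full = P_prev
    R = np.eye(n) - P_full
    df_res = n - rank_prev

    def ss_terms(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(H * Gm)) for H in projectors])
        return ss, float(np.sum(R * Gm))

    dfs_arr = np.array(dfs, dtype=float)
    testable = dfs_arr > 0
    ss, ss_res = ss_terms(G)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms = np.where(testable, ss / np.where(testable, dfs_arr, 1.0), np.nan)
    ms_res = ss_res / df_res
    f_obs = ms / ms_res

    rng = rng_for(seed, "permanova")
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        Gp = G[np.ix_(p, p)]
        ss_p, ss_res_p = ss_terms(Gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ss_p / np.where(testable, dfs_arr, 1.0)) / (ss_res_p / df_res)
        exceed += np.where(testable, f_p >= f_obs - 1e-12, 0)
    pvals = np.where(testable, (exceed + 1) / (n_perm + 1), np.nan)

    rows = []
    for t, df, s, m, f, p, in zip(terms, dfs, ss, ms, f_obs, pvals):
        rows.append((t, df, s, m, f, s / ss_total, p))
    rows.append(("Residuals", df_res, ss_res, ms_res, np.nan, ss_res / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, np.nan, 1.0, np.nan))
    table = pd.DataFrame(
        rows, columns=["SourceVar", "Df", "SumsOfSqs", "MeanSqs", "F.Model", "R2", "Pr(>F)"]
    ).set_index("SourceVar")
    return VarianceDecomposition(table, n_perm, seed)
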