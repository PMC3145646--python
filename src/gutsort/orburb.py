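"""Rank-abundance inflection-point cutoff and the ORB/URB split.

For each library the family percentages are sorted descending, the
log10-abundance curve is smoothed by local quadratic regression against
rank, and inflection points are read off the sign changes of the second
finite difference of the smoothed curve. The cutoff of a library is the
smoothed abundance at the *last* inflection point along the sorted curve
(under ascending sort, the high-abundance end of the head/tail elbow —
see :func:`library_cutoff` for the direction convention and its
alternative); the consensus across libraries is the most recurrent cutoff, found
by log-binning. Families above the consensus cutoff are over-represented
(ORB), the rest under-represented (URB). The active-vs-total contrast per
family is a Welch two-sample t-test on per-subject median percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ACTIVE_FRACTIONS, TOTAL_FRACTIONS


@dataclass
class OrderedDistribution:
    """Families of one library sorted by descending percentage."""

    library_id: str
    families: list[str]
    percentages: np.ndarray  # same order, non-increasing, sums to the input sum

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.families) + 1)


@dataclass
class InflectionDiagnostics:
    ranks: np.ndarray
    log10_pct: np.ndarray
    smoothed: np.ndarray  # smoothed log10 percentage at each rank
    second_derivative: np.ndarray  # nan at the two edge ranks
    inflection_ranks: list[int]


@dataclass
class CutoffResult:
    per_library: dict[str, float | None]
    consensus: float
    labels: pd.DataFrame  # family x library, "ORB"/"URB"/"" (absent)
    group_labels: pd.DataFrame  # family x {active, total} medians and labels
    diagnostics: dict[str, InflectionDiagnostics] = field(default_factory=dict)


def ordered_distribution(column: pd.Series, library_id: str = "") -> OrderedDistribution:
    """Sort a percent-normalized library column descending, ties alphabetical."""
    col = column[column > 0]
    if col.empty:
        raise ValueError(f"library {library_id or column.name!r} has no positive values")
    df = col.rename("pct").rename_axis("family").reset_index()
    df = df.sort_values(["pct", "family"], ascending=[False, True], kind="mergesort")
    return OrderedDistribution(
        library_id or str(column.name), list(df["family"]), df["pct"].to_numpy(dtype=float)
    )


def _loess_quadratic(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Local quadratic regression with tricube weights, evaluated at x.

    ``span`` is the fraction of points in each local window (at least the
    3 needed for a quadratic fit). Reproduces polynomials up to degree 2
    exactly, so a log-linear curve smooths to itself.
    """
    n = len(x)
    k = max(4, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        w = (1 - (d[idx] / (dmax if dmax > 0 else 1.0)) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        X = np.stack([np.ones(k), x[idx] - x[i], (x[idx] - x[i]) ** 2], axis=1)
        W = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        out[i] = beta[0]
    return out


def find_inflections(
    dist: OrderedDistribution,
    smoothing_span: float = 0.15,
    curvature_rel_tol: float = 0.05,
    curvature_abs_tol: float = 1e-4,
) -> InflectionDiagnostics:
    """Locate curvature sign changes on the smoothed rank-abundance curve.

    log10(percentage) is smoothed against rank by local quadratic
    regression at ``smoothing_span``; the second derivative is the central
    finite difference of the smoothed values at integer ranks. Curvature
    within a deadband (``curvature_rel_tol`` of the maximum magnitude,
    floored at ``curvature_abs_tol`` log10-units/rank^2) counts as zero, so
    a log-linear (single geometric) curve yields no inflections and float
    jitter creates no spurious sign changes. Inflection ranks are where
    the thresholded curvature sign changes.
    """
    if len(dist.families) < 5:
        raise ValueError(
            f"library {dist.library_id!r} has {len(dist.families)} families; "
            "need at least 5 to locate inflections"
        )
    x = dist.ranks.astype(float)
    y = np.log10(dist.percentages)
    sm = _loess_quadratic(x, y, smoothing_span)
    d2 = np.full_like(sm, np.nan)
    d2[1:-1] = sm[2:] - 2 * sm[1:-1] + sm[:-2]

    mags = np.abs(d2[1:-1])
    tol = max(curvature_abs_tol, curvature_rel_tol * (mags.max() if mags.size else 0.0))
    sign = np.zeros_like(sm)
    inner = slice(1, len(sm) - 1)
    sign[inner] = np.where(d2[inner] > tol, 1, np.where(d2[inner] < -tol, -1, 0))

    # an inflection is any rank where the thresholded curvature sign differs
    # from the previous rank's (0 counts as a state, so entering and leaving
    # a curvature dip both register); a flat curve registers nothing
    inflections: list[int] = []
    prev = sign[1]
    for i in range(2, len(sm) - 1):
        if sign[i] != prev:
            inflections.append(int(x[i]))
        prev = sign[i]
    return InflectionDiagnostics(dist.ranks, y, sm, d2, inflections)


def library_cutoff(
    dist: OrderedDistribution,
    diag: InflectionDiagnostics,
    endpoint: str = "high",
) -> float | None:
    """Cutoff percentage at the last inflection point, or None.

    The abundance list is sorted before the inflection search and "last"
    refers to the end of the sorted curve. With the conventional ascending
    sort the last inflection sits at the *high*-abundance end — the head
    side of the head/tail elbow — and that is the default; it is also the
    reading under which the recovered cutoff tracks a planted knee.
    ``endpoint="low"`` takes the opposite end (the greatest rank of the
    descending curve) instead. The cutoff is the smoothed percentage at
    the chosen inflection rank.
    """
    if not diag.inflection_ranks:
        return None
    if endpoint not in ("high", "low"):
        raise ValueError(f"endpoint must be 'high' or 'low', got {endpoint!r}")
    r = min(diag.inflection_ranks) if endpoint == "high" else max(diag.inflection_ranks)
    return float(10 ** diag.smoothed[r - 1])


def consensus_cutoff(cutoffs: dict[str, float | None], bin_width: float = 0.25) -> float:
    """Most recurrent per-library cutoff, binned in log10 space.

    Histogram bins of ``bin_width`` log10-units are anchored half a bin
    below the smallest cutoff; the consensus is the geometric mean of the
    cutoffs falling in the modal bin (ties going to the lower bin), which
    returns a single or all-equal cutoff unchanged and is insensitive to
    where the bin edges happen to fall within the bin.
    """
    vals = np.array([c for c in cutoffs.values() if c is not None and c > 0])
    if vals.size == 0:
        raise ValueError(
            "no library produced an inflection cutoff; supply a manual cutoff"
        )
    logs = np.log10(vals)
    lo, hi = logs.min() - bin_width / 2, logs.max()
    nbins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(nbins + 1)
    edges[-1] = max(edges[-1], hi + 1e-12)
    hist, _ = np.histogram(logs, bins=edges)
    mode = int(np.argmax(hist))  # argmax takes the first (lower) modal bin
    members = logs[(logs >= edges[mode]) & (logs < edges[mode + 1])]
    return float(10 ** members.mean())


def classify(
    percent: pd.DataFrame, design: pd.DataFrame, cutoff: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ORB/URB labels per library and per group at a cutoff percentage.

    A family is ORB in a library when its percentage exceeds the cutoff,
    URB when positive but at or below it (the boundary itself is URB), and
    unlabeled when absent. Group labels use the family's median percentage
    across the active ({PA, LC, HC}) and total ({FS, R}) libraries.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    labels = pd.DataFrame("", index=percent.index, columns=percent.columns)
    labels[percent > cutoff] = "ORB"
    labels[(percent > 0) & (percent <= cutoff)] = "URB"

    frac_of = design.set_index("library_id")["fraction"]
    groups = {
        "active": [c for c in percent.columns if frac_of[c] in ACTIVE_FRACTIONS],
        "total": [c for c in percent.columns if frac_of[c] in TOTAL_FRACTIONS],
    }
    rows = []
    for fam in percent.index:
        row = {"family": fam}
        for g, cols in groups.items():
            med = float(percent.loc[fam, cols].median()) if cols else np.nan
            row[f"{g}_median_pct"] = med
            row[f"{g}_label"] = "" if med == 0 else ("ORB" if med > cutoff else "URB")
        rows.append(row)
    return labels, pd.DataFrame(rows).set_index("family")


def classification_summary(group_labels: pd.DataFrame) -> pd.DataFrame:
    """Counts of ORB/URB/present families per group."""
    rows = []
    for g in ("active", "total"):
        lab = group_labels[f"{g}_label"]
        rows.append({
            "group": g,
            "present": int((lab != "").sum()),
            "orb": int((lab == "ORB").sum()),
            "urb": int((lab == "URB").sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class WelchResult:
    table: pd.DataFrame  # per family: medians, t, df, p, significant
    alpha: float


def welch_family_test(
    percent: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    include_zeros: bool = False,
    bh_correct: bool = False,
) -> WelchResult:
    """Per-family Welch t-test of active vs total per-subject medians.

    For each family and subject, the active value is the median percentage
    across that subject's PA/LC/HC libraries and the total value the
    median across FS/R — one value per subject per group (n = number of
    subjects). Welch's statistic t = (xa - xt) / sqrt(sa^2/na + st^2/nt)
    with Welch-Satterthwaite df; two-sided p. Subjects where the family is
    absent from a group are dropped from that group unless
    ``include_zeros``. Zero variance in both groups yields t = 0, p = 1
    for equal means, and a flagged degenerate row for unequal means.
    Raw p-values by default; Benjamini-Hochberg behind ``bh_correct``.
    """
    frac_of = design.set_index("library_id")["fraction"]
    samp_of = design.set_index("library_id")["sample"]
    samples = sorted(design["sample"].unique())
    rows = []
    for fam in percent.index:
        vals = {"active": [], "total": []}
        for s in samples:
            for g, members in (("active", ACTIVE_FRACTIONS), ("total", TOTAL_FRACTIONS)):
                cols = [c for c in percent.columns
                        if samp_of[c] == s and frac_of[c] in members]
                if not cols:
                    continue
                m = float(percent.loc[fam, cols].median())
                if m > 0 or include_zeros:
                    vals[g].append(m)
        a, t = np.array(vals["active"]), np.array(vals["total"])
        row = {
            "family": fam,
            "n_active": len(a), "n_total": len(t),
            "active_median": float(np.median(a)) if len(a) else np.nan,
            "total_median": float(np.median(t)) if len(t) else np.nan,
            "max_pct": float(percent.loc[fam].max()),
        }
        # variances at float-noise level count as zero, else the t statistic
        # explodes on effectively-constant groups
        def _zero_var(v: np.ndarray) -> bool:
            return v.var(ddof=1) <= (1e-9 * max(np.abs(v).max(), 1e-300)) ** 2

        if len(a) < 2 or len(t) < 2:
            row.update(t_stat=np.nan, df=np.nan, p=np.nan, degenerate=False)
        elif _zero_var(a) and _zero_var(t):
            if a.mean() == t.mean():
                row.update(t_stat=0.0, df=np.nan, p=1.0, degenerate=False)
            else:
                row.update(t_stat=np.nan, df=np.nan, p=np.nan, degenerate=True)
        else:
            with warnings.catch_warnings():
                # near-identical groups trip scipy's precision-loss warning;
                # the degenerate cases are handled explicitly above
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(a, t, equal_var=False)
            row.update(t_stat=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue), degenerate=False)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("family")
    pcol = table["p"].copy()
    if bh_correct:
        mask = pcol.notna()
        pcol.loc[mask] = stats.false_discovery_control(pcol[mask].to_numpy())
        table["p_adjusted"] = pcol
    table["significant"] = pcol <= alpha
    return WelchResult(table, alpha)


def run_orb_urb(
    percent: pd.DataFrame,
    design: pd.DataFrame,
    smoothing_span: float = 0.15,
    bin_width: float = 0.25,
    alpha: float = 0.05,
    endpoint: str = "high",
) -> tuple[CutoffResult, WelchResult]:
    """Full ORB/URB analysis over a percent table: per-library inflection
    cutoffs, consensus, classification and the Welch comparison."""
    cutoffs: dict[str, float | None] = {}
    diagnostics: dict[str, InflectionDiagnostics] = {}
    for lib in percent.columns:
        dist = ordered_distribution(percent[lib], lib)
        diag = find_inflections(dist, smoothing_span)
        diagnostics[lib] = diag
        cutoffs[lib] = library_cutoff(dist, diag, endpoint)
    consensus = consensus_cutoff(cutoffs, bin_width)
    labels, group_labels = classify(percent, design, consensus)
    welch = welch_family_test(percent, design, alpha=alpha)
    return CutoffResult(cutoffs, consensus, labels, group_labels, diagnostics), welch
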