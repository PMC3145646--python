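"""LCA taxonomic assignment from tabular similarity hits.

Each read's retained hits (bitscore within a window of its best hit, above
a minimum identity) vote through their lineages; the read is assigned to
the lowest common ancestor. Reads whose LCA is shallower than the family
rank are counted as "unclassified" in family tables; reads with no
retained hits are unassigned and excluded from tables but reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import HIT_COLUMNS
from .taxonomy import RANK_DEPTH, TaxonomyTree

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Assignment:
    read_id: str
    assigned_node: int
    assigned_rank: str
    best_hit_identity: float


@dataclass
class LcaParams:
    """Hit-retention defaults follow the common LCA-binning convention."""

    min_identity: float = 80.0
    score_window: float = 0.9


def load_hits(path: str | Path) -> pd.DataFrame:
    """Read a headerless 12-column hit table (outfmt-6 column order)."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    if (df["pident"].lt(0) | df["pident"].gt(100)).any():
        raise ValueError("percent identity outside [0, 100]")
    if df["bitscore"].lt(0).any():
        raise ValueError("negative bitscore")
    return df


def retain_hits(hits: pd.DataFrame, params: LcaParams) -> pd.DataFrame:
    """Keep hits with bitscore >= window * best bitscore, above min identity.

    The best hit is always retained (ties at the maximum all fall inside
    any window). Returns an empty frame when everything fails the identity
    floor — the read then becomes unassigned.
    """
    ok = hits[hits["pident"] >= params.min_identity]
    if ok.empty:
        return ok
    best = ok["bitscore"].max()
    return ok[ok["bitscore"] >= params.score_window * best]


def assign_read(
    read_id: str,
    hits: pd.DataFrame,
    tree: TaxonomyTree,
    params: LcaParams,
    subject_to_node=int,
) -> Assignment | None:
    """Assign one read to the LCA of its retained hits' subjects."""
    kept = retain_hits(hits, params)
    if kept.empty:
        return None
    nodes = [subject_to_node(s) for s in kept["sseqid"]]
    node = tree.lca(nodes)
    return Assignment(read_id, node, tree.rank_of(node), float(kept["pident"].max()))


def assign_all(
    hits: pd.DataFrame,
    tree: TaxonomyTree,
    params: LcaParams | None = None,
    subject_to_node=int,
) -> tuple[list[Assignment], list[str]]:
    """Assign every read present in the hit table.

    Returns (assignments, unassigned read ids). Reads absent from the hit
    table are unknown here; account for them upstream.
    """
    params = params or LcaParams()
    assignments, unassigned = [], []
    for rid, grp in hits.groupby("qseqid", sort=True):
        a = assign_read(str(rid), grp, tree, params, subject_to_node)
        if a is None:
            unassigned.append(str(rid))
        else:
            assignments.append(a)
    return assignments, unassigned


def rank_counts(
    assignments: list[Assignment],
    library_of: dict[str, str],
    tree: TaxonomyTree,
    rank: str,
) -> pd.DataFrame:
    """Count-table of taxa (plus ``unclassified``) x library at one rank.

    A read whose assignment is deeper than or at ``rank`` counts for its
    ancestor at that rank; a read whose LCA is shallower counts as
    unclassified at that rank. Column sums equal assigned read counts per
    library.
    """
    if rank not in RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    counts: dict[str, dict[str, int]] = {}
    for a in assignments:
        lib = library_of[a.read_id]
        anc = tree.ancestor_at_rank(a.assigned_node, rank)
        taxon = tree.name_of(anc) if anc is not None else UNCLASSIFIED
        counts.setdefault(taxon, {})
        counts[taxon][lib] = counts[taxon].get(lib, 0) + 1
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    table = table.sort_index().sort_index(axis=1)
    # keep unclassified last for readability
    if UNCLASSIFIED in table.index:
        order = [i for i in table.index if i != UNCLASSIFIED] + [UNCLASSIFIED]
        table = table.loc[order]
    return table


def identity_fingerprint(
    assignments: list[Assignment],
    library_of: dict[str, str],
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Per-library density of best-hit identity — the similarity fingerprint.

    Bins cover [0, 100] at ``bin_width``; each library's densities sum to
    one. Returned long-form: (library, bin_left, density).
    """
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    rows = []
    by_lib: dict[str, list[float]] = {}
    for a in assignments:
        by_lib.setdefault(library_of[a.read_id], []).append(a.best_hit_identity)
    for lib in sorted(by_lib):
        vals = np.clip(by_lib[lib], 0, 100 - 1e-9)
        hist, _ = np.histogram(vals, bins=edges)
        dens = hist / hist.sum()
        for left, d in zip(edges[:-1], dens):
            rows.append((lib, float(left), float(d)))
    return pd.DataFrame(rows, columns=["library", "bin_left", "density"])


def assignments_frame(assignments: list[Assignment], tree: TaxonomyTree) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "node_id": a.assigned_node,
                "node_name": tree.name_of(a.assigned_node),
                "rank": a.assigned_rank,
                "best_identity": a.best_hit_identity,
            }
            for a in assignments
        ]
    )
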