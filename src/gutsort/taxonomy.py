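"""Rooted, rank-labelled taxonomy with lineage and LCA queries.

The tree is stored as a flat ``id -> TaxNode(parent, rank, name)`` map, the
shape of an NCBI-style nodes/names dump. Ranks are the fixed ordered list
root < domain < phylum < class < order < family < genus < species.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

RANKS = ["root", "domain", "phylum", "class", "order", "family", "genus", "species"]
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxNode:
    parent: int
    rank: str
    name: str


class TaxonomyTree:
    """A rooted taxonomy supporting lineage lookup and LCA.

    Parameters
    ----------
    nodes
        Map of node id to :class:`TaxNode`. The root is the unique node
        whose parent is itself (or absent from the map).
    """

    def __init__(self, nodes: dict[int, TaxNode]):
        self.nodes = dict(nodes)
        roots = [i for i, n in self.nodes.items() if n.parent == i or n.parent not in self.nodes]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._validate_acyclic()

    def _validate_acyclic(self) -> None:
        for start in self.nodes:
            seen = set()
            i = start
            while i != self.root:
                if i in seen:
                    raise ValueError(f"cycle detected through node {start}")
                seen.add(i)
                i = self.nodes[i].parent

    # -- queries ---------------------------------------------------------

    def lineage(self, node_id: int) -> list[int]:
        """Root-to-node path of ids."""
        path = []
        i = node_id
        while True:
            path.append(i)
            if i == self.root:
                break
            i = self.nodes[i].parent
        return path[::-1]

    def rank_of(self, node_id: int) -> str:
        return self.nodes[node_id].rank

    def name_of(self, node_id: int) -> str:
        return self.nodes[node_id].name

    def depth(self, node_id: int) -> int:
        return len(self.lineage(node_id)) - 1

    def ancestor_at_rank(self, node_id: int, rank: str) -> int | None:
        """The node's ancestor (or itself) with the given rank, if any."""
        for i in self.lineage(node_id):
            if self.nodes[i].rank == rank:
                return i
        return None

    def children(self, node_id: int) -> list[int]:
        return [i for i, n in self.nodes.items() if n.parent == node_id and i != node_id]

    def nodes_at_rank(self, rank: str) -> list[int]:
        return [i for i, n in self.nodes.items() if n.rank == rank]

    def lca(self, node_ids: Iterable[int]) -> int:
        """Lowest common ancestor of a set of nodes."""
        return lca([self.lineage(i) for i in node_ids])

    # -- I/O (NCBI-dump-like two-file TSV) -------------------------------

    def to_tsv(self, nodes_path: str | Path, names_path: str | Path) -> None:
        rows = [(i, n.parent, n.rank) for i, n in sorted(self.nodes.items())]
        pd.DataFrame(rows, columns=["id", "parent_id", "rank"]).to_csv(
            nodes_path, sep="\t", index=False
        )
        names = [(i, n.name) for i, n in sorted(self.nodes.items())]
        pd.DataFrame(names, columns=["id", "name"]).to_csv(names_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, nodes_path: str | Path, names_path: str | Path) -> "TaxonomyTree":
        nodes_df = pd.read_csv(nodes_path, sep="\t")
        names_df = pd.read_csv(names_path, sep="\t").set_index("id")["name"]
        nodes = {
            int(r.id): TaxNode(int(r.parent_id), str(r.rank), str(names_df.get(int(r.id), "")))
            for r in nodes_df.itertuples()
        }
        return cls(nodes)

    @classmethod
    def from_lineages(cls, lineage_strings: dict[str, str]) -> "TaxonomyTree":
        """Build a tree from ``leaf_name -> 'domain;phylum;...;species'`` strings.

        Rank labels are assigned positionally starting at ``domain``.
        """
        nodes: dict[int, TaxNode] = {0: TaxNode(0, "root", "root")}
        index: dict[tuple, int] = {(): 0}
        next_id = 1
        for _leaf, lin in lineage_strings.items():
            parts = tuple(p.strip() for p in lin.split(";") if p.strip())
            for k in range(1, len(parts) + 1):
                key = parts[:k]
                if key not in index:
                    rank = RANKS[min(k, len(RANKS) - 1)]
                    index[key] = next_id
                    nodes[next_id] = TaxNode(index[key[:-1]], rank, key[-1])
                    next_id += 1
        return cls(nodes)


def lca(lineages: list[list[int]]) -> int:
    """Deepest node present in every root-to-node lineage.

    All lineages must come from the same tree (they share the root). The
    result is found by walking the aligned prefixes until they diverge.
    """
    if not lineages:
        raise ValueError("lca of an empty lineage list is undefined")
    shortest = min(len(p) for p in lineages)
    result = lineages[0][0]
    for d in range(shortest):
        col = {p[d] for p in lineages}
        if len(col) != 1:
            break
        result = lineages[0][d]
    return result
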