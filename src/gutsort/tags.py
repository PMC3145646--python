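"""Tag scheme for MID-PERMUTAG-linker-primer amplicon reads.

Reads carry, 5' to 3': a multiplex identifier (MID) naming the library, an
8-base degenerate PERMUTAG (default pattern ``WGNGNNGW``, 256 concrete
expansions) that distinguishes emulsion-PCR duplicates from genuinely
identical templates, a two-base linker (``TC``) and the forward PCR primer,
followed by the 16S insert.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from ._rng import rng_for

#: IUPAC nucleotide codes mapped to the bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# 27F / 530R universal 16S primers (530R = reverse complement of 530F).
DEFAULT_FORWARD_PRIMER = "AGAGTTTGATCMTGGCTCAG"
DEFAULT_REVERSE_PRIMER = "CCGCGGCKGCTGGCAC"
DEFAULT_PERMUTAG = "WGNGNNGW"
DEFAULT_LINKER = "TC"


def expand_degenerate(pattern: str) -> set[str]:
    """Enumerate every concrete DNA sequence matching an IUPAC pattern.

    The cardinality is the product of the per-position degeneracies; the
    default PERMUTAG ``WGNGNNGW`` expands to 2*1*4*1*4*4*1*2 = 256 tags.

    Raises
    ------
    ValueError
        If the pattern is empty or contains a non-IUPAC character (the
        offending position is reported).
    """
    if not pattern:
        raise ValueError("empty degenerate pattern")
    choices = []
    for i, ch in enumerate(pattern.upper()):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} at position {i}")
        choices.append(IUPAC[ch])
    return {"".join(bases) for bases in itertools.product(*choices)}


def matches_pattern(seq: str, pattern: str) -> bool:
    """Positionwise IUPAC match of a concrete sequence against a pattern."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC.get(p.upper(), "") for b, p in zip(seq.upper(), pattern))


def default_mids(n: int, length: int = 8, seed: int = 2011) -> dict[str, str]:
    """Generate ``n`` distinct MID barcodes of the given length.

    Codes are drawn deterministically and kept at pairwise Hamming distance
    >= 3 so a single substitution cannot turn one MID into another.
    """
    if n <= 0:
        raise ValueError("need at least one MID")
    rng = rng_for(seed, "mids")
    bases = "ACGT"
    mids: list[str] = []
    while len(mids) < n:
        cand = "".join(rng.choice(list(bases), size=length))
        if all(sum(a != b for a, b in zip(cand, m)) >= 3 for m in mids):
            mids.append(cand)
    return {f"MID{i+1:02d}": m for i, m in enumerate(mids)}


@dataclass
class TagScheme:
    """The tag layout that defines read structure.

    Attributes
    ----------
    mids
        Map of MID id -> barcode sequence; one MID per library.
    permutag_pattern
        IUPAC pattern of the degenerate tag between MID and linker.
    linker
        Constant spacer between PERMUTAG and primer.
    forward_primer, reverse_primer
        PCR primer sequences (IUPAC allowed in the primer).
    """

    mids: dict[str, str]
    permutag_pattern: str = DEFAULT_PERMUTAG
    linker: str = DEFAULT_LINKER
    forward_primer: str = DEFAULT_FORWARD_PRIMER
    reverse_primer: str = DEFAULT_REVERSE_PRIMER
    _tags: frozenset = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        for ch in self.permutag_pattern:
            if ch.upper() not in IUPAC:
                raise ValueError(f"permutag pattern contains non-IUPAC code {ch!r}")
        if not self.mids:
            raise ValueError("tag scheme has no MIDs")

    @property
    def permutags(self) -> frozenset:
        """All concrete PERMUTAG expansions (cached)."""
        if self._tags is None:
            object.__setattr__(self, "_tags", frozenset(expand_degenerate(self.permutag_pattern)))
        return self._tags

    @property
    def tag_block_length(self) -> int:
        """MID + PERMUTAG + linker + forward primer length (MIDs equal-length)."""
        mid_len = len(next(iter(self.mids.values())))
        return mid_len + len(self.permutag_pattern) + len(self.linker) + len(self.forward_primer)
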