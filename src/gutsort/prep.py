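"""Tag-aware read preparation: parse, demultiplex, dereplicate, strip.

A read is accepted only if, walking from base 0: an exact MID from the
scheme, an 8-mer matching the PERMUTAG pattern positionwise, the exact
linker, and the forward primer with at most two substitutions. Failures
are categorized, never silently dropped. Dereplication collapses reads
identical in both length and full tagged sequence — the PERMUTAG is part
of the sequence, so emulsion-PCR duplicates collapse while identical
inserts from different template molecules (different PERMUTAGs) survive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .tags import IUPAC, TagScheme, matches_pattern

FAIL_STAGES = ("no_mid", "bad_permutag", "bad_linker", "bad_primer")


@dataclass(frozen=True)
class ParsedRead:
    read_id: str
    mid_id: str
    permutag: str
    insert: str
    full_tagged_sequence: str


@dataclass(frozen=True)
class UnassignedRead:
    read_id: str
    stage: str  # one of FAIL_STAGES


@dataclass
class DereplicationResult:
    unique: list[ParsedRead]
    multiplicity: dict[str, int]  # read_id of representative -> copies seen
    removed_count: int


def _primer_mismatches(seq: str, primer: str) -> int:
    """Hamming distance treating IUPAC degeneracy in the primer as wildcards."""
    return sum(b not in IUPAC.get(p.upper(), "") for b, p in zip(seq.upper(), primer))


def parse_read(
    read_id: str,
    sequence: str,
    scheme: TagScheme,
    max_primer_mismatches: int = 2,
    try_reverse_complement: bool = False,
) -> ParsedRead | UnassignedRead:
    """Parse one read against the MID-PERMUTAG-linker-primer layout.

    MID and linker must match exactly; the PERMUTAG must satisfy the
    degenerate pattern positionwise; the primer tolerates up to
    ``max_primer_mismatches`` substitutions (no indels). With
    ``try_reverse_complement`` the reverse complement is tried before
    declaring ``no_mid``.
    """
    seq = sequence.upper()
    mid_id = next((m for m, code in scheme.mids.items() if seq.startswith(code.upper())), None)
    if mid_id is None:
        if try_reverse_complement:
            rc = str(Seq(seq).reverse_complement())
            if any(rc.startswith(code.upper()) for code in scheme.mids.values()):
                return parse_read(read_id, rc, scheme, max_primer_mismatches, False)
        return UnassignedRead(read_id, "no_mid")
    pos = len(scheme.mids[mid_id])
    tag_len = len(scheme.permutag_pattern)
    tag = seq[pos:pos + tag_len]
    if len(tag) < tag_len or not matches_pattern(tag, scheme.permutag_pattern):
        return UnassignedRead(read_id, "bad_permutag")
    pos += tag_len
    if seq[pos:pos + len(scheme.linker)] != scheme.linker.upper():
        return UnassignedRead(read_id, "bad_linker")
    pos += len(scheme.linker)
    primer_obs = seq[pos:pos + len(scheme.forward_primer)]
    if (len(primer_obs) < len(scheme.forward_primer)
            or _primer_mismatches(primer_obs, scheme.forward_primer) > max_primer_mismatches):
        return UnassignedRead(read_id, "bad_primer")
    pos += len(scheme.forward_primer)
    return ParsedRead(read_id, mid_id, tag, seq[pos:], seq)


def parse_reads(
    reads: list[tuple[str, str]], scheme: TagScheme, **kwargs
) -> tuple[list[ParsedRead], list[UnassignedRead]]:
    """Parse a batch, preserving file order; assigned + unassigned = input."""
    parsed, failed = [], []
    for rid, seq in reads:
        out = parse_read(rid, seq, scheme, **kwargs)
        (parsed if isinstance(out, ParsedRead) else failed).append(out)
    return parsed, failed


def dereplicate(parsed: list[ParsedRead]) -> DereplicationResult:
    """Collapse reads with identical (length, full tagged sequence).

    The first occurrence in input order is kept as representative. The
    PERMUTAG is part of the compared sequence, so only true byte-identical
    duplicates collapse. Idempotent.
    """
    seen: dict[tuple[int, str], str] = {}
    unique: list[ParsedRead] = []
    mult: Counter = Counter()
    for r in parsed:
        key = (len(r.full_tagged_sequence), r.full_tagged_sequence)
        if key in seen:
            mult[seen[key]] += 1
        else:
            seen[key] = r.read_id
            unique.append(r)
            mult[r.read_id] = 1
    return DereplicationResult(unique, dict(mult), len(parsed) - len(unique))


def strip_tags(
    derep: DereplicationResult, mid_to_library: dict[str, str]
) -> pd.DataFrame:
    """Remove MID/PERMUTAG/linker/primer, keep the insert with its library.

    Returns a frame (read_id, library_id, insert) in retained order.
    """
    rows = [
        (r.read_id, mid_to_library[r.mid_id], r.insert)
        for r in derep.unique
    ]
    return pd.DataFrame(rows, columns=["read_id", "library_id", "insert"])


def demux_report(
    parsed: list[ParsedRead],
    failed: list[UnassignedRead],
    derep: DereplicationResult,
    mid_to_library: dict[str, str],
) -> pd.DataFrame:
    """Per-library accounting: assigned, failure categories, duplicates removed."""
    retained_ids = {r.read_id for r in derep.unique}
    assigned = Counter(mid_to_library[r.mid_id] for r in parsed)
    removed = Counter(
        mid_to_library[r.mid_id] for r in parsed if r.read_id not in retained_ids
    )
    fails = Counter(u.stage for u in failed)
    rows = []
    for lib in sorted(assigned):
        rows.append({
            "library_id": lib,
            "assigned": assigned[lib],
            "removed_duplicates": removed.get(lib, 0),
        })
    report = pd.DataFrame(rows, columns=["library_id", "assigned", "removed_duplicates"])
    for stage in FAIL_STAGES:
        report[stage] = 0
    # unassigned reads carry no library; a catch-all row keeps file-level
    # conservation (assigned + unassigned = input) checkable from the report
    total = {"library_id": "__unassigned__", "assigned": 0, "removed_duplicates": 0}
    for stage in FAIL_STAGES:
        total[stage] = fails.get(stage, 0)
    report = pd.concat([report, pd.DataFrame([total])], ignore_index=True)
    return report


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Load FASTA or FASTQ (sniffed from the first byte) as (id, seq) pairs."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_clean_fasta(clean: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write per-library FASTA files of clean inserts; returns library -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lib, grp in clean.groupby("library_id", sort=True):
        p = out_dir / f"{lib}.clean.fasta"
        with open(p, "w") as fh:
            for row in grp.itertuples():
                fh.write(f">{row.read_id}\n{row.insert}\n")
        paths[lib] = p
    return paths
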