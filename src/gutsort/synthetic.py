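"""Synthetic community, read and hit-table generator with known ground truth.

Emulates the study design this pipeline targets: four subjects, each
profiled in five flow-sorted fractions — PA, LC, HC (the *active*,
RNA-rich cells) and FS, R (the *total*, unsorted community) — by tagged 16S
amplicon sequencing. The generator plants:

* a heavy-tailed family abundance profile with a small over-represented
  head (ORB) and a long, even under-represented tail (URB), separated by a
  knee at a known percentage;
* multiplicative active-vs-total fold changes on chosen families (e.g. one
  family several-fold enriched in the total fractions, a few enriched in
  the actives);
* emulsion-PCR duplicate reads — byte-identical copies sharing MID,
  PERMUTAG and insert — at a controlled rate;
* per-read best-hit identity structure for the similarity "fingerprint".

Everything is deterministic for a fixed seed; every quantity the pipeline
estimates has its true value recorded so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._rng import rng_for
from .tags import TagScheme, default_mids
from .taxonomy import TaxNode, TaxonomyTree

ACTIVE_FRACTIONS = ("PA", "LC", "HC")
TOTAL_FRACTIONS = ("FS", "R")
FRACTIONS = ACTIVE_FRACTIONS + TOTAL_FRACTIONS

#: Nominal per-library sequencing depth the tail truncation refers to.
NOMINAL_DEPTH = 2000


def library_id(sample: str, fraction: str) -> str:
    return f"{sample}_{fraction}"


def default_design(n_samples: int = 4) -> list[tuple[str, str]]:
    """The study layout: ``n_samples`` subjects x five sorted fractions."""
    return [(f"S{i+1}", f) for i in range(n_samples) for f in FRACTIONS]


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def gen_taxonomy(n_phyla: int, n_families: int, seed: int) -> TaxonomyTree:
    """Generate a rooted eight-rank taxonomy with the requested widths.

    The realistic scale for a human gut community is ~79 families across
    ~13 phyla. Families are spread over phyla (each phylum gets at least
    one), each family carries one or two genera and each genus one to three
    species leaves. Deterministic for a fixed seed.
    """
    if n_phyla < 1 or n_families < n_phyla:
        raise ValueError("need n_families >= n_phyla >= 1")
    rng = rng_for(seed, "taxonomy")
    nodes: dict[int, TaxNode] = {0: TaxNode(0, "root", "root"), 1: TaxNode(0, "domain", "Bacteria")}
    nid = 2

    fam_per_phylum = rng.multinomial(n_families - n_phyla, np.full(n_phyla, 1 / n_phyla)) + 1
    fam_idx = 0
    for p in range(n_phyla):
        phy = nid
        nodes[nid] = TaxNode(1, "phylum", f"Phylum_{p+1:02d}")
        nid += 1
        cls = nid
        nodes[nid] = TaxNode(phy, "class", f"Class_{p+1:02d}")
        nid += 1
        order = nid
        nodes[nid] = TaxNode(cls, "order", f"Order_{p+1:02d}")
        nid += 1
        for _ in range(fam_per_phylum[p]):
            fam_idx += 1
            fam = nid
            nodes[nid] = TaxNode(order, "family", f"Family_{fam_idx:03d}")
            nid += 1
            for g in range(int(rng.integers(1, 3))):
                gen = nid
                nodes[nid] = TaxNode(fam, "genus", f"Genus_{fam_idx:03d}_{g+1}")
                nid += 1
                for s in range(int(rng.integers(1, 4))):
                    nodes[nid] = TaxNode(gen, "species", f"Species_{fam_idx:03d}_{g+1}_{s+1}")
                    nid += 1
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# community truth
# ---------------------------------------------------------------------------

@dataclass
class CommunityTruth:
    """Ground truth for a simulated community.

    Attributes
    ----------
    tree
        The taxonomy the families live in.
    families
        Family names ordered by descending base abundance.
    base_abundance
        DataFrame (family x library_id) of relative abundances; every
        column sums to 1. Fold effects and per-library jitter included.
    orb_flag
        Per-family boolean: True when the family sits above the planted
        knee in the base profile.
    effect_map
        Family -> total:active fold change (values > 1 enrich the total
        fractions, < 1 the active ones).
    knee_pct
        The planted head/tail boundary, in percent.
    design
        (sample, fraction) pairs, one per library.
    """

    tree: TaxonomyTree
    families: list[str]
    base_abundance: pd.DataFrame
    orb_flag: pd.Series
    effect_map: dict[str, float]
    knee_pct: float
    design: list[tuple[str, str]]

    @property
    def libraries(self) -> list[str]:
        return [library_id(s, f) for s, f in self.design]

    def percentages(self) -> pd.DataFrame:
        return self.base_abundance * 100.0


def _head_values(n_orb: int, head_sum: float, h_min: float) -> np.ndarray:
    """Geometric head: n values summing to head_sum with minimum h_min."""
    if n_orb == 1:
        return np.array([head_sum])
    # solve h_min * (r^n - 1)/(r - 1) = head_sum for the ratio r > 1
    def f(r: float) -> float:
        return h_min * (r ** n_orb - 1) / (r - 1) - head_sum

    if f(1 + 1e-9) > 0:
        raise ValueError("head cannot sum to the requested mass above the knee")
    r = brentq(f, 1 + 1e-9, 1e3)
    vals = h_min * r ** np.arange(n_orb - 1, -1, -1, dtype=float)
    return vals


def _tail_values(n_urb: int, knee_pct: float, tail_top: float = 0.6,
                 nominal_depth: int = NOMINAL_DEPTH) -> np.ndarray:
    """Log-series-shaped tail truncated near one expected read.

    Weights w_j = x^j / j are scaled so the largest tail family sits at
    ``tail_top * knee_pct`` and x is solved so the smallest lands near the
    percentage worth one read at the nominal depth — a long, even tail.
    """
    if n_urb == 0:
        return np.array([])
    top = tail_top * knee_pct
    if n_urb == 1:
        return np.array([top])
    floor_pct = 100.0 / nominal_depth
    min_rel = min(floor_pct / top, 0.9)

    def g(x: float) -> float:
        return (n_urb - 1) * np.log(x) - np.log(n_urb) - np.log(min_rel)

    x = brentq(g, 1e-3, 2.0)
    j = np.arange(1, n_urb + 1, dtype=float)
    w = np.sort(x ** j / j)[::-1]
    return w / w[0] * top


def gen_community(
    design: list[tuple[str, str]],
    knee_pct: float,
    n_orb: int,
    n_urb: int,
    effects: dict[str, float] | None,
    seed: int,
    tree: TaxonomyTree | None = None,
    jitter_sd: float = 0.10,
    head_min_factor: float = 1.5,
    tail_top_factor: float = 0.6,
) -> CommunityTruth:
    """Plant a two-regime rank-abundance community over a design.

    Per library, abundances are the canonical two-regime profile (geometric
    head above ``knee_pct``, log-series tail below) with lognormal jitter,
    fold effects applied to total vs active fractions, then renormalized.
    Effects are applied symmetrically (totals x sqrt(f), actives / sqrt(f))
    so the realized total:active percentage ratio tracks f after
    renormalization.
    """
    if not design:
        raise ValueError("empty design")
    for s, f in design:
        if f not in FRACTIONS:
            raise ValueError(f"unknown fraction {f!r} in design (library {s})")
    if not 0 < knee_pct < 100:
        raise ValueError("knee_pct must lie in (0, 100)")
    if n_orb < 1 or n_urb < 0:
        raise ValueError("need n_orb >= 1 and n_urb >= 0")

    n_fam = n_orb + n_urb
    if tree is None:
        tree = gen_taxonomy(min(13, n_fam), n_fam, seed)
    fam_nodes = sorted(tree.nodes_at_rank("family"), key=tree.name_of)
    if len(fam_nodes) < n_fam:
        raise ValueError(f"taxonomy has only {len(fam_nodes)} families, need {n_fam}")
    families = [tree.name_of(i) for i in fam_nodes[:n_fam]]

    effects = dict(effects or {})
    unknown = set(effects) - set(families)
    if unknown:
        raise ValueError(f"effects reference unknown families: {sorted(unknown)}")

    tail = _tail_values(n_urb, knee_pct, tail_top=tail_top_factor)
    head = _head_values(n_orb, 100.0 - tail.sum(), head_min_factor * knee_pct)
    base = np.concatenate([head, tail])  # canonical percentages, sum 100
    orb = pd.Series([True] * n_orb + [False] * n_urb, index=families, name="orb_flag")

    # an effect must not push its family across the knee in any fraction
    for fam, f in effects.items():
        b = base[families.index(fam)]
        swing = np.sqrt(max(f, 1 / f))
        if bool(orb[fam]) and b / swing <= knee_pct * 1.2:
            raise ValueError(
                f"effect {f} on head family {fam} (base {b:.2f}%) would cross "
                "the knee; plant effects on more abundant families"
            )
        if not bool(orb[fam]) and b * swing >= knee_pct * 0.8:
            raise ValueError(
                f"effect {f} on tail family {fam} (base {b:.2f}%) would cross "
                "the knee; plant effects deeper in the tail or on the head"
            )

    rng = rng_for(seed, "community")
    cols = {}
    for s, frac in design:
        vals = base * np.exp(rng.normal(0.0, jitter_sd, size=n_fam))
        # keep jittered values on the correct side of the knee
        vals[:n_orb] = np.maximum(vals[:n_orb], knee_pct * 1.2)
        if n_urb:
            vals[n_orb:] = np.minimum(vals[n_orb:], knee_pct * 0.8)
        for fam, f in effects.items():
            k = families.index(fam)
            vals[k] *= np.sqrt(f) if frac in TOTAL_FRACTIONS else 1 / np.sqrt(f)
        cols[library_id(s, frac)] = vals / vals.sum()
    table = pd.DataFrame(cols, index=families)
    return CommunityTruth(tree, families, table, orb, effects, knee_pct, list(design))


def default_effects(truth_families: list[str]) -> dict[str, float]:
    """The planted fold changes of the default scenario.

    One head family enriched ninefold in the total fractions (the
    Bacteroidetes-like signal) and three head families enriched fourfold in
    the actives.
    """
    return {
        truth_families[2]: 9.0,
        truth_families[3]: 0.25,
        truth_families[4]: 0.25,
        truth_families[5]: 0.25,
    }


def choose_default_effects(
    truth: CommunityTruth,
    fold_total: float = 9.0,
    fold_active: float = 0.25,
    n_active: int = 3,
) -> dict[str, float]:
    """Pick safely-placed fold effects for an already generated community.

    The total-enriched family and the active-enriched families are drawn
    from the head, starting at the third rank, subject to the requirement
    that the effect cannot push them across the knee in any library.
    Families the head cannot accommodate are simply not planted.
    """
    pct = truth.percentages()
    min_b = pct.min(axis=1)
    margin = truth.knee_pct * 1.3
    effects: dict[str, float] = {}
    head = [f for f in truth.families if truth.orb_flag[f]]
    for fam in head[2:]:
        if not effects:
            if min_b[fam] / np.sqrt(fold_total) > margin:
                effects[fam] = fold_total
        elif len(effects) <= n_active and \
                min_b[fam] / np.sqrt(max(fold_active, 1 / fold_active)) > margin:
            effects[fam] = fold_active
    return effects


def default_scenario(seed: int, n_samples: int = 4) -> CommunityTruth:
    """The default study conditions: 13 phyla / 79 families, 8 ORB + 71 URB,
    knee at 1%, planted 9x total-enriched family plus three active-enriched."""
    tree = gen_taxonomy(13, 79, seed)
    fam_nodes = sorted(tree.nodes_at_rank("family"), key=tree.name_of)
    families = [tree.name_of(i) for i in fam_nodes]
    return gen_community(
        default_design(n_samples), knee_pct=1.0, n_orb=8, n_urb=71,
        effects=default_effects(families), seed=seed, tree=tree,
    )


def clear_separation_scenario(seed: int, n_samples: int = 4) -> CommunityTruth:
    """The default scenario with a wide head/tail gap (head >= 3x the knee,
    tail <= a third of it) — the regime where ORB/URB truth is unambiguous."""
    tree = gen_taxonomy(13, 79, seed)
    fam_nodes = sorted(tree.nodes_at_rank("family"), key=tree.name_of)
    families = [tree.name_of(i) for i in fam_nodes]
    return gen_community(
        default_design(n_samples), knee_pct=1.0, n_orb=8, n_urb=71,
        effects=default_effects(families), seed=seed, tree=tree,
        head_min_factor=3.0, tail_top_factor=1 / 3,
    )


def sample_counts(truth: CommunityTruth, reads_per_library: int, seed: int) -> pd.DataFrame:
    """Multinomially sample a family count table directly from the truth.

    The read-free shortcut for abundance-level experiments: equivalent in
    distribution to generating reads with no errors and assigning each to
    its true family.
    """
    rng = rng_for(seed, "counts")
    cols = {}
    for lib in truth.libraries:
        p = truth.base_abundance[lib].to_numpy()
        cols[lib] = rng.multinomial(reads_per_library, p / p.sum())
    return pd.DataFrame(cols, index=truth.families)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    read_id: str
    source_family: str
    source_species: int
    sample: str
    fraction: str
    permutag: str
    mid_id: str
    is_emulsion_duplicate: bool
    n_errors: int
    insert_length: int

    @property
    def library(self) -> str:
        return library_id(self.sample, self.fraction)


@dataclass
class SyntheticReads:
    """Reads plus their per-read truth ledger and the reference sequences."""

    records: list[tuple[str, str]]  # (read_id, sequence), file order
    truths: list[ReadTruth]
    references: dict[int, str]  # species node id -> reference sequence
    mid_by_library: dict[str, str]  # library_id -> mid_id

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": t.read_id, "source_family": t.source_family,
                    "source_species": t.source_species, "sample": t.sample,
                    "fraction": t.fraction, "permutag": t.permutag,
                    "mid_id": t.mid_id,
                    "is_emulsion_duplicate": t.is_emulsion_duplicate,
                    "n_errors": t.n_errors, "insert_length": t.insert_length,
                }
                for t in self.truths
            ]
        )


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _substitute(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode(), int(len(hits))


def gen_reads(
    truth: CommunityTruth,
    scheme: TagScheme | None,
    reads_per_library: int,
    dup_rate: float,
    error_rate: float,
    seed: int,
    insert_length: tuple[int, int] = (460, 520),
) -> SyntheticReads:
    """Generate tagged amplicon reads with emulsion-PCR duplicates.

    Each read is MID + PERMUTAG + linker + forward primer + insert, the
    insert being a window of the source species' reference sequence with
    per-base substitution errors. A ``dup_rate`` share of each library's
    reads are byte-identical copies of earlier reads in that library
    (duplicates are drawn after error injection). Substitution errors only;
    no flowgram or homopolymer modelling.
    """
    if not 0 <= dup_rate < 1 or not 0 <= error_rate < 1:
        raise ValueError("dup_rate and error_rate must lie in [0, 1)")
    libs = truth.libraries
    if scheme is None:
        scheme = TagScheme(mids=default_mids(len(libs)))
    if len(scheme.mids) < len(libs):
        raise ValueError(f"scheme has {len(scheme.mids)} MIDs for {len(libs)} libraries")
    mid_ids = sorted(scheme.mids)
    mid_by_library = {lib: mid_ids[i] for i, lib in enumerate(libs)}
    permutags = sorted(scheme.permutags)

    fam_species: dict[str, list[int]] = {}
    for sp in sorted(truth.tree.nodes_at_rank("species")):
        fam_node = truth.tree.ancestor_at_rank(sp, "family")
        fam_species.setdefault(truth.tree.name_of(fam_node), []).append(sp)
    ref_len = insert_length[1] + 80
    ref_rng = rng_for(seed, "references")
    references = {
        sp: _random_dna(ref_rng, ref_len)
        for sps in fam_species.values() for sp in sps
    }

    records: list[tuple[str, str]] = []
    truths: list[ReadTruth] = []
    n_dup = int(round(reads_per_library * dup_rate))
    n_unique = reads_per_library - n_dup
    for (samp, frac) in truth.design:
        lib = library_id(samp, frac)
        rng = rng_for(seed, "reads", lib)
        mid_id = mid_by_library[lib]
        mid = scheme.mids[mid_id]
        p = truth.base_abundance[lib].to_numpy()
        fam_draws = rng.multinomial(n_unique, p / p.sum())
        lib_records: list[tuple[str, str]] = []
        lib_truths: list[ReadTruth] = []
        i_read = 0
        for fam, count in zip(truth.families, fam_draws):
            species = fam_species[fam]
            for _ in range(count):
                sp = species[rng.integers(0, len(species))]
                ilen = int(rng.integers(insert_length[0], insert_length[1] + 1))
                start = int(rng.integers(0, ref_len - ilen + 1))
                insert, nerr = _substitute(rng, references[sp][start:start + ilen], error_rate)
                tag = permutags[rng.integers(0, len(permutags))]
                read_id = f"{lib}_r{i_read:06d}"
                i_read += 1
                lib_records.append((read_id, mid + tag + scheme.linker + scheme.forward_primer + insert))
                lib_truths.append(ReadTruth(read_id, fam, sp, samp, frac, tag, mid_id,
                                            False, nerr, ilen))
        # emulsion duplicates: byte-identical copies of earlier reads
        for _ in range(n_dup):
            if not lib_records:
                break
            j = int(rng.integers(0, len(lib_records)))
            parent_id, seq = lib_records[j]
            pt = lib_truths[j]
            read_id = f"{lib}_r{i_read:06d}"
            i_read += 1
            lib_records.append((read_id, seq))
            lib_truths.append(ReadTruth(read_id, pt.source_family, pt.source_species,
                                        samp, frac, pt.permutag, mid_id, True,
                                        pt.n_errors, pt.insert_length))
        records.extend(lib_records)
        truths.extend(lib_truths)
    return SyntheticReads(records, truths, references, mid_by_library)


def write_fasta(reads: SyntheticReads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads.records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(reads: SyntheticReads, path: str | Path, quality: int = 30) -> None:
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in reads.records:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


# ---------------------------------------------------------------------------
# similarity hits
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def gen_hits(
    reads: SyntheticReads,
    tree: TaxonomyTree,
    identity_noise_sd: float,
    seed: int,
    max_decoys: int = 2,
    decoy_scope: str = "confamilial",
) -> pd.DataFrame:
    """Simulate a 12-column similarity-search hit table for tagged reads.

    The true source species always receives the top bitscore, at percent
    identity ``100 - per-read divergence + N(0, identity_noise_sd)``.
    Decoy hits (0..max_decoys per read) target random congeners
    (``decoy_scope='genus'``) or confamilial species, at planted extra
    divergence (3-6 points within the genus, 8-15 within the family) and
    strictly lower bitscore. Stands in for an external search engine; the
    pipeline consumes the table, it never runs the search.
    """
    rng = rng_for(seed, "hits")
    genus_members: dict[int, list[int]] = {}
    family_members: dict[int, list[int]] = {}
    for sp in tree.nodes_at_rank("species"):
        g = tree.ancestor_at_rank(sp, "genus")
        f = tree.ancestor_at_rank(sp, "family")
        genus_members.setdefault(g, []).append(sp)
        family_members.setdefault(f, []).append(sp)

    rows = []
    for t in reads.truths:
        alen = t.insert_length
        divergence = 100.0 * t.n_errors / alen
        pid = float(np.clip(100.0 - divergence + rng.normal(0.0, identity_noise_sd), 0, 100))
        bit_true = round(2.0 * alen * pid / 100.0, 1)
        rows.append((t.read_id, str(t.source_species), round(pid, 2), alen, t.n_errors,
                     0, 1, alen, 1, alen, _evalue(bit_true), bit_true))
        genus = tree.ancestor_at_rank(t.source_species, "genus")
        fam = tree.ancestor_at_rank(t.source_species, "family")
        congeners = [s for s in genus_members[genus] if s != t.source_species]
        confam = [s for s in family_members[fam] if s != t.source_species]
        pool = congeners if decoy_scope == "genus" else (congeners + confam)
        for _ in range(int(rng.integers(0, max_decoys + 1))):
            if not pool:
                break
            s = pool[rng.integers(0, len(pool))]
            extra = (rng.uniform(3, 6) if s in congeners else rng.uniform(8, 15))
            dpid = float(np.clip(pid - extra + rng.normal(0.0, identity_noise_sd), 0, 100))
            dbit = min(round(2.0 * alen * dpid / 100.0, 1), bit_true - 0.1)
            rows.append((t.read_id, str(s), round(dpid, 2), alen,
                         int(round(alen * (100 - dpid) / 100)), 0, 1, alen, 1, alen,
                         _evalue(dbit), dbit))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _evalue(bitscore: float) -> float:
    return float(f"{10 ** -min(bitscore / 5.0, 180.0):.2e}")


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, header=False)


def write_design(design: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(
        [(library_id(s, f), s, f) for s, f in design],
        columns=["library_id", "sample", "fraction"],
    ).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"library_id", "sample", "fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    return df
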