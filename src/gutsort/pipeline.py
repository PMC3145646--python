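"""End-to-end orchestration: simulate -> demux -> assign -> profile ->
metrics -> classify, from one config with one seed.

Every stage is re-runnable from its predecessor's TSV outputs, and every
output file starts with a header comment carrying the tool version, the
config hash and the seed, so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, assign, metrics, orburb, prep, synthetic
from .tags import TagScheme, default_mids
from .taxonomy import TaxonomyTree

log = logging.getLogger("gutsort")


@dataclass
class RunConfig:
    """All knobs for a pipeline run; see module docstrings for semantics."""

    out_dir: str = "results/run"
    seed: int = 1
    # simulation
    n_samples: int = 4
    n_phyla: int = 13
    n_families: int = 79
    n_orb: int = 8
    knee_pct: float = 1.0
    reads_per_library: int = 2000
    dup_rate: float = 0.15
    error_rate: float = 0.005
    identity_noise_sd: float = 0.5
    # stage inputs (filled by simulate, or pointed at real data)
    reads_path: str | None = None
    hits_path: str | None = None
    nodes_path: str | None = None
    names_path: str | None = None
    design_path: str | None = None
    # LCA
    min_identity: float = 80.0
    score_window: float = 0.9
    # metrics
    n_perm: int = 1000
    rarefaction_depths: list[int] = field(default_factory=lambda: [1, 10, 50, 100, 250, 500, 1000])
    # orb/urb
    smoothing_span: float = 0.15
    bin_width: float = 0.25
    alpha: float = 0.05
    cutoff_endpoint: str = "high"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# gutsort {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"


def write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: RunConfig, overwrite: bool = False) -> dict[str, Path]:
    """Write a complete synthetic dataset plus its truth ledger and manifest."""
    out = Path(cfg.out_dir) / "sim"
    manifest_path = out / "manifest.yaml"
    if manifest_path.exists() and not overwrite:
        raise StageError("simulate", f"{manifest_path} exists; pass overwrite to replace")
    out.mkdir(parents=True, exist_ok=True)

    tree = synthetic.gen_taxonomy(cfg.n_phyla, cfg.n_families, cfg.seed)
    design = synthetic.default_design(cfg.n_samples)
    base_truth = synthetic.gen_community(
        design, cfg.knee_pct, cfg.n_orb, cfg.n_families - cfg.n_orb,
        None, cfg.seed, tree=tree,
    )
    effects = synthetic.choose_default_effects(base_truth)
    truth = synthetic.gen_community(
        design, cfg.knee_pct, cfg.n_orb, cfg.n_families - cfg.n_orb,
        effects, cfg.seed, tree=tree,
    )
    scheme = TagScheme(mids=default_mids(len(truth.libraries)))
    reads = synthetic.gen_reads(truth, scheme, cfg.reads_per_library,
                                cfg.dup_rate, cfg.error_rate, cfg.seed)
    hits = synthetic.gen_hits(reads, tree, cfg.identity_noise_sd, cfg.seed)

    paths = {
        "reads": out / "reads.fasta",
        "hits": out / "hits.tsv",
        "nodes": out / "taxonomy.nodes.tsv",
        "names": out / "taxonomy.names.tsv",
        "design": out / "design.tsv",
        "truth_reads": out / "truth.reads.tsv",
        "truth_abundance": out / "truth.abundance.tsv",
        "mids": out / "mids.tsv",
    }
    synthetic.write_fasta(reads, paths["reads"])
    synthetic.write_hits(hits, paths["hits"])
    tree.to_tsv(paths["nodes"], paths["names"])
    synthetic.write_design(truth.design, paths["design"])
    write_tsv(reads.truth_frame(), paths["truth_reads"], cfg)
    write_tsv(truth.percentages().rename_axis("family"), paths["truth_abundance"], cfg, index=True)
    mids = pd.DataFrame(
        [(lib, mid, scheme.mids[mid]) for lib, mid in reads.mid_by_library.items()],
        columns=["library_id", "mid_id", "mid_sequence"],
    )
    write_tsv(mids, paths["mids"], cfg)
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(
            {"version": __version__, "seed": cfg.seed, "config": asdict(cfg),
             "config_hash": cfg.config_hash(),
             "files": {k: str(v) for k, v in paths.items()}},
            fh, sort_keys=True,
        )
    cfg.reads_path = str(paths["reads"])
    cfg.hits_path = str(paths["hits"])
    cfg.nodes_path = str(paths["nodes"])
    cfg.names_path = str(paths["names"])
    cfg.design_path = str(paths["design"])
    log.info("simulate: %d libraries, %d reads", len(truth.libraries), len(reads.records))
    return paths


def run_demux(cfg: RunConfig, scheme: TagScheme, mid_to_library: dict[str, str]) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    if not cfg.reads_path or not Path(cfg.reads_path).exists():
        raise StageError("demux", f"reads file missing: {cfg.reads_path}")
    raw = prep.read_sequences(cfg.reads_path)
    parsed, failed = prep.parse_reads(raw, scheme)
    derep = prep.dereplicate(parsed)
    clean = prep.strip_tags(derep, mid_to_library)
    report = prep.demux_report(parsed, failed, derep, mid_to_library)
    write_tsv(report, out / "demux_report.tsv", cfg)
    write_tsv(clean, out / "clean_reads.tsv", cfg)
    prep.write_clean_fasta(clean, out / "clean")
    log.info("demux: %d in, %d assigned, %d duplicates removed, %d unassigned",
             len(raw), len(parsed), derep.removed_count, len(failed))
    return clean


def run_assign(cfg: RunConfig, clean: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(cfg.out_dir)
    if not cfg.hits_path or not Path(cfg.hits_path).exists():
        raise StageError("assign", f"hits file missing: {cfg.hits_path}")
    tree = TaxonomyTree.from_tsv(cfg.nodes_path, cfg.names_path)
    hits = assign.load_hits(cfg.hits_path)
    hits = hits[hits["qseqid"].isin(set(clean["read_id"]))]
    params = assign.LcaParams(cfg.min_identity, cfg.score_window)
    assignments, unassigned = assign.assign_all(hits, tree, params)
    library_of = dict(zip(clean["read_id"], clean["library_id"]))
    fam_counts = assign.rank_counts(assignments, library_of, tree, "family")
    phy_counts = assign.rank_counts(assignments, library_of, tree, "phylum")
    fingerprint = assign.identity_fingerprint(assignments, library_of)
    write_tsv(assign.assignments_frame(assignments, tree), out / "assignments.tsv", cfg)
    write_tsv(fam_counts.rename_axis("family"), out / "family_counts.tsv", cfg, index=True)
    write_tsv(phy_counts.rename_axis("phylum"), out / "phylum_counts.tsv", cfg, index=True)
    write_tsv(fingerprint, out / "fingerprint.tsv", cfg)
    log.info("assign: %d assigned, %d unassigned, %d families",
             len(assignments), len(unassigned), len(fam_counts))
    return fam_counts, fingerprint


def run_metrics(cfg: RunConfig, fam_counts: pd.DataFrame, design: pd.DataFrame) -> dict:
    out = Path(cfg.out_dir)
    counts = fam_counts.drop(index=[assign.UNCLASSIFIED], errors="ignore")
    percent = metrics.normalize_percent(counts)
    dist = metrics.distance_matrix(percent)
    dendro = metrics.cluster_complete(dist)
    decomp = metrics.permanova(dist, design, n_perm=cfg.n_perm, seed=cfg.seed)
    depths = [d for d in cfg.rarefaction_depths if d <= counts.sum(axis=0).min()]
    rare = pd.concat([
        metrics.rarefaction(counts[lib], depths).assign(library=lib)
        for lib in counts.columns
    ])[["library", "depth", "expected_richness"]]
    div = metrics.diversity_table(counts)

    write_tsv(percent.rename_axis("family"), out / "family_percent.tsv", cfg, index=True)
    write_tsv(dist.rename_axis("library"), out / "bray_curtis.tsv", cfg, index=True)
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    write_tsv(decomp.table.reset_index(), out / "permanova.tsv", cfg)
    write_tsv(rare, out / "rarefaction.tsv", cfg)
    write_tsv(div, out / "diversity.tsv", cfg)
    log.info("metrics: PERMANOVA actives-vs-totals p=%.4g",
             decomp.table.loc["actives_vs_totals", "Pr(>F)"])
    return {"percent": percent, "distance": dist, "dendrogram": dendro,
            "permanova": decomp, "rarefaction": rare, "diversity": div}


def run_classify(cfg: RunConfig, percent: pd.DataFrame, design: pd.DataFrame) -> dict:
    out = Path(cfg.out_dir)
    cut, welch = orburb.run_orb_urb(percent, design, cfg.smoothing_span,
                                    cfg.bin_width, cfg.alpha, cfg.cutoff_endpoint)
    cut_rows = pd.DataFrame(
        [(lib, c, len(cut.diagnostics[lib].inflection_ranks))
         for lib, c in cut.per_library.items()],
        columns=["library", "cutoff_pct", "n_inflections"],
    )
    diag_rows = pd.concat([
        pd.DataFrame({
            "library": lib, "rank": d.ranks, "percentage": 10 ** d.log10_pct,
            "smoothed": 10 ** d.smoothed, "second_derivative": d.second_derivative,
        })
        for lib, d in cut.diagnostics.items()
    ])
    summary = welch.table.join(cut.group_labels[["active_label", "total_label"]])
    write_tsv(cut_rows, out / "cutoffs.tsv", cfg)
    write_tsv(diag_rows, out / "inflection_diagnostics.tsv", cfg)
    write_tsv(cut.labels.rename_axis("family"), out / "orb_urb_labels.tsv", cfg, index=True)
    write_tsv(orburb.classification_summary(cut.group_labels), out / "orb_urb_summary.tsv", cfg)
    write_tsv(summary.reset_index(), out / "welch.tsv", cfg)
    log.info("classify: consensus cutoff %.3g%%, %d significant families",
             cut.consensus, int(welch.table["significant"].sum()))
    return {"cutoffs": cut, "welch": welch}


def run_all(cfg: RunConfig, overwrite: bool = False) -> dict:
    """Execute every stage; on failure the failing stage is named and
    partial outputs are retained."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    results["sim"] = run_simulate(cfg, overwrite=overwrite)
    mids = read_tsv(Path(cfg.out_dir) / "sim" / "mids.tsv")
    scheme = TagScheme(mids=dict(zip(mids["mid_id"], mids["mid_sequence"])))
    mid_to_library = dict(zip(mids["mid_id"], mids["library_id"]))
    clean = run_demux(cfg, scheme, mid_to_library)
    fam_counts, _ = run_assign(cfg, clean)
    design = synthetic.read_design(cfg.design_path)
    results["metrics"] = run_metrics(cfg, fam_counts, design)
    results["classify"] = run_classify(cfg, results["metrics"]["percent"], design)

    # family sets found per group (active-only / total-only / shared)
    percent = results["metrics"]["percent"]
    frac_of = design.set_index("library_id")["fraction"]
    active_cols = [c for c in percent.columns if frac_of[c] in synthetic.ACTIVE_FRACTIONS]
    total_cols = [c for c in percent.columns if frac_of[c] in synthetic.TOTAL_FRACTIONS]
    in_active = set(percent.index[(percent[active_cols] > 0).any(axis=1)])
    in_total = set(percent.index[(percent[total_cols] > 0).any(axis=1)])
    overlap = pd.DataFrame([
        ("families_total_fractions", len(in_total)),
        ("families_active_fractions", len(in_active)),
        ("families_shared", len(in_active & in_total)),
        ("families_active_only", len(in_active - in_total)),
        ("families_total_only", len(in_total - in_active)),
    ], columns=["quantity", "value"])
    write_tsv(overlap, out / "family_sets.tsv", cfg)
    results["family_sets"] = overlap
    return results
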