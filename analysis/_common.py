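"""Shared configuration for the numbered analysis scripts.

One run directory, one seed: every script reads its predecessor's outputs
from RESULTS and appends its own, so the sequence 01..05 reproduces the
whole analysis from nothing.
"""

from pathlib import Path

from gutsort.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def make_config(seed: int = 1) -> RunConfig:
    cfg = RunConfig(out_dir=str(RESULTS), seed=seed,
                    reads_per_library=2000, n_perm=999)
    sim = RESULTS / "sim"
    if (sim / "manifest.yaml").exists():
        cfg.reads_path = str(sim / "reads.fasta")
        cfg.hits_path = str(sim / "hits.tsv")
        cfg.nodes_path = str(sim / "taxonomy.nodes.tsv")
        cfg.names_path = str(sim / "taxonomy.names.tsv")
        cfg.design_path = str(sim / "design.tsv")
    return cfg
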