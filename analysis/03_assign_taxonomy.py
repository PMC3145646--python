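#!/usr/bin/env python
"""Assign each clean read to its lowest common ancestor and profile.

Hits within 90% of a read's best bitscore (and above 80% identity) vote
through their lineages; reads whose LCA is shallower than family count as
"unclassified" at family rank. Writes family- and phylum-level count
tables and the best-hit identity fingerprint.
"""

from _common import RESULTS, make_config
from gutsort.pipeline import read_tsv, run_assign


def main() -> None:
    cfg = make_config()
    clean = read_tsv(RESULTS / "clean_reads.tsv")
    fam_counts, _ = run_assign(cfg, clean)
    n_unclassified = int(fam_counts.loc["unclassified"].sum()) \
        if "unclassified" in fam_counts.index else 0
    print(f"assigned {fam_counts.to_numpy().sum()} reads "
          f"({n_unclassified} to unclassified families)")
    print(f"{len(fam_counts.drop(index='unclassified', errors='ignore'))} families "
          f"observed -> {RESULTS / 'family_counts.tsv'}")


if __name__ == "__main__":
    main()
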