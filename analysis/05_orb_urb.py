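#!/usr/bin/env python
"""Split families into ORB and URB and compare active vs total fractions.

Per library, the ordered family distribution is smoothed on a log scale,
inflection points are read from the second derivative, and the cutoff is
the value at the last inflection along the sorted curve; the consensus
(most recurrent) cutoff defines ORB (> cutoff) vs URB. Each family's
active-vs-total contrast is a Welch t-test on per-subject median
percentages.
"""

from _common import RESULTS, make_config
from gutsort.pipeline import read_tsv, run_classify
from gutsort.synthetic import read_design


def main() -> None:
    cfg = make_config()
    percent = read_tsv(RESULTS / "family_percent.tsv", index_col="family")
    design = read_design(cfg.design_path)
    out = run_classify(cfg, percent, design)
    cut = out["cutoffs"]
    welch = out["welch"]
    print(f"consensus cutoff: {cut.consensus:.3g}% "
          f"(per-library cutoffs from {len(cut.per_library)} libraries)")
    summary = read_tsv(RESULTS / "orb_urb_summary.tsv")
    print(summary.to_string(index=False))
    sig = welch.table[welch.table["significant"]]
    print(f"{len(sig)} families differ significantly between active and "
          f"total fractions (alpha {welch.alpha}):")
    cols = ["active_median", "total_median", "t_stat", "p"]
    print(sig[cols].to_string(float_format=lambda v: f"{v:.4g}"))

    frac_of = design.set_index("library_id")["fraction"]
    active_cols = [c for c in percent.columns if frac_of[c] in ("PA", "LC", "HC")]
    total_cols = [c for c in percent.columns if frac_of[c] in ("FS", "R")]
    in_active = set(percent.index[(percent[active_cols] > 0).any(axis=1)])
    in_total = set(percent.index[(percent[total_cols] > 0).any(axis=1)])
    print(f"\nfamilies seen in total fractions: {len(in_total)}; "
          f"in active fractions: {len(in_active)} "
          f"({len(in_active - in_total)} visible only after cell sorting)")


if __name__ == "__main__":
    main()
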