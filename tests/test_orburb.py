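import numpy as np
import pandas as pd
import pytest

from conftest import design_frame
from gutsort.metrics import normalize_percent
from gutsort.orburb import (
    InflectionDiagnostics,
    classify,
    classification_summary,
    consensus_cutoff,
    find_inflections,
    library_cutoff,
    ordered_distribution,
    run_orb_urb,
    welch_family_test,
)
from gutsort.synthetic import clear_separation_scenario, sample_counts


def dist_from(values, names=None):
    names = names or [f"F{i:02d}" for i in range(len(values))]
    return ordered_distribution(pd.Series(values, index=names, name="L1"))


class TestOrderedDistribution:
    def test_sorted_descending_with_values(self):
        d = dist_from({"A": 50.0, "B": 30.0, "C": 20.0}.values(),
                      names=["A", "B", "C"])
        assert d.families == ["A", "B", "C"]
        assert list(d.percentages) == [50.0, 30.0, 20.0]

    def test_ties_break_alphabetically(self):
        s = pd.Series({"b": 25.0, "a": 25.0, "d": 25.0, "c": 25.0}, name="L")
        d = ordered_distribution(s)
        assert d.families == ["a", "b", "c", "d"]

    def test_sum_conserved_and_zeros_dropped(self):
        s = pd.Series({"a": 60.0, "b": 40.0, "c": 0.0}, name="L")
        d = ordered_distribution(s)
        assert d.percentages.sum() == pytest.approx(100.0)
        assert "c" not in d.families


class TestFindInflections:
    def geometric(self, n=60, ratio=1.25, top=30.0):
        return top / ratio ** np.arange(n)

    def test_pure_geometric_curve_has_no_inflections(self):
        d = dist_from(self.geometric())
        for span in (0.3, 0.5, 0.8):
            diag = find_inflections(d, smoothing_span=span)
            assert diag.inflection_ranks == []
            inner = diag.second_derivative[1:-1]
            assert np.nanmax(np.abs(inner)) < 1e-6

    def test_constant_distribution_has_no_inflections(self):
        d = dist_from(np.full(12, 100 / 12))
        assert find_inflections(d).inflection_ranks == []

    def test_too_few_families_flagged(self):
        with pytest.raises(ValueError, match="at least 5"):
            find_inflections(dist_from([40.0, 30, 20, 10]))

    def test_planted_regime_change_is_localized(self):
        """Two concatenated geometric decays: the detected inflection nearest
        the junction must sit within 2 ranks of the exact curvature onset,
        computed from the noise-free generating function on a dense grid."""
        r0, n = 20, 60
        steep, shallow = 0.22, 0.02  # log10 decrements per rank
        ranks = np.arange(1, n + 1)
        logy = np.where(ranks <= r0, -steep * ranks,
                        -steep * r0 - shallow * (ranks - r0))
        d = dist_from(10.0 ** logy)
        diag = find_inflections(d, smoothing_span=0.15)
        assert diag.inflection_ranks, "no inflection found at a planted knee"
        # dense-grid oracle: exact second derivative of the generator is zero
        # away from r0 and a positive spike at r0
        grid = np.linspace(1, n, 10_000)
        exact = np.gradient(np.gradient(
            np.where(grid <= r0, -steep * grid, -steep * r0 - shallow * (grid - r0)),
            grid), grid)
        oracle_rank = grid[int(np.argmax(np.abs(exact)))]
        nearest = min(diag.inflection_ranks, key=lambda r: abs(r - oracle_rank))
        assert abs(nearest - oracle_rank) <= 2


class TestLibraryCutoff:
    def make_diag(self, inflections, n=60):
        sm = np.linspace(1.5, -2.0, n)
        return InflectionDiagnostics(np.arange(1, n + 1), sm, sm,
                                     np.zeros(n), inflections)

    def test_low_endpoint_takes_greatest_rank(self):
        d = dist_from(10 ** np.linspace(1.5, -2.0, 60))
        diag = self.make_diag([5, 23])
        assert library_cutoff(d, diag, endpoint="low") == pytest.approx(
            10 ** diag.smoothed[22])

    def test_high_endpoint_takes_smallest_rank(self):
        d = dist_from(10 ** np.linspace(1.5, -2.0, 60))
        diag = self.make_diag([5, 23])
        assert library_cutoff(d, diag, endpoint="high") == pytest.approx(
            10 ** diag.smoothed[4])

    def test_no_inflections_returns_none(self):
        d = dist_from(10 ** np.linspace(1.5, -2.0, 60))
        assert library_cutoff(d, self.make_diag([])) is None

    def test_unknown_endpoint_rejected(self):
        d = dist_from(10 ** np.linspace(1.5, -2.0, 60))
        with pytest.raises(ValueError):
            library_cutoff(d, self.make_diag([3]), endpoint="middle")


class TestConsensusCutoff:
    def test_modal_bin_dominates(self):
        c = consensus_cutoff({"a": 0.9, "b": 1.0, "c": 1.1, "d": 3.2}, bin_width=0.25)
        assert abs(np.log10(c)) < 0.125  # within half a bin of 1%

    def test_all_equal_returns_that_value(self):
        assert consensus_cutoff({"a": 0.7, "b": 0.7}) == pytest.approx(0.7)

    def test_single_library_returns_its_own(self):
        assert consensus_cutoff({"a": 2.5}) == pytest.approx(2.5)

    def test_all_none_is_an_error(self):
        with pytest.raises(ValueError, match="manual"):
            consensus_cutoff({"a": None, "b": None})


class TestClassify:
    @pytest.fixture()
    def small(self):
        percent = pd.DataFrame({
            "S1_PA": [5.0, 1.0, 94.0], "S1_FS": [4.0, 0.5, 95.5],
        }, index=["big", "edge", "huge"])
        design = pd.DataFrame({
            "library_id": ["S1_PA", "S1_FS"], "sample": ["S1", "S1"],
            "fraction": ["PA", "FS"],
        })
        return percent, design

    def test_above_cutoff_is_orb_at_cutoff_is_urb(self, small):
        percent, design = small
        labels, group = classify(percent, design, cutoff=1.0)
        assert labels.loc["big", "S1_PA"] == "ORB"
        assert labels.loc["edge", "S1_PA"] == "URB"  # boundary convention
        summary = classification_summary(group)
        assert (summary["orb"] + summary["urb"] == summary["present"]).all()

    def test_partition_per_library(self, percent_default, design_default):
        labels, _ = classify(percent_default, design_default, cutoff=1.0)
        for lib in percent_default.columns:
            present = int((percent_default[lib] > 0).sum())
            orb = int((labels[lib] == "ORB").sum())
            urb = int((labels[lib] == "URB").sum())
            assert orb + urb == present

    def test_labels_invariant_to_common_rescaling(self, percent_default, design_default):
        # cutoff chosen off the count grid so float jitter cannot flip a label
        labels_a, _ = classify(percent_default, design_default, 0.97)
        rescaled = normalize_percent(percent_default * 4.2)
        labels_b, _ = classify(rescaled, design_default, 0.97)
        assert labels_a.equals(labels_b)

    def test_nonpositive_cutoff_rejected(self, small):
        percent, design = small
        with pytest.raises(ValueError):
            classify(percent, design, 0.0)


class TestWelch:
    def welch_inputs(self, a_vals, t_vals):
        """Build a table where per-sample medians equal the given vectors."""
        samples = [f"S{i+1}" for i in range(len(a_vals))]
        design = design_frame([(s, f) for s in samples
                               for f in ("PA", "LC", "HC", "FS", "R")])
        data = {}
        for s, a, t in zip(samples, a_vals, t_vals):
            for f in ("PA", "LC", "HC"):
                data[f"{s}_{f}"] = [a]
            for f in ("FS", "R"):
                data[f"{s}_{f}"] = [t]
        return pd.DataFrame(data, index=["fam"]), design

    def test_identical_groups_give_t0_p1(self):
        percent, design = self.welch_inputs([1, 2, 3], [1, 2, 3])
        res = welch_family_test(percent, design)
        row = res.table.loc["fam"]
        assert row["t_stat"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_worked_example_statistic_and_df(self):
        percent, design = self.welch_inputs([1, 2, 3], [2, 3, 4])
        res = welch_family_test(percent, design)
        row = res.table.loc["fam"]
        assert row["t_stat"] == pytest.approx(-1.2247, abs=1e-4)
        assert row["df"] == pytest.approx(4.0, abs=1e-9)

    def test_degenerate_equal_variance_zero(self):
        percent, design = self.welch_inputs([2, 2, 2], [5, 5, 5])
        res = welch_family_test(percent, design)
        assert bool(res.table.loc["fam", "degenerate"])

    def test_matches_permutation_oracle_direction(self):
        """The Welch p agrees with a label-permutation test on the same
        per-sample values to within Monte-Carlo error."""
        from itertools import combinations

        a, b = [1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 4.5, 6.0]
        percent, design = self.welch_inputs(a, b)
        res = welch_family_test(percent, design)
        p_welch = res.table.loc["fam", "p"]
        pooled = np.array(a + b)
        obs = abs(np.mean(a) - np.mean(b))
        count = total = 0
        for idx in combinations(range(8), 4):
            left = pooled[list(idx)]
            right = np.delete(pooled, list(idx))
            total += 1
            count += abs(left.mean() - right.mean()) >= obs - 1e-12
        p_perm = count / total
        assert p_welch < 0.05 and p_perm < 0.05

    def test_bh_correction_is_monotone(self, percent_default, design_default):
        raw = welch_family_test(percent_default, design_default)
        adj = welch_family_test(percent_default, design_default, bh_correct=True)
        mask = adj.table["p_adjusted"].notna()
        assert (adj.table.loc[mask, "p_adjusted"] >= raw.table.loc[mask, "p"] - 1e-12).all()


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_knee_and_labels_recovered_on_default_scenario(self, seed):
        from gutsort.synthetic import default_scenario

        truth = default_scenario(seed=seed)
        percent = normalize_percent(sample_counts(truth, 10_000, seed=seed))
        design = design_frame(truth.design)
        cut, _ = run_orb_urb(percent, design)
        assert truth.knee_pct / 2 <= cut.consensus <= truth.knee_pct * 2
        ok = tot = 0
        for fam in percent.index:
            for lib in percent.columns:
                if percent.loc[fam, lib] > 0:
                    tot += 1
                    ok += (cut.labels.loc[fam, lib] == "ORB") == bool(truth.orb_flag[fam])
        assert ok / tot >= 0.95

    def test_labels_fully_recovered_under_clear_separation(self):
        truth = clear_separation_scenario(seed=3)
        percent = normalize_percent(sample_counts(truth, 10_000, seed=3))
        design = design_frame(truth.design)
        cut, _ = run_orb_urb(percent, design)
        ok = tot = 0
        for fam in percent.index:
            for lib in percent.columns:
                if percent.loc[fam, lib] > 0:
                    tot += 1
                    ok += (cut.labels.loc[fam, lib] == "ORB") == bool(truth.orb_flag[fam])
        assert ok / tot >= 0.95
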