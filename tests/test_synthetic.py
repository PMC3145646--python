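import numpy as np
import pandas as pd
import pytest

from gutsort.synthetic import (
    ACTIVE_FRACTIONS,
    TOTAL_FRACTIONS,
    default_design,
    default_effects,
    gen_community,
    gen_hits,
    gen_reads,
    gen_taxonomy,
    sample_counts,
    write_hits,
)
from gutsort.tags import TagScheme, default_mids, matches_pattern


@pytest.fixture(scope="module")
def tree79():
    return gen_taxonomy(13, 79, seed=1)


class TestGenCommunity:
    def test_library_abundances_sum_to_one(self, truth_default):
        assert np.allclose(truth_default.base_abundance.sum(), 1.0, atol=1e-9)

    def test_every_family_has_a_rooted_lineage(self, truth_default):
        tree = truth_default.tree
        name_to_node = {tree.name_of(i): i for i in tree.nodes_at_rank("family")}
        for fam in truth_default.families:
            lin = tree.lineage(name_to_node[fam])
            assert lin[0] == tree.root
            assert tree.rank_of(lin[-1]) == "family"

    def test_orb_flags_consistent_with_knee_everywhere(self, truth_default):
        pct = truth_default.percentages()
        for fam in truth_default.families:
            flag = bool(truth_default.orb_flag[fam])
            vals = pct.loc[fam]
            if flag:
                assert (vals > truth_default.knee_pct).all()
            else:
                assert (vals <= truth_default.knee_pct).all()

    def test_no_effects_and_no_jitter_make_fractions_identical(self):
        truth = gen_community(default_design(2), 1.0, 5, 20, None, seed=4,
                              jitter_sd=0.0)
        cols = truth.base_abundance
        ref = cols.iloc[:, 0]
        for c in cols.columns:
            assert np.allclose(cols[c], ref)

    def test_all_orb_when_tail_empty(self):
        truth = gen_community(default_design(1), 1.0, 6, 0, None, seed=2)
        assert truth.orb_flag.all()
        assert len(truth.families) == 6

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(design=[], knee_pct=1.0, n_orb=2, n_urb=2), "empty design"),
            (dict(design=[("S1", "XX")], knee_pct=1.0, n_orb=2, n_urb=2), "fraction"),
            (dict(design=default_design(1), knee_pct=0.0, n_orb=2, n_urb=2), "knee"),
            (dict(design=default_design(1), knee_pct=1.0, n_orb=2, n_urb=2,
                  effects={"NotAFamily": 2.0}), "unknown families"),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs, msg):
        kwargs.setdefault("effects", None)
        with pytest.raises(ValueError, match=msg):
            gen_community(seed=1, **kwargs)

    def test_effect_that_would_cross_the_knee_is_refused(self, tree79):
        fams = sorted(tree79.name_of(i) for i in tree79.nodes_at_rank("family"))
        top_tail_family = fams[8]  # first family below the knee
        with pytest.raises(ValueError, match="cross the knee"):
            gen_community(default_design(1), 1.0, 8, 71,
                          {top_tail_family: 9.0}, seed=1, tree=tree79)

    def test_rank_order_preserved_without_effects(self):
        truth = gen_community(default_design(1), 1.0, 5, 20, None, seed=8,
                              jitter_sd=0.0)
        for lib in truth.libraries:
            vals = truth.base_abundance[lib].to_numpy()
            assert (np.diff(vals) <= 1e-12).all()

    def test_planted_ninefold_enrichment_recovered_by_sampling(self, truth_default):
        """Monte-Carlo check of the realized total:active percentage ratio
        against the generating fold change, at 10,000 reads per library."""
        counts = sample_counts(truth_default, 10_000, seed=5)
        pct = counts / counts.sum() * 100
        fam9 = next(f for f, v in truth_default.effect_map.items() if v == 9.0)
        tot_cols = [l for l in pct.columns if l.split("_")[1] in TOTAL_FRACTIONS]
        act_cols = [l for l in pct.columns if l.split("_")[1] in ACTIVE_FRACTIONS]
        ratio = pct.loc[fam9, tot_cols].mean() / pct.loc[fam9, act_cols].mean()
        assert 9.0 * 0.75 <= ratio <= 9.0 * 1.25


class TestGenReads:
    def test_read_structure_and_counts(self, truth_small):
        reads = gen_reads(truth_small, None, 30, dup_rate=0.1, error_rate=0.0, seed=1)
        scheme = TagScheme(mids=default_mids(len(truth_small.libraries)))
        mid_codes = set(scheme.mids.values())
        per_lib = {}
        for t in reads.truths:
            per_lib[t.library] = per_lib.get(t.library, 0) + 1
            assert matches_pattern(t.permutag, scheme.permutag_pattern)
        assert all(n == 30 for n in per_lib.values())
        for rid, seq in reads.records[:20]:
            assert seq[:8] in mid_codes

    def test_duplicates_are_byte_identical_to_their_parent(self, truth_small):
        reads = gen_reads(truth_small, None, 50, dup_rate=0.3, error_rate=0.01, seed=2)
        seqs = dict(reads.records)
        by_seq = {}
        for rid, seq in reads.records:
            by_seq.setdefault(seq, []).append(rid)
        for t in reads.truths:
            if t.is_emulsion_duplicate:
                assert len(by_seq[seqs[t.read_id]]) >= 2

    def test_no_errors_means_insert_is_reference_substring(self, truth_small):
        reads = gen_reads(truth_small, None, 25, dup_rate=0.0, error_rate=0.0, seed=3)
        scheme = TagScheme(mids=default_mids(len(truth_small.libraries)))
        block = scheme.tag_block_length
        for (rid, seq), t in zip(reads.records, reads.truths):
            insert = seq[block:]
            assert insert in reads.references[t.source_species]

    def test_deterministic_per_seed(self, truth_small):
        a = gen_reads(truth_small, None, 20, 0.1, 0.01, seed=7)
        b = gen_reads(truth_small, None, 20, 0.1, 0.01, seed=7)
        assert a.records == b.records

    def test_invalid_rates_and_missing_mids(self, truth_small):
        with pytest.raises(ValueError):
            gen_reads(truth_small, None, 10, dup_rate=1.0, error_rate=0.0, seed=1)
        short_scheme = TagScheme(mids=default_mids(2))
        with pytest.raises(ValueError, match="MIDs"):
            gen_reads(truth_small, short_scheme, 10, 0.0, 0.0, seed=1)


class TestGenHits:
    def test_perfect_reads_have_identity_100(self, truth_small):
        reads = gen_reads(truth_small, None, 20, 0.0, 0.0, seed=4)
        hits = gen_hits(reads, truth_small.tree, identity_noise_sd=0.0, seed=4)
        best = hits.loc[hits.groupby("qseqid")["bitscore"].idxmax()]
        assert (best["pident"] == 100.0).all()

    def test_true_species_always_has_top_bitscore(self, truth_small):
        reads = gen_reads(truth_small, None, 30, 0.0, 0.01, seed=5)
        hits = gen_hits(reads, truth_small.tree, 0.5, seed=5)
        truth_sp = {t.read_id: str(t.source_species) for t in reads.truths}
        best = hits.loc[hits.groupby("qseqid")["bitscore"].idxmax()]
        for row in best.itertuples():
            assert row.sseqid == truth_sp[row.qseqid]

    def test_hit_table_is_byte_stable(self, truth_small, tmp_path):
        reads = gen_reads(truth_small, None, 15, 0.0, 0.01, seed=6)
        for i in (1, 2):
            hits = gen_hits(reads, truth_small.tree, 0.5, seed=6)
            write_hits(hits, tmp_path / f"h{i}.tsv")
        assert (tmp_path / "h1.tsv").read_bytes() == (tmp_path / "h2.tsv").read_bytes()


class TestSampleCounts:
    def test_column_totals_equal_depth(self, truth_small):
        c = sample_counts(truth_small, 500, seed=1)
        assert (c.sum() == 500).all()
        assert list(c.index) == truth_small.families

    def test_default_effects_reference_head_families(self, tree79):
        fams = sorted(tree79.name_of(i) for i in tree79.nodes_at_rank("family"))
        effects = default_effects(fams)
        assert 9.0 in effects.values()
        assert list(effects.values()).count(0.25) == 3
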