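"""QC cascade: exact boundary behaviour and clean-data identity."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from rookery.genotypes import MISSING, DepthTable, GenotypeTable
from rookery.qc import (
    CallFlags,
    FilterReport,
    TableEmptiedError,
    call_from_depths,
    caller_consensus,
    contamination_rule,
    final_consistency_filter,
    iterative_missingness_filter,
    locus_ratio_acceptability,
    maf_filter,
    replicate_mismatch_filter,
    run_qc,
    sample_depth_filter,
)
from rookery.simulate import ErrorModel, apply_errors, simulate_panel


def depth_table(counts_by_individual, loci=("L1",), k=2):
    inds = list(counts_by_individual)
    n, m = len(inds), len(loci)
    counts = np.zeros((n, m, k), dtype=np.int64)
    for i, ind in enumerate(inds):
        counts[i] = counts_by_individual[ind]
    alleles = {l: [chr(65 + a) for a in range(k)] for l in loci}
    return DepthTable(counts, inds, list(loci), alleles)


class TestSampleDepth:
    def test_boundary_inclusive_at_threshold(self):
        dt = depth_table({"lo": [[9_999, 0]], "at": [[10_000, 0]], "hi": [[20_000, 0]]})
        kept = sample_depth_filter(dt)
        assert kept == ["at", "hi"]

    def test_planted_fraction_dropped_matches_direct_count(self):
        rng = np.random.default_rng(0)
        totals = np.where(rng.random(200) < 0.18, 5_000, 50_000)
        counts = totals[:, None, None] * np.ones((200, 1, 1), dtype=np.int64)
        dt = DepthTable(counts, [f"I{i}" for i in range(200)], ["L1"], {"L1": ["A"]})
        kept = sample_depth_filter(dt)
        assert len(kept) == int((totals >= 10_000).sum())


class TestReplicateMismatch:
    def _pairs_table(self, n_mismatch, n_pairs=100):
        # locus L1: n_mismatch discordant replicate pairs out of n_pairs
        codes = np.zeros((2 * n_pairs, 1, 2), dtype=np.int16)
        codes[n_pairs : n_pairs + n_mismatch, 0, :] = (0, 1)
        tab = make_table(codes)
        pairs = [(f"I{i + 1}", f"I{n_pairs + i + 1}") for i in range(n_pairs)]
        return tab, pairs

    def test_rate_strictly_above_seven_percent_removed(self):
        tab, pairs = self._pairs_table(8)
        kept, rates = replicate_mismatch_filter(tab, pairs)
        assert kept == [] and rates.loc["L1", "mismatch_rate"] == 0.08

    def test_rate_at_exactly_seven_percent_retained(self):
        tab, pairs = self._pairs_table(7)
        kept, _ = replicate_mismatch_filter(tab, pairs)
        assert kept == ["L1"]

    def test_error_free_replicates_remove_nothing(self, rookery_clean):
        b = rookery_clean.bundle
        kept, rates = replicate_mismatch_filter(b.observed, b.replicate_pairs)
        assert kept == b.observed.loci
        assert (rates["mismatch_rate"] == 0).all()

    def test_missing_calls_excluded_from_denominator(self):
        tab, pairs = self._pairs_table(8)
        codes = tab.codes.copy()
        codes[100] = MISSING  # one mismatching pair becomes uninformative
        tab2 = GenotypeTable(codes, tab.individuals, tab.loci, tab.alleles)
        _, rates = replicate_mismatch_filter(tab2, pairs)
        assert rates.loc["L1", "mismatch_rate"] == pytest.approx(7 / 99)

    def test_dropout_mismatch_rate_matches_analytic_expectation(self):
        # two fresh error draws of the same truth: P(mismatch | het) ~ 2d(1-d)
        panel = simulate_panel(30, seed=5)
        rng = np.random.default_rng(6)
        from rookery.relatedness import _freq_matrix, _hw_draw

        kvec = np.array([len(panel.alleles[l]) for l in panel.loci])
        P = _freq_matrix(panel.loci, panel.alleles, panel.group_freqs())
        truth = GenotypeTable(
            _hw_draw(rng, P, kvec, 600), [f"I{i}" for i in range(600)], panel.loci, panel.alleles
        )
        d = 0.035
        err = ErrorModel(d, 0.0, 0.0)
        rep1 = apply_errors(truth, panel, err, np.random.default_rng(7))
        rep2 = apply_errors(truth, panel, err, np.random.default_rng(8))
        merged = GenotypeTable(
            np.concatenate([rep1.codes, rep2.codes]),
            [f"a{i}" for i in range(600)] + [f"b{i}" for i in range(600)],
            panel.loci,
            panel.alleles,
        )
        pairs = [(f"a{i}", f"b{i}") for i in range(600)]
        _, rates = replicate_mismatch_filter(merged, pairs)
        het_frac = truth.het_mask().mean()
        expected = het_frac * 2 * d * (1 - d)
        observed = rates["mismatch_rate"].mean()
        se = np.sqrt(expected * (1 - expected) / (600 * 30))
        assert abs(observed - expected) < 4 * se + 0.002


class TestCallerConsensus:
    def test_variant_in_one_of_three_callers_removed(self):
        base = make_table(np.zeros((4, 2, 2), dtype=np.int16), loci=["L1", "L2"])
        only1 = base.subset(loci=["L1"])
        kept, df = caller_consensus([base, only1, only1])
        assert "L1" in kept and "L2" not in kept
        assert df.loc["L2", "n_callers"] == 1

    def test_identical_callsets_keep_everything(self, rookery_clean):
        views = rookery_clean.bundle.caller_views
        kept, df = caller_consensus(views)
        assert kept == views[0].loci and (df["mismatch_rate"] == 0).all()

    def test_mismatch_pooled_over_caller_pairs_matches_recount(self, rookery_small):
        views = rookery_small.bundle.caller_views
        _, df = caller_consensus(views)
        # brute-force oracle: recount pooled pairwise mismatches per locus
        for locus in rookery_small.panel.loci[:10]:
            mism = comp = 0
            for a in range(3):
                for b in range(a + 1, 3):
                    ga = views[a].codes[:, views[a].locus_idx(locus)]
                    gb = views[b].codes[:, views[b].locus_idx(locus)]
                    for i in range(views[a].n_individuals):
                        if ga[i, 0] >= 0 and gb[i, 0] >= 0:
                            comp += 1
                            mism += int(tuple(ga[i]) != tuple(gb[i]))
            assert df.loc[locus, "mismatch_rate"] == pytest.approx(mism / comp)

    def test_boundary_rate_and_disjoint_individuals(self):
        # 5.5% mismatches retained, strictly above removed
        n = 200
        codes = np.zeros((n, 1, 2), dtype=np.int16)
        a = make_table(codes)
        codes2 = codes.copy()
        codes2[:11, 0, :] = (0, 1)  # 11/200 = 5.5%
        b = GenotypeTable(codes2, a.individuals, a.loci, a.alleles)
        kept, _ = caller_consensus([a, b])
        assert kept == ["L1"]
        codes3 = codes.copy()
        codes3[:12, 0, :] = (0, 1)  # 6% > 5.5%
        c = GenotypeTable(codes3, a.individuals, a.loci, a.alleles)
        kept, _ = caller_consensus([a, c])
        assert kept == []
        other = make_table(codes, prefix="Z")
        with pytest.raises(ValueError):
            caller_consensus([a, other])


class TestMafAndMissingness:
    def test_rare_minor_allele_removed_boundary_retained(self):
        codes = np.zeros((100, 2, 2), dtype=np.int16)
        codes[0, 0] = (0, 1)  # L1 minor count 1/200 = 0.5% -> removed
        codes[0, 1] = (0, 1)
        codes[1, 1] = (0, 1)  # L2 minor count 2/200 = 1.0% -> retained
        tab = make_table(codes)
        kept, df = maf_filter(tab)
        assert kept == ["L2"]
        assert df.loc["L1", "reason"] == "maf"

    def test_monomorphic_locus_removed_with_reason(self):
        tab = make_table(np.zeros((10, 1, 2), dtype=np.int16))
        kept, df = maf_filter(tab)
        assert kept == [] and df.loc["L1", "reason"] == "monomorphic"

    def test_maf_retention_equals_brute_force_recount(self, rookery_small):
        tab = rookery_small.observed
        kept, _ = maf_filter(tab)
        expect = []
        for j, locus in enumerate(tab.loci):
            calls = tab.codes[:, j, :].ravel()
            calls = calls[calls >= 0]
            freqs = np.bincount(calls, minlength=len(tab.alleles[locus])) / len(calls)
            minor = np.sort(freqs)[:-1]
            if minor.size and minor.max() > 0 and minor.max() >= 0.01:
                expect.append(locus)
        assert kept == expect

    def test_fully_observed_table_unchanged(self):
        tab = make_table(np.tile([[0, 1]], (8, 3, 1)))
        out = iterative_missingness_filter(tab)
        assert out.equals(tab)

    def test_half_missing_individual_dropped_loci_kept(self):
        codes = np.tile([[0, 1]], (6, 4, 1)).astype(np.int16)
        codes[0, :2] = MISSING  # one individual 50% missing
        tab = make_table(codes)
        out = iterative_missingness_filter(tab, end=0.30)
        assert out.loci == tab.loci
        assert "I1" not in out.individuals

    def test_planted_missingness_final_below_allowance(self):
        rng = np.random.default_rng(3)
        codes = np.tile([[0, 1]], (60, 30, 1)).astype(np.int16)
        miss = rng.random((60, 30)) < rng.uniform(0, 0.6, size=(1, 30))
        codes[miss] = MISSING
        out = iterative_missingness_filter(make_table(codes))
        assert out.missingness_by_locus().max() <= 0.30
        assert out.missingness_by_individual().max() <= 0.30

    def test_emptied_table_raises_with_level(self):
        codes = np.full((4, 3, 2), MISSING, dtype=np.int16)
        with pytest.raises(TableEmptiedError):
            iterative_missingness_filter(make_table(codes))


class TestDepthCalling:
    def _depths(self, rows, k=3):
        counts = np.array(rows, dtype=np.int64)[:, None, :]
        alleles = {"L1": [chr(65 + a) for a in range(k)]}
        return DepthTable(counts, [f"I{i}" for i in range(len(rows))], ["L1"], alleles)

    def test_ratio_rules_hand_cases(self):
        dt = self._depths([[100, 60, 0], [100, 0, 0], [100, 15, 0], [100, 9, 0], [5, 4, 0], [0, 0, 0]])
        calls, flags = call_from_depths(dt)
        got = [tuple(c) for c in calls.codes[:, 0, :]]
        assert got[0] == (0, 1)  # ratio 0.60 >= 0.20 -> het A/B
        assert got[1] == (0, 0)  # hom A/A
        assert got[2] == (MISSING, MISSING) and flags.ambiguous[2, 0]  # 0.09 < 0.15 < 0.20
        assert got[3] == (0, 0)  # 0.09 boundary inclusive for hom
        assert got[4] == (MISSING, MISSING) and flags.low_depth[4, 0]  # total 9 < 12
        assert got[5] == (MISSING, MISSING)

    def test_minimum_depth_boundary(self):
        dt = self._depths([[12, 0, 0], [11, 0, 0]])
        calls, flags = call_from_depths(dt)
        assert tuple(calls.codes[0, 0]) == (0, 0)
        assert flags.low_depth[1, 0]

    def test_contamination_hand_cases(self):
        dt = self._depths([[100, 60, 3], [100, 60, 40], [100, 60, 0]])
        calls, flags = call_from_depths(dt)
        cleaned, kept = contamination_rule(dt, calls, flags, locus_removal_fraction=0.5)
        assert tuple(cleaned.codes[0, 0]) == (0, 1)  # C masked, het A/B
        assert tuple(cleaned.codes[1, 0]) == (MISSING, MISSING)  # C at 40% -> missing
        assert tuple(cleaned.codes[2, 0]) == (0, 1)  # no third allele: untouched

    def test_contaminated_locus_removed_above_fraction(self):
        rows = [[100, 60, 40]] * 3 + [[100, 60, 0]] * 7
        dt = self._depths(rows)
        calls, flags = call_from_depths(dt)
        _, kept = contamination_rule(dt, calls, flags)  # 30% affected > 5%
        assert kept == []

    def test_ratio_acceptability_thresholds(self):
        rows = [[100, 15, 0]] * 35 + [[100, 60, 0]] * 65  # 65% acceptable < 0.7
        calls, flags = call_from_depths(self._depths(rows))
        kept, frac = locus_ratio_acceptability(flags, ["L1"])
        assert kept == [] and frac["L1"] == pytest.approx(0.65)
        rows = [[100, 15, 0]] * 30 + [[100, 60, 0]] * 70  # exactly 0.7 retained
        calls, flags = call_from_depths(self._depths(rows))
        kept, _ = locus_ratio_acceptability(flags, ["L1"])
        assert kept == ["L1"]


class TestConsistencyAndCascade:
    def test_ninety_three_percent_boundary(self):
        n = 100
        codes = np.zeros((2 * n, 1, 2), dtype=np.int16)
        codes[n : n + 8, 0, :] = (0, 1)  # 92% agreement -> removed
        tab = make_table(codes)
        pairs = [(f"I{i + 1}", f"I{n + i + 1}") for i in range(n)]
        kept, _ = final_consistency_filter(tab, pairs)
        assert kept == []
        codes[n + 7, 0, :] = 0  # 93% agreement -> retained
        tab = make_table(codes)
        kept, _ = final_consistency_filter(tab, pairs)
        assert kept == ["L1"]

    def test_cascade_identity_on_clean_data(self, rookery_clean):
        # with error-free data the cascade may only act through the MAF rule
        # (the ~25 founders can leave panel-rare alleles unsampled)
        b = rookery_clean.bundle
        res = run_qc(b.depths, b.caller_views, b.replicate_pairs)
        maf_keep, _ = maf_filter(b.observed)
        assert res.table.loci == maf_keep
        df = res.report.to_frame()
        assert df.loc[df["rule"] != "maf", "removed"].sum() == 0
        assert res.table.n_individuals == b.observed.n_individuals
        # calls reproduce the truth for every primary individual
        truth = rookery_clean.truth.subset(loci=res.table.loci)
        for s in truth.individuals[:50]:
            np.testing.assert_array_equal(
                res.table.codes[res.table.ind_idx(s)], truth.codes[truth.ind_idx(s)]
            )

    def test_report_rows_reconcile_and_monotone(self, rookery_small):
        b = rookery_small.bundle
        res = run_qc(b.depths, b.caller_views, b.replicate_pairs)
        df = res.report.to_frame()
        assert (df["removed"] + df["retained"] == df["input"]).all()
        locus_rows = df[df["axis"] == "loci"]
        assert (locus_rows["retained"].diff().dropna() <= 0).all() or (
            locus_rows["input"].values[1:] <= locus_rows["retained"].values[:-1]
        ).all()

    def test_filter_report_rejects_impossible_counts(self):
        rep = FilterReport()
        with pytest.raises(ValueError):
            rep.add("bad", 0, 10, 11)
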