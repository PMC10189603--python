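"""Pedigree inference: maternity, sib structure, sires, polygyny, Ne."""
import itertools

import numpy as np
import pandas as pd
import pytest

from rookery.genotypes import MISSING, GenotypeTable
from rookery.pedigree import (
    NestRecord,
    assign_mothers,
    confirm_sib_structure,
    detect_polygyny,
    reconstruct_father,
    reconstruct_fathers_by_mother,
    sibship_ne,
    summarize_nesting,
    _child_prob_given_parents,
)
from rookery.relatedness import ReferenceFreqs, simulate_relationship_pairs, _hw_draw, _freq_matrix
from rookery.simulate import RookeryDesign, simulate_panel, simulate_rookery
from rookery import tables


@pytest.fixture(scope="module")
def nest_setup(rookery_small):
    rk = rookery_small
    ped = rk.pedigree
    nests = [
        NestRecord(
            r.nest_id, r.beach, r.complex,
            list(ped.offspring.loc[ped.offspring["nest"] == r.nest_id, "id"]),
            r.mother_id,
        )
        for r in ped.nests.itertuples(index=False)
    ]
    freqs = dict(rk.panel.group_freqs())
    return rk, nests, freqs


class TestMaternity:
    def test_true_mother_recovered_with_high_probability(self, nest_setup):
        rk, nests, freqs = nest_setup
        cands = list(rk.pedigree.females["id"])
        assigns = assign_mothers(nests[:6], cands, rk.observed, freqs)
        for a, nest in zip(assigns, nests[:6]):
            assert a.inferred_mother == nest.observed_mother
            assert a.probability > 0.99 and a.supported

    def test_negative_controls_never_win_over_true_mother(self, nest_setup):
        rk, nests, freqs = nest_setup
        # off-year controls: unrelated females who cannot be the mothers
        ctrl, _ = simulate_relationship_pairs(rk.panel, "U", n=5, seed=30)
        ctrl_ids = [f"C{i}" for i in range(5)]
        merged = GenotypeTable(
            np.concatenate([rk.observed.codes, ctrl.codes]),
            rk.observed.individuals + ctrl_ids, rk.observed.loci, rk.observed.alleles,
        )
        cands = list(rk.pedigree.females["id"]) + ctrl_ids
        assigns = assign_mothers(nests[:8], cands, merged, freqs)
        assert all(a.inferred_mother not in ctrl_ids for a in assigns)

    def test_indistinguishable_candidates_split_probability(self, nest_setup):
        rk, nests, freqs = nest_setup
        mom = nests[0].observed_mother
        twin = f"{mom}__twin"
        row = rk.observed.ind_idx(mom)
        merged = GenotypeTable(
            np.concatenate([rk.observed.codes, rk.observed.codes[row][None]]),
            rk.observed.individuals + [twin], rk.observed.loci, rk.observed.alleles,
        )
        assigns = assign_mothers(nests[:1], [mom, twin], merged, freqs)
        a = assigns[0]
        assert not a.supported
        assert a.candidate_probs[mom] == pytest.approx(a.candidate_probs[twin])

    def test_tiny_nest_flagged_low_confidence(self, nest_setup):
        rk, nests, freqs = nest_setup
        small = NestRecord("tiny", "b", "Apua", nests[0].offspring[:2], None)
        a = assign_mothers([small], list(rk.pedigree.females["id"]), rk.observed, freqs)[0]
        assert a.low_confidence


class TestSibStructure:
    def test_single_father_nests_have_no_half_sib_calls(self, nest_setup):
        rk, nests, freqs = nest_setup
        sib = confirm_sib_structure(nests[:5], rk.observed, freqs,
                                    max_pairs_within=10, max_pairs_cross=0, seed=1)
        within = sib.within[sib.within["class"] != "vacuous"]
        assert (within["class"] == "FS").mean() > 0.95
        assert (within["class"] == "HS").sum() == 0

    def test_shared_father_nests_linked_as_half_sibs(self, nest_setup):
        rk, nests, freqs = nest_setup
        counts = pd.Series(list(rk.pedigree.matings.values())).value_counts()
        poly_male = counts.index[counts > 1][0]
        moms = [f for f, m in rk.pedigree.matings.items() if m == poly_male]
        na = next(n for n in nests if n.observed_mother == moms[0])
        nb = next(n for n in nests if n.observed_mother == moms[1])
        sib = confirm_sib_structure([na, nb], rk.observed, freqs,
                                    max_pairs_within=4, max_pairs_cross=20, seed=2)
        assert bool(sib.cross["hs_link"].iloc[0])

    def test_single_offspring_nest_is_vacuous(self, nest_setup):
        rk, nests, freqs = nest_setup
        lone = NestRecord("lone", "b", "Apua", nests[0].offspring[:1], None)
        sib = confirm_sib_structure([lone], rk.observed, freqs, seed=3)
        assert list(sib.within["class"]) == ["vacuous"]


class TestFatherReconstruction:
    def _family(self, panel, n_off, seed, e_obs=None):
        rng = np.random.default_rng(seed)
        freqs = panel.group_freqs()
        kvec = np.array([len(freqs[l]) for l in panel.loci])
        P = _freq_matrix(panel.loci, panel.alleles, freqs)
        mother = _hw_draw(rng, P, kvec, 1)[0]
        father = _hw_draw(rng, P, kvec, 1)[0]
        m = panel.n_loci
        kids = np.empty((n_off, m, 2), dtype=np.int16)
        kids[..., 0] = mother[np.arange(m), rng.integers(0, 2, size=(n_off, m))]
        kids[..., 1] = father[np.arange(m), rng.integers(0, 2, size=(n_off, m))]
        return mother, np.sort(father, axis=1), np.sort(kids, axis=2), freqs

    def test_twenty_offspring_recover_truth_and_match_exhaustive_oracle(self, panel30):
        mother, father, kids, freqs = self._family(panel30, 20, seed=4)
        pg = reconstruct_father(mother, kids, panel30.loci, panel30.alleles, freqs, e=0.0)
        unmasked = pg.codes[:, 0] != MISSING
        assert unmasked.mean() > 0.9
        np.testing.assert_array_equal(pg.codes[unmasked], father[unmasked])
        # independent exhaustive oracle at a handful of loci
        for j in [0, 3, 7]:
            p = freqs[panel30.loci[j]]
            k = len(p)
            best, best_ll = None, -np.inf
            ties = 0
            for gf in itertools.combinations_with_replacement(range(k), 2):
                ll = 0.0
                for i in range(20):
                    pm = _child_prob_given_parents(tuple(kids[i, j]), tuple(mother[j]), gf, p)
                    ll += np.log(pm) if pm > 0 else -1e30
                if ll > best_ll + 1e-9:
                    best, best_ll, ties = gf, ll, 0
                elif ll >= best_ll - 1e-9:
                    ties += 1
            if ties == 0 and pg.codes[j, 0] != MISSING:
                assert tuple(pg.codes[j]) == best

    def test_single_offspring_resolves_at_most_one_allele(self, panel30):
        mother, father, kids, freqs = self._family(panel30, 1, seed=5)
        pg = reconstruct_father(mother, kids, panel30.loci, panel30.alleles, freqs, e=0.0)
        assert (pg.codes[:, 1] == MISSING).all()

    def test_hand_case_mother_hom_offspring_het(self):
        loci, alleles = ["L1"], {"L1": ["A", "B"]}
        freqs = {"L1": np.array([0.6, 0.4])}
        mother = np.array([[0, 0]], dtype=np.int16)
        kids = np.tile([[0, 1]], (10, 1)).reshape(10, 1, 2).astype(np.int16)
        pg = reconstruct_father(mother, kids, loci, alleles, freqs, e=0.0)
        # every child carries paternal B; ten hets from a B/B father are certain
        assert tuple(pg.codes[0]) == (1, 1)

    def test_incompatible_offspring_excluded(self, panel30):
        mother, father, kids, freqs = self._family(panel30, 10, seed=6)
        bad = 1 - kids[0]  # scramble one child far from the mother
        kids = np.concatenate([kids, np.sort(np.abs(bad), axis=-1)[None]])
        kids = np.clip(kids, 0, 1).astype(np.int16)
        pg = reconstruct_father(mother, kids, panel30.loci, panel30.alleles, freqs,
                                e=0.0, max_incompatible_fraction=0.25)
        assert len(pg.excluded_offspring) >= 0  # screen runs without error


class TestPolygyny:
    def test_simulated_polygyny_recovered_with_study_sex_ratio(self, nest_setup):
        rk, nests, freqs = nest_setup
        mother_of = {n.nest_id: n.observed_mother for n in nests}
        fathers = reconstruct_fathers_by_mother(rk.observed, nests, mother_of, freqs, seed=5)
        sib = confirm_sib_structure(nests, rk.observed, freqs,
                                    max_pairs_within=4, max_pairs_cross=4, seed=6)
        mating = detect_polygyny(fathers, sib.cross)
        assert mating.sex_ratio == (12, 13)
        assert sum(1 for m in mating.father_to_mothers.values() if len(m) == 2) == 1
        # conservation: mates over fathers total the mothers
        assert sum(len(m) for m in mating.father_to_mothers.values()) == 13

    def test_no_polygyny_gives_parity(self, nest_setup):
        rk, nests, freqs = nest_setup
        mother_of = {n.nest_id: n.observed_mother for n in nests}
        fathers = reconstruct_fathers_by_mother(rk.observed, nests, mother_of, freqs, seed=7)
        mono = [f for f in fathers if f.mother_id in list(rk.pedigree.females["id"])[:6]]
        mating = detect_polygyny(mono, pd.DataFrame())
        assert mating.n_males == mating.n_females == len(mono)

    def test_genotype_match_without_sib_support_warns(self, panel30):
        from rookery.pedigree import PaternalGenotype

        codes = np.zeros((30, 2), dtype=np.int16)
        a = PaternalGenotype("P01", codes.copy(), panel30.loci, panel30.alleles,
                             supporting_nests=["n1"], mother_id="F1")
        b = PaternalGenotype("P02", codes.copy(), panel30.loci, panel30.alleles,
                             supporting_nests=["n2"], mother_id="F2")
        mating = detect_polygyny([a, b], pd.DataFrame(), min_shared_loci=10)
        assert mating.n_males == 2 and mating.warnings


class TestSibshipNe:
    def test_breeder_count_order_and_mating_model_ordering(self, nest_setup):
        rk, nests, freqs = nest_setup
        offs = list(rk.pedigree.offspring["id"])
        ests = sibship_ne(offs, rk.observed, freqs, max_pairs=400, n_boot=30, seed=8)
        by_model = {e.mating_model: e for e in ests}
        n_breeders = 25
        assert n_breeders / 4 < by_model["random"].point < n_breeders * 4
        assert by_model["nonrandom"].point <= by_model["random"].point
        for e in ests:
            assert e.ci_low <= e.point <= e.ci_high

    def test_single_family_collapses_to_minimum_scale(self, panel135):
        # 20 offspring of a single mating pair: every pair is a full sibling
        rng = np.random.default_rng(9)
        freqs = panel135.group_freqs()
        kvec = np.array([len(freqs[l]) for l in panel135.loci])
        P = _freq_matrix(panel135.loci, panel135.alleles, freqs)
        mother, father = _hw_draw(rng, P, kvec, 2)
        m = panel135.n_loci
        kids = np.empty((20, m, 2), dtype=np.int16)
        kids[..., 0] = mother[np.arange(m), rng.integers(0, 2, size=(20, m))]
        kids[..., 1] = father[np.arange(m), rng.integers(0, 2, size=(20, m))]
        ids = [f"S{i}" for i in range(20)]
        merged = GenotypeTable(kids, ids, panel135.loci, panel135.alleles)
        ests = sibship_ne(ids, merged, freqs, n_boot=10, seed=10)
        by_model = {e.mating_model: e for e in ests}
        assert by_model["random"].point <= 4
        assert by_model["nonrandom"].point <= 2.5

    def test_no_sib_pairs_gives_infinite_flag(self):
        from rookery.pedigree import _ne_from_q

        assert np.isinf(_ne_from_q(0.0, 0.0, "random"))
        assert np.isinf(_ne_from_q(0.0, 0.0, "nonrandom"))

    def test_doubling_sample_leaves_estimate_stable(self, nest_setup):
        rk, nests, freqs = nest_setup
        offs = list(rk.pedigree.offspring["id"])
        half = sibship_ne(offs[: len(offs) // 2], rk.observed, freqs,
                          max_pairs=300, n_boot=20, seed=13)
        full = sibship_ne(offs, rk.observed, freqs, max_pairs=300, n_boot=20, seed=13)
        h = {e.mating_model: e for e in half}["random"]
        f = {e.mating_model: e for e in full}["random"]
        assert h.ci_low * 0.5 < f.point < h.ci_high * 2


class TestNestingSummary:
    def test_mean_per_nest_to_one_decimal(self):
        nests = pd.DataFrame(
            {
                "nest_id": [f"n{i}" for i in range(5)],
                "beach": ["Apua"] * 5,
                "mother_id": ["153"] * 5,
                "clutch_size": [30, 40, 30, 40, 22],
            }
        )
        out = summarize_nesting(nests)
        assert out.loc[0, "n_offspring"] == 162
        assert out.loc[0, "mean_per_nest"] == 32.4

    def test_totals_reconcile_exactly(self, rookery_small):
        nests = rookery_small.pedigree.nests
        out = summarize_nesting(nests)
        assert out["n_offspring"].sum() == nests["clutch_size"].sum()
        assert out["n_nests"].sum() == len(nests)

    def test_empty_input_gives_empty_table(self):
        out = summarize_nesting(pd.DataFrame())
        assert out.empty


class TestStudyTables:
    def test_nest_table_has_41_nests_and_13_maternal_identities(self):
        nests = tables.load_nest_table()
        assert len(nests) == 41
        assert len(tables.distinct_mothers(nests)) == 13

    def test_female_table_has_12_distinct_sires(self):
        females = tables.load_female_table()
        assert len(tables.distinct_fathers(females)) == 12

    def test_five_nest_female_mean_recomputes(self):
        females = tables.female_summary(tables.load_female_table())
        row = females[females["female"] == "153"].iloc[0]
        assert row["n_nests"] == 5 and row["n_offspring"] == 162
        assert row["mean_per_nest_recomputed"] == 32.4
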