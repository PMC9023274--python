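import numpy as np
import pytest

from cpbind.evaluation import (
    IntervalSet,
    bsc,
    bsc_curve,
    jaccard,
    normalized_bsc,
    reference_from_coverage,
    shuffle_test,
)
from cpbind.scales import builtin_polar_requirement
from cpbind.synthetic import SyntheticParams, generate_pair

from conftest import random_protein, random_rna


def _iv(*intervals, genome="g"):
    return IntervalSet(genome_id=genome, intervals=tuple(intervals))


class TestIntervalSet:
    def test_sorted_and_overlaps_merged(self):
        ivs = _iv((30, 40), (1, 10), (8, 15))
        assert ivs.intervals == ((1, 15), (30, 40))
        assert ivs.n_positions() == 15 + 11

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            _iv((0, 5))
        with pytest.raises(ValueError):
            _iv((10, 5))

    def test_bounds_check(self):
        with pytest.raises(ValueError):
            _iv((10, 20)).check_within(15)


class TestBsc:
    def test_direct_count(self):
        ref = _iv((10, 19))
        assert bsc({10, 11, 12}, ref, set(range(1, 100))) == pytest.approx(0.3)

    def test_superset_gives_one(self):
        ref = _iv((5, 8))
        assert bsc(set(range(1, 50)), ref, set(range(1, 50))) == 1.0

    def test_restricted_to_defined_positions(self):
        ref = _iv((10, 19))
        defined = set(range(15, 100))  # only 15..19 of the reference is defined
        assert bsc({15, 16}, ref, defined) == pytest.approx(2 / 5)

    def test_reference_outside_defined_rejected(self):
        with pytest.raises(ValueError):
            bsc({1}, _iv((50, 60)), set(range(1, 10)))


class TestNormalizedBsc:
    def test_identical_sets(self):
        assert normalized_bsc(set(range(1, 11)), _iv((1, 10)),
                              set(range(1, 100))) == pytest.approx(0.1)

    def test_doubling_off_target_calls_halves_value(self):
        ref = _iv((1, 10))
        defined = set(range(1, 200))
        v1 = normalized_bsc(set(range(1, 21)), ref, defined)
        v2 = normalized_bsc(set(range(1, 41)), ref, defined)
        assert v2 == pytest.approx(v1 / 2)

    def test_empty_called_rejected(self):
        with pytest.raises(ValueError):
            normalized_bsc(set(), _iv((1, 10)), set(range(1, 100)))


class TestJaccard:
    def test_identical(self):
        assert jaccard(_iv((1, 10)), _iv((1, 10))) == 1.0

    def test_partial_overlap(self):
        assert jaccard(_iv((1, 10)), _iv((6, 15))) == pytest.approx(1 / 3)

    def test_disjoint(self):
        assert jaccard(_iv((1, 10)), _iv((20, 30))) == 0.0

    def test_different_genomes_rejected(self):
        with pytest.raises(ValueError):
            jaccard(_iv((1, 10)), _iv((1, 10), genome="other"))


class TestShuffleTest:
    def test_shuffling_preserves_composition(self):
        from cpbind.evaluation import _shuffled
        rng = np.random.default_rng(0)
        seq = "ACGUACGGUUACG" * 5
        for _ in range(20):
            assert sorted(_shuffled(seq, rng)) == sorted(seq)

    def test_seeded_run_is_bit_reproducible(self, rng, polar):
        case = generate_pair(SyntheticParams(n_sites=1), seed=3)
        kwargs = dict(mode="shuffle_gRNA", profile_kind="pearson", n=25,
                      seed=11, base_set=("C", "U"))
        a = shuffle_test(case.gRNA, case.protein, polar, case.planted, -0.6, **kwargs)
        b = shuffle_test(case.gRNA, case.protein, polar, case.planted, -0.6, **kwargs)
        assert np.array_equal(a.null_bscs, b.null_bscs)
        assert a.p_value == b.p_value
        assert a.p_value == pytest.approx((a.null_bscs >= a.native_bsc).mean())

    def test_unbeatable_native_gives_p_zero(self, polar):
        """With the reference pinned to the core of a noise-free planted
        site, the native prediction covers every reference position while a
        shuffled genome essentially never can."""
        from cpbind.matching import sliding_pearson

        case = generate_pair(SyntheticParams(n_sites=1, noise=0.0), seed=2)
        prof = sliding_pearson(case.gRNA, case.protein, polar, ("C", "U"))
        s, e = case.planted.intervals[0]
        in_site = [p for p in range(s, e + 1)
                   if prof.first_defined <= p <= prof.last_defined]
        pmin = min(in_site, key=prof.at)
        ref = IntervalSet(case.gRNA.id, ((pmin - 10, pmin + 10),))
        res = shuffle_test(case.gRNA, case.protein, polar, ref,
                           cutoff=-0.7, mode="shuffle_gRNA",
                           profile_kind="pearson", n=50, seed=0,
                           base_set=("C", "U"))
        assert res.native_bsc == 1.0
        assert res.p_value == 0.0

    def test_cp_shuffle_mode_runs(self, polar):
        case = generate_pair(SyntheticParams(n_sites=1), seed=4)
        res = shuffle_test(case.gRNA, case.protein, polar, case.planted,
                           cutoff=-0.8, mode="shuffle_CP",
                           profile_kind="pearson", n=20, seed=1,
                           base_set=("C", "U"))
        assert 0 <= res.p_value <= 1
        assert res.mode == "shuffle_CP"

    def test_invalid_mode_rejected(self, polar):
        case = generate_pair(SyntheticParams(n_sites=1), seed=5)
        with pytest.raises(ValueError):
            shuffle_test(case.gRNA, case.protein, polar, case.planted, -0.5,
                         mode="both", base_set=("C", "U"))


class TestBscCurve:
    def test_native_bsc_monotone_in_cutoff(self, polar):
        case = generate_pair(SyntheticParams(n_sites=2), seed=6)
        cutoffs = [-0.9, -0.7, -0.5, -0.3, -0.1]
        curve = bsc_curve(case.gRNA, case.protein, polar, case.planted,
                          cutoffs, profile_kind="pearson", n=10, seed=0,
                          base_set=("C", "U"), modes=("shuffle_gRNA",))
        native = curve["native_bsc"].to_numpy()
        assert (np.diff(native) >= 0).all()
        assert set(curve.columns) >= {"cutoff", "native_bsc",
                                      "median_null_bsc_shuffle_gRNA",
                                      "p_shuffle_gRNA"}

    def test_vacuous_cutoff_gives_p_one_when_all_null_zero(self, polar):
        case = generate_pair(SyntheticParams(n_sites=1), seed=7)
        curve = bsc_curve(case.gRNA, case.protein, polar, case.planted,
                          [-1.01], profile_kind="pearson", n=10, seed=0,
                          base_set=("C", "U"), modes=("shuffle_gRNA",))
        assert curve["native_bsc"].iloc[0] == 0.0
        assert curve["p_shuffle_gRNA"].iloc[0] == 1.0


class TestCoverageReference:
    def test_top_positions_become_intervals(self):
        cov = {p: 0.0 for p in range(1, 101)}
        for p in range(40, 50):
            cov[p] = 10.0
        ref = reference_from_coverage(cov, "g", top_pct=10.0)
        assert ref.intervals == ((40, 49),)

    def test_flank_extension(self):
        cov = {p: 0.0 for p in range(1, 101)}
        cov[50] = 5.0
        ref = reference_from_coverage(cov, "g", top_pct=1.0, flank=2)
        assert ref.intervals == ((48, 52),)
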