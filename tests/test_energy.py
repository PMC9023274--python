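import numpy as np
import pytest

from cpbind.energy import (
    EnergyProfile,
    call_sites_from_energy,
    energy_profile,
    fragment_energy,
    predict_regions,
)
from cpbind.profiles import ProteinSequence, RnaSequence
from cpbind.scales import STANDARD_AA, AffinityScale

from conftest import random_protein, random_rna
from oracles import brute_energy_profile


def _scale(values=0.0, **overrides):
    vals = {aa: float(values) for aa in STANDARD_AA}
    vals.update({k: float(v) for k, v in overrides.items()})
    return AffinityScale("t", vals)


def _fake_profile(smoothed, first=100, z=None):
    smoothed = np.asarray(smoothed, float)
    if z is None:
        sd = smoothed.std(ddof=0)
        z = (smoothed - smoothed.mean()) / sd if sd else np.full_like(smoothed, np.nan)
    return EnergyProfile(genome_id="g", protein_id="p", raw=smoothed,
                         raw_first=first, smoothed=smoothed, z=np.asarray(z, float),
                         first_defined=first, smoothing_window=63, n_aa=10)


class TestFragmentEnergy:
    def test_hand_sum(self):
        scales = {"A": _scale(K=-1.0), "G": _scale(R=-2.0),
                  "C": _scale(), "U": _scale()}
        g = RnaSequence("g", "AAAGGG")
        e = fragment_energy(g, 1, ProteinSequence("p", "KR"), scales)
        assert e == pytest.approx(-9.0)

    def test_all_zero_scales_give_zero(self, rng):
        scales = {b: _scale() for b in "AGCU"}
        g = random_rna(rng, 60)
        assert fragment_energy(g, 4, random_protein(rng, 10), scales) == 0.0

    def test_additive_over_protein_halves(self, rng, toy_base_scales):
        g = random_rna(rng, 120)
        p = random_protein(rng, 20)
        whole = fragment_energy(g, 7, p, toy_base_scales)
        first = fragment_energy(g, 7, ProteinSequence("a", p.residues[:8]),
                                toy_base_scales)
        second = fragment_energy(g, 7 + 24, ProteinSequence("b", p.residues[8:]),
                                 toy_base_scales)
        assert whole == pytest.approx(first + second)

    def test_out_of_range_rejected(self, rng, toy_base_scales):
        g = random_rna(rng, 40)
        with pytest.raises(ValueError):
            fragment_energy(g, 20, random_protein(rng, 10), toy_base_scales)


class TestEnergyProfile:
    @pytest.mark.parametrize("n_aa", [15, 16])
    def test_matches_per_fragment_oracle(self, n_aa, toy_base_scales):
        r = np.random.default_rng(n_aa)
        genome = random_rna(r, 400)
        protein = random_protein(r, n_aa)
        prof = energy_profile(genome, protein, toy_base_scales, smoothing_window=63)
        scales_dict = {b: toy_base_scales[b].values for b in "AGCU"}
        ref = brute_energy_profile(genome.bases, protein.residues, scales_dict, sw=63)
        assert min(ref["smoothed"]) == prof.first_defined
        assert max(ref["smoothed"]) == prof.last_defined
        for pos, v in ref["smoothed"].items():
            assert prof.smoothed[pos - prof.first_defined] == pytest.approx(v, abs=1e-9)
        for pos, v in ref["z"].items():
            assert prof.z_at(pos) == pytest.approx(v, abs=1e-9)

    def test_margins_for_129_aa_protein(self, rng, toy_base_scales):
        genome = random_rna(rng, 3569)
        protein = random_protein(rng, 129)
        prof = energy_profile(genome, protein, toy_base_scales)
        assert prof.first_defined == 225
        assert prof.last_defined == 3569 - 224

    def test_z_is_standardized(self, rng, toy_base_scales):
        prof = energy_profile(random_rna(rng, 1000), random_protein(rng, 30),
                              toy_base_scales)
        assert abs(prof.z.mean()) < 1e-9
        assert abs(prof.z.std(ddof=0) - 1) < 1e-9

    def test_constant_composition_genome_flagged(self, toy_base_scales):
        genome = RnaSequence("g", "ACGU" * 100)  # identical triplet counts frame-wise
        protein = ProteinSequence("p", "A" * 12)
        prof = energy_profile(genome, protein, toy_base_scales)
        assert np.isnan(prof.z).all()
        assert call_sites_from_energy(prof, 0.0) == set()

    def test_fractional_content_rescales_raw_but_not_z(self, rng, toy_base_scales):
        genome = random_rna(rng, 600)
        protein = random_protein(rng, 21)
        counts = energy_profile(genome, protein, toy_base_scales)
        thirds = {b: s.transformed(scale=1 / 3) for b, s in toy_base_scales.items()}
        fracs = energy_profile(genome, protein, thirds)
        assert np.allclose(fracs.raw, counts.raw / 3)
        assert np.allclose(fracs.z, counts.z, atol=1e-9)

    def test_constant_scale_offset_shifts_raw_uniformly_not_z(self, rng, toy_base_scales):
        genome = random_rna(rng, 600)
        protein = random_protein(rng, 21)
        base = energy_profile(genome, protein, toy_base_scales)
        shifted_scales = {b: s.transformed(shift=2.5) for b, s in toy_base_scales.items()}
        shifted = energy_profile(genome, protein, shifted_scales)
        # every triplet has 3 bases, so the offset adds 2.5 * 3 * N_aa everywhere
        assert np.allclose(shifted.raw - base.raw, 2.5 * 3 * 21)
        assert np.allclose(shifted.z, base.z, atol=1e-9)

    def test_even_window_rejected(self, rng, toy_base_scales):
        with pytest.raises(ValueError):
            energy_profile(random_rna(rng, 400), random_protein(rng, 20),
                           toy_base_scales, smoothing_window=62)


class TestPredictRegions:
    def test_single_run(self):
        sm = np.zeros(500)
        sm[200:207] = -10
        regions = predict_regions(_fake_profile(sm, first=100), percentile=1)
        assert regions.intervals == ((300, 306),)

    def test_close_runs_merge(self):
        sm = np.zeros(1000)
        sm[0:11] = -10   # positions 100..110
        sm[15:21] = -10  # positions 115..120, gap of 4 < 10
        regions = predict_regions(_fake_profile(sm, first=100), percentile=1)
        assert regions.intervals == ((100, 120),)

    def test_gap_of_exactly_ten_not_merged(self):
        sm = np.zeros(1000)
        sm[0:11] = -10   # 100..110
        sm[21:27] = -10  # 121..126, gap of 10
        regions = predict_regions(_fake_profile(sm, first=100), percentile=1,
                                  merge_gap=10)
        assert regions.intervals == ((100, 110), (121, 126))
        closer = np.zeros(1000)
        closer[0:11] = -10
        closer[20:26] = -10  # gap of 9 -> merged
        merged = predict_regions(_fake_profile(closer, first=100), percentile=1,
                                 merge_gap=10)
        assert merged.intervals == ((100, 125),)

    def test_min_z_reported_per_region(self):
        sm = np.zeros(500)
        sm[100:110] = [-5, -6, -7, -8, -9, -9, -8, -7, -6, -5]
        prof = _fake_profile(sm)
        regions = predict_regions(prof, percentile=2)
        assert len(regions.min_z) == len(regions.intervals) == 1
        assert regions.min_z[0] == pytest.approx(float(np.nanmin(prof.z)))

    @pytest.mark.parametrize("pct", [0, 100, -3])
    def test_percentile_bounds(self, pct):
        with pytest.raises(ValueError):
            predict_regions(_fake_profile(np.arange(100.0)), percentile=pct)


class TestEnergySiteCalling:
    def test_threshold_scan(self):
        prof = _fake_profile(np.zeros(3), first=300,
                             z=[-1.5, -0.9, -2.0])
        assert call_sites_from_energy(prof, -1.3) == {300, 302}

    def test_cutoff_at_max_calls_everything(self, rng, toy_base_scales):
        prof = energy_profile(random_rna(rng, 500), random_protein(rng, 20),
                              toy_base_scales)
        called = call_sites_from_energy(prof, float(np.max(prof.z)))
        assert called == set(map(int, prof.positions()))

    def test_cutoff_below_minimum_empty(self):
        prof = _fake_profile(np.zeros(3), z=[-1.0, 0.0, 1.0])
        assert call_sites_from_energy(prof, -5.0) == set()
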