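"""Linearly additive gRNA/protein interaction-energy profiles.

The relative interaction energy of a protein placed at a genome offset is
the sum, over all residues, of the per-base affinities of each residue
multiplied by the base counts of the triplet it faces (one amino acid per
three consecutive nucleobases, both chains unstructured).  Energies are in
relative (dimensionless) units and meaningful only for ranking positions
within one genome/protein pair, never as absolute binding free energies.

The per-fragment energy is assigned to the fragment's central nucleotide,
the resulting track is window-averaged (63 nt by default) and standardized
to z-scores over all defined positions; candidate binding regions are the
stretches in the lowest percentile of smoothed energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .profiles import ProteinSequence, RnaSequence
from .scales import AffinityScale

__all__ = [
    "EnergyProfile",
    "PredictionRegions",
    "fragment_energy",
    "energy_profile",
    "predict_regions",
    "call_sites_from_energy",
]

_BASES = "AGCU"


@dataclass(frozen=True)
class EnergyProfile:
    """Raw, smoothed and z-scored relative interaction energies.

    ``raw[k]`` sits at genome position ``raw_first + k``; ``smoothed`` and
    ``z`` share ``first_defined``.  z is standardized (population formula by
    default) over all defined smoothed positions.
    """

    genome_id: str
    protein_id: str
    raw: np.ndarray
    raw_first: int
    smoothed: np.ndarray
    z: np.ndarray
    first_defined: int
    smoothing_window: int
    n_aa: int

    @property
    def last_defined(self) -> int:
        return self.first_defined + len(self.smoothed) - 1

    def positions(self) -> np.ndarray:
        return np.arange(self.first_defined, self.last_defined + 1)

    def defined_positions(self) -> np.ndarray:
        return self.positions()[np.isfinite(self.z)]

    def z_at(self, position: int) -> float:
        if self.first_defined <= position <= self.last_defined:
            return float(self.z[position - self.first_defined])
        return float("nan")


def _affinity_matrix(protein: ProteinSequence,
                     scales: Mapping[str, AffinityScale]) -> np.ndarray:
    """(N_aa, 4) matrix of per-residue affinities for A, G, C, U."""
    missing = [b for b in _BASES if b not in {k.upper() for k in scales}]
    if missing:
        raise ValueError(f"missing per-base affinity scales for: {missing}")
    lookup = {k.upper(): v for k, v in scales.items()}
    return np.column_stack([lookup[b].vector(protein.residues) for b in _BASES])


def fragment_energy(gRNA: RnaSequence, start: int, protein: ProteinSequence,
                    scales: Mapping[str, AffinityScale]) -> float:
    """Interaction energy of the protein aligned at 1-based genome ``start``.

    Residue ``j`` faces the triplet at ``start + 3*(j-1)``; the energy adds
    ``affinity_b(aa_j) * count_b(triplet_j)`` over the four bases, with
    integer base counts 0-3.
    """
    n = len(protein)
    if start < 1 or start + 3 * n - 1 > len(gRNA):
        raise ValueError(
            f"fragment [{start}, {start + 3 * n - 1}] outside genome of length {len(gRNA)}"
        )
    aff = _affinity_matrix(protein, scales)
    total = 0.0
    for j in range(n):
        triplet = gRNA.bases[start - 1 + 3 * j: start + 2 + 3 * j]
        for bi, b in enumerate(_BASES):
            total += aff[j, bi] * triplet.count(b)
    return total


def _fragment_energies(gRNA: RnaSequence, protein: ProteinSequence,
                       scales: Mapping[str, AffinityScale]) -> np.ndarray:
    """Vectorized per-start fragment energies via per-base cross-correlation."""
    aff = _affinity_matrix(protein, scales)
    kernel = np.repeat(aff, 3, axis=0)  # nucleotide m faces residue m // 3
    codes = np.frombuffer(gRNA.bases.encode(), dtype=np.uint8)
    span = kernel.shape[0]
    if len(codes) < span:
        raise ValueError(
            f"genome of length {len(codes)} too short for a {span}-nt fragment"
        )
    total = np.zeros(len(codes) - span + 1)
    for bi, b in enumerate(_BASES):
        onehot = (codes == ord(b)).astype(float)
        total += np.correlate(onehot, kernel[:, bi], mode="valid")
    return total


def energy_profile(gRNA: RnaSequence, protein: ProteinSequence,
                   scales: Mapping[str, AffinityScale],
                   smoothing_window: int = 63,
                   drop_initial_met: bool = False,
                   population_sd: bool = True) -> EnergyProfile:
    """Relative interaction-energy profile of a protein along a genome.

    Fragment energies are assigned to fragment centres (with the i +/- 0.5
    averaging rule for even protein lengths), boxcar-averaged over
    ``smoothing_window`` nucleotides and z-scored over the defined range.
    The undefined margins are (3*N_aa - 1)/2 + (sw - 1)/2 positions on each
    side for odd N_aa and 3*N_aa/2 + (sw - 1)/2 for even N_aa.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError(f"smoothing window must be odd, got {smoothing_window}")
    if drop_initial_met:
        protein = protein.without_initial_met()
    n = len(protein)
    frag = _fragment_energies(gRNA, protein, scales)
    span = 3 * n
    if span % 2 == 1:  # odd N_aa
        raw = frag
        raw_first = 1 + (span - 1) // 2
    else:
        if len(frag) < 2:
            raise ValueError("genome too short for even-length centre averaging")
        raw = 0.5 * (frag[:-1] + frag[1:])
        raw_first = 1 + span // 2
    half = (smoothing_window - 1) // 2
    if len(raw) < smoothing_window:
        raise ValueError(
            f"only {len(raw)} raw energies; cannot smooth with window {smoothing_window}"
        )
    if smoothing_window == 1:
        smoothed = raw.copy()
    else:
        kernel = np.full(smoothing_window, 1.0 / smoothing_window)
        smoothed = np.convolve(raw, kernel, mode="valid")
    first_defined = raw_first + half
    sd = smoothed.std(ddof=0 if population_sd else 1)
    if sd > 0 and np.ptp(smoothed) > 0:
        z = (smoothed - smoothed.mean()) / sd
    else:  # exactly constant profile: z is undefined, flagged not poisoned
        z = np.full_like(smoothed, np.nan)
    return EnergyProfile(
        genome_id=gRNA.id, protein_id=protein.id, raw=raw, raw_first=raw_first,
        smoothed=smoothed, z=z, first_defined=first_defined,
        smoothing_window=smoothing_window, n_aa=n,
    )


@dataclass(frozen=True)
class PredictionRegions:
    """Lowest-percentile energy regions (1-based inclusive intervals)."""

    genome_id: str
    protein_id: str
    percentile: float
    threshold: float
    intervals: tuple[tuple[int, int], ...]
    min_z: tuple[float, ...]

    def __iter__(self):
        return iter(self.intervals)

    def positions(self) -> set[int]:
        return {p for s, e in self.intervals for p in range(s, e + 1)}


def _merge_runs(positions: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of positions, then merge intervals < merge_gap apart."""
    if len(positions) == 0:
        return []
    breaks = np.where(np.diff(positions) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(positions) - 1]])
    runs = [(int(positions[s]), int(positions[e])) for s, e in zip(starts, ends)]
    merged = [runs[0]]
    for s, e in runs[1:]:
        gap = s - merged[-1][1] - 1  # positions strictly between
        if gap < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def predict_regions(profile: EnergyProfile, percentile: float = 1.0,
                    merge_gap: int = 10) -> PredictionRegions:
    """Regions in the lowest ``percentile`` % of smoothed interaction energy.

    The threshold is the linearly interpolated percentile of all defined
    smoothed values; positions at or below it form maximal runs, and runs
    separated by fewer than ``merge_gap`` intervening nucleotides are merged
    (a gap of exactly ``merge_gap`` is kept separate).
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    finite = np.isfinite(profile.smoothed)
    if not finite.any():
        raise ValueError("energy profile has no defined values")
    threshold = float(np.percentile(profile.smoothed[finite], percentile))
    mask = finite & (profile.smoothed <= threshold)
    intervals = _merge_runs(profile.positions()[mask], merge_gap)
    min_z = []
    for s, e in intervals:
        zslice = profile.z[s - profile.first_defined: e - profile.first_defined + 1]
        min_z.append(float(np.nanmin(zslice)) if np.isfinite(zslice).any() else float("nan"))
    return PredictionRegions(
        genome_id=profile.genome_id, protein_id=profile.protein_id,
        percentile=percentile, threshold=threshold,
        intervals=tuple(intervals), min_z=tuple(min_z),
    )


def call_sites_from_energy(profile: EnergyProfile, z_cutoff: float) -> set[int]:
    """Genome positions with z-scored smoothed energy <= cutoff."""
    mask = np.isfinite(profile.z) & (profile.z <= z_cutoff)
    return set(map(int, profile.positions()[mask]))
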