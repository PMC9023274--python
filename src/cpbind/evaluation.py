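"""Comparison of predicted sites with reference binding intervals.

Binding-site coverage (BSC) is the fraction of reference-binding-site
nucleotides recovered by a prediction, restricted to genome positions that
actually carry a predicted value; significance is assessed against
composition-preserving shuffles of either the genome or the protein, with
the permutation p-value defined as the fraction of shuffles reaching a BSC
greater than or equal to the native one (no pseudocount, so p = 0 is
reportable at finite shuffle counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .energy import call_sites_from_energy, energy_profile
from .matching import call_sites_from_match, sliding_pearson
from .profiles import ProteinSequence, RnaSequence
from .scales import AffinityScale

__all__ = [
    "IntervalSet",
    "PermutationResult",
    "bsc",
    "normalized_bsc",
    "jaccard",
    "shuffle_test",
    "bsc_curve",
    "reference_from_coverage",
]


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, overlap-free 1-based inclusive intervals on one genome."""

    genome_id: str
    intervals: tuple[tuple[int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        norm: list[tuple[int, int]] = []
        for s, e in sorted((int(s), int(e)) for s, e in self.intervals):
            if s < 1 or e < s:
                raise ValueError(f"invalid interval ({s}, {e})")
            if norm and s <= norm[-1][1]:  # overlap: merge
                norm[-1] = (norm[-1][0], max(norm[-1][1], e))
            else:
                norm.append((s, e))
        object.__setattr__(self, "intervals", tuple(norm))

    def __len__(self) -> int:
        return len(self.intervals)

    def positions(self) -> set[int]:
        return {p for s, e in self.intervals for p in range(s, e + 1)}

    def n_positions(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def check_within(self, genome_length: int) -> "IntervalSet":
        for s, e in self.intervals:
            if e > genome_length:
                raise ValueError(
                    f"interval ({s}, {e}) beyond genome of length {genome_length}"
                )
        return self


def bsc(called_positions: Iterable[int], reference: IntervalSet,
        defined_positions: Iterable[int]) -> float:
    """Binding-site coverage: |called ∩ reference ∩ defined| / |reference ∩ defined|."""
    called = set(called_positions)
    defined = set(defined_positions)
    ref_def = reference.positions() & defined
    if not ref_def:
        raise ValueError("reference lies entirely outside the defined profile range")
    return len(called & ref_def) / len(ref_def)


def normalized_bsc(called_positions: Iterable[int], reference: IntervalSet,
                   defined_positions: Iterable[int]) -> float:
    """BSC divided by the number of called (defined) positions.

    Puts shuffles with different called-set sizes on a common footing: the
    quantity rewards calls in the right places, not sheer call volume.
    """
    called = set(called_positions)
    defined = set(defined_positions)
    denom = len(called & defined)
    if denom == 0:
        raise ValueError("called set is empty within the defined range")
    return bsc(called, reference, defined) / denom


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Intersection-over-union of the positions covered by two interval sets."""
    if a.genome_id != b.genome_id:
        raise ValueError(f"interval sets on different genomes: {a.genome_id!r} vs {b.genome_id!r}")
    pa, pb = a.positions(), b.positions()
    union = pa | pb
    if not union:
        raise ValueError("both interval sets are empty")
    return len(pa & pb) / len(union)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a shuffled-sequence BSC significance test."""

    native_bsc: float
    null_bscs: np.ndarray
    p_value: float
    n_shuffles: int
    mode: str
    seed: int | None
    cutoff: float

    def summary(self) -> dict:
        return {
            "native_bsc": self.native_bsc,
            "p_value": self.p_value,
            "median_null_bsc": float(np.median(self.null_bscs)),
            "n_shuffles": self.n_shuffles,
            "mode": self.mode,
            "seed": self.seed,
            "cutoff": self.cutoff,
        }


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode()


class _ProfileRunner:
    """Recomputes a full profile and called set for (possibly shuffled) inputs."""

    def __init__(self, profile_kind: str, scale_or_scales, base_set,
                 w: int, energy_window: int, drop_initial_met: bool):
        if profile_kind not in ("pearson", "energy"):
            raise ValueError(f"profile_kind must be 'pearson' or 'energy', got {profile_kind!r}")
        self.kind = profile_kind
        self.scales = scale_or_scales
        self.base_set = base_set
        self.w = w
        self.energy_window = energy_window
        self.drop_initial_met = drop_initial_met
        if profile_kind == "pearson" and base_set is None:
            raise ValueError("base_set is required for Pearson profiles")

    def profile(self, gRNA: RnaSequence, protein: ProteinSequence):
        if self.kind == "pearson":
            return sliding_pearson(gRNA, protein, self.scales, self.base_set,
                                   w=self.w, drop_initial_met=self.drop_initial_met)
        return energy_profile(gRNA, protein, self.scales,
                              smoothing_window=self.energy_window,
                              drop_initial_met=self.drop_initial_met)

    def values_and_positions(self, profile):
        if self.kind == "pearson":
            vals = profile.values
            direction = profile.direction
        else:
            vals = profile.z
            direction = "min"
        return vals, profile.first_defined, direction

    def called(self, profile, cutoff: float) -> set[int]:
        if self.kind == "pearson":
            return call_sites_from_match(profile, cutoff)
        return call_sites_from_energy(profile, cutoff)


def _bsc_fast(vals: np.ndarray, first: int, direction: str, cutoff: float,
              ref_mask: np.ndarray, n_ref_def: int) -> float:
    """BSC from a value array without building Python sets.

    ``ref_mask`` is a genome-length boolean array of reference positions;
    ``n_ref_def`` the count of reference positions inside the defined range.
    """
    window = ref_mask[first - 1: first - 1 + len(vals)]
    if direction == "min":
        hit = vals <= cutoff
    else:
        hit = vals >= cutoff
    hit &= np.isfinite(vals)
    return int((hit & window).sum()) / n_ref_def


def shuffle_test(gRNA: RnaSequence, protein: ProteinSequence, scale_or_scales,
                 reference: IntervalSet, cutoff: float,
                 mode: str = "shuffle_gRNA", profile_kind: str = "pearson",
                 n: int = 1000, seed: int | None = None,
                 base_set: Iterable[str] | None = None, w: int = 21,
                 energy_window: int = 63,
                 drop_initial_met: bool = False) -> PermutationResult:
    """Permutation significance of the native BSC at one cutoff.

    Either the genome (``mode="shuffle_gRNA"``) or the protein
    (``mode="shuffle_CP"``) is re-ordered uniformly at random ``n`` times
    without changing its composition; the full profile is recomputed for
    every replicate and the p-value is the fraction of replicates whose BSC
    is >= the native one.
    """
    if mode not in ("shuffle_gRNA", "shuffle_CP"):
        raise ValueError(f"mode must be 'shuffle_gRNA' or 'shuffle_CP', got {mode!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    runner = _ProfileRunner(profile_kind, scale_or_scales, base_set, w,
                            energy_window, drop_initial_met)
    native = runner.profile(gRNA, protein)
    vals, first, direction = runner.values_and_positions(native)
    reference.check_within(len(gRNA))
    ref_mask = np.zeros(len(gRNA), dtype=bool)
    for s, e in reference.intervals:
        ref_mask[s - 1: e] = True
    defined_mask = np.zeros(len(gRNA), dtype=bool)
    pos_idx = np.arange(first - 1, first - 1 + len(vals))
    defined_mask[pos_idx[np.isfinite(vals)]] = True
    n_ref_def = int((ref_mask & defined_mask).sum())
    if n_ref_def == 0:
        raise ValueError("reference lies entirely outside the defined profile range")
    native_bsc = _bsc_fast(vals, first, direction, cutoff, ref_mask, n_ref_def)

    rng = np.random.default_rng(seed)
    null = np.empty(n)
    for i in range(n):
        if mode == "shuffle_gRNA":
            g = RnaSequence(gRNA.id, _shuffled(gRNA.bases, rng))
            p = protein
        else:
            g = gRNA
            residues = protein.residues
            if drop_initial_met:
                # shuffle the mature sequence the profile actually uses,
                # keeping the dropped initiator in front
                p = ProteinSequence(protein.id, "M" + _shuffled(residues[1:], rng))
            else:
                p = ProteinSequence(protein.id, _shuffled(residues, rng))
        prof = runner.profile(g, p)
        v, f, d = runner.values_and_positions(prof)
        null[i] = _bsc_fast(v, f, d, cutoff, ref_mask, n_ref_def)
    p_value = float((null >= native_bsc).sum()) / n
    return PermutationResult(
        native_bsc=native_bsc, null_bscs=null, p_value=p_value,
        n_shuffles=n, mode=mode, seed=seed, cutoff=cutoff,
    )


def bsc_curve(gRNA: RnaSequence, protein: ProteinSequence, scale_or_scales,
              reference: IntervalSet, cutoffs: Sequence[float],
              profile_kind: str = "pearson", modes: Sequence[str] = ("shuffle_gRNA", "shuffle_CP"),
              n: int = 1000, seed: int | None = None,
              base_set: Iterable[str] | None = None, w: int = 21,
              energy_window: int = 63, drop_initial_met: bool = False,
              independent_nulls: bool = False) -> pd.DataFrame:
    """Native BSC, median null BSC and p-value per cutoff.

    By default one seeded shuffle set per mode is reused across all cutoffs,
    so the curve is internally coherent; ``independent_nulls`` redraws the
    shuffles for every cutoff instead.
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoffs must be nonempty")
    runner = _ProfileRunner(profile_kind, scale_or_scales, base_set, w,
                            energy_window, drop_initial_met)
    native = runner.profile(gRNA, protein)
    vals, first, direction = runner.values_and_positions(native)
    reference.check_within(len(gRNA))
    ref_mask = np.zeros(len(gRNA), dtype=bool)
    for s, e in reference.intervals:
        ref_mask[s - 1: e] = True
    defined_mask = np.zeros(len(gRNA), dtype=bool)
    pos_idx = np.arange(first - 1, first - 1 + len(vals))
    defined_mask[pos_idx[np.isfinite(vals)]] = True
    n_ref_def = int((ref_mask & defined_mask).sum())
    if n_ref_def == 0:
        raise ValueError("reference lies entirely outside the defined profile range")

    cutoffs = list(cutoffs)
    native_bscs = [_bsc_fast(vals, first, direction, c, ref_mask, n_ref_def)
                   for c in cutoffs]
    rows = {"cutoff": cutoffs, "native_bsc": native_bscs}
    rng = np.random.default_rng(seed)

    def _null_block(mode: str, block_cutoffs: Sequence[float]) -> np.ndarray:
        null = np.empty((n, len(block_cutoffs)))
        for i in range(n):
            if mode == "shuffle_gRNA":
                g = RnaSequence(gRNA.id, _shuffled(gRNA.bases, rng))
                p = protein
            else:
                g = gRNA
                if drop_initial_met:
                    p = ProteinSequence(protein.id,
                                        "M" + _shuffled(protein.residues[1:], rng))
                else:
                    p = ProteinSequence(protein.id, _shuffled(protein.residues, rng))
            prof = runner.profile(g, p)
            v, f, d = runner.values_and_positions(prof)
            for ci, c in enumerate(block_cutoffs):
                null[i, ci] = _bsc_fast(v, f, d, c, ref_mask, n_ref_def)
        return null

    for mode in modes:
        if independent_nulls:
            null = np.hstack([_null_block(mode, [c]) for c in cutoffs])
        else:
            null = _null_block(mode, cutoffs)
        rows[f"median_null_bsc_{mode}"] = np.median(null, axis=0)
        rows[f"p_{mode}"] = (null >= np.asarray(native_bscs)).sum(axis=0) / n
    return pd.DataFrame(rows)


def reference_from_coverage(coverage: "pd.Series | Mapping[int, float]",
                            genome_id: str, top_pct: float = 10.0,
                            flank: int = 0, merge_gap: int = 1,
                            label: str = "coverage") -> IntervalSet:
    """Build a reference interval set from per-position read coverage.

    Positions in the top ``top_pct`` percent of coverage are taken as
    binding evidence (ties at the threshold included), optionally extended
    by ``flank`` nucleotides on each side, and runs closer than
    ``merge_gap`` are merged.  This mirrors how crosslinking read-coverage
    tracks are converted to binding-site references when the original
    authors provide none.
    """
    if not 0 < top_pct < 100:
        raise ValueError(f"top_pct must be in (0, 100), got {top_pct}")
    series = pd.Series(dict(coverage)) if not isinstance(coverage, pd.Series) else coverage
    threshold = float(np.percentile(series.values, 100 - top_pct))
    top = np.sort(series.index[series.values >= threshold].astype(int))
    if flank:
        top = np.unique(np.concatenate(
            [top + d for d in range(-flank, flank + 1)]))
        top = top[top >= 1]
    from .energy import _merge_runs
    intervals = _merge_runs(top, merge_gap)
    return IntervalSet(genome_id=genome_id, intervals=tuple(intervals), label=label)
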