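"""Sliding Pearson comparison of protein affinity vs gRNA density profiles.

The smoothed affinity profile of a protein (length ``l`` values) is slid
along the genome in steps of one nucleotide; at each offset it is compared,
via Pearson R, against the ``l`` smoothed density values of the in-frame
triplets it would pair with (one residue per triplet).  R is assigned to the
central nucleotide of the 3*l-nucleotide stretch spanned by those triplets;
for even ``l`` the two straddling half-integer centres are averaged onto the
integer position between them.  Matched (complementary) profiles give
negative R for ``direction="min"`` scales and positive R for adenine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .profiles import (
    PositionProfile,
    ProteinSequence,
    RnaSequence,
    affinity_profile,
    density_profile,
)
from .scales import AffinityScale, require_scales

__all__ = [
    "MatchProfile",
    "sliding_pearson",
    "combined_knowledge_profile",
    "call_sites_from_match",
    "KNOWLEDGE_BASE_SETS",
]

#: Base set probed by each knowledge-based per-base scale.
KNOWLEDGE_BASE_SETS = {"ADE": "A", "GUA": "G", "CYT": "C", "URA": "U"}

# sum-of-squares below which a comparison window counts as zero-variance
_VARIANCE_FLOOR = 1e-20


@dataclass(frozen=True)
class MatchProfile:
    """Per-nucleotide Pearson R between a protein and a genome.

    ``values[k]`` is the R at genome position ``first_defined + k``
    (1-based); NaN marks positions whose comparison window had zero
    variance and is excluded from site calling and statistics.
    """

    genome_id: str
    protein_id: str
    scale_name: str
    direction: str
    values: np.ndarray
    first_defined: int
    w: int
    l: int

    @property
    def last_defined(self) -> int:
        return self.first_defined + len(self.values) - 1

    def positions(self) -> np.ndarray:
        return np.arange(self.first_defined, self.last_defined + 1)

    def defined_positions(self) -> np.ndarray:
        """Genome positions carrying a finite R."""
        return self.positions()[np.isfinite(self.values)]

    def at(self, position: int) -> float:
        if self.first_defined <= position <= self.last_defined:
            return float(self.values[position - self.first_defined])
        return float("nan")


def _pearson_vs_fixed(windows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson R of each row of ``windows`` against the fixed vector ``y``."""
    yc = y - y.mean()
    syy = float(yc @ yc)
    xm = windows.mean(axis=1, keepdims=True)
    xc = windows - xm
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxy = xc @ yc
    # Constant windows are undefined.  Smoothed tracks are quantized (means
    # of 1/3-step densities or tabulated scale values), so any genuinely
    # non-constant window has a sum of squares many orders of magnitude
    # above the ulp-level noise left by mean subtraction; 1e-20 separates
    # the two regimes cleanly.
    bad = (sxx < _VARIANCE_FLOOR) | (syy < _VARIANCE_FLOOR)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    r[bad] = np.nan
    return r


def _fragment_pearsons(density: PositionProfile, y: np.ndarray) -> np.ndarray:
    """R for every fragment start, indexed by inner-triplet offset.

    Entry ``t`` compares ``y`` with the smoothed density values at triplet
    positions ``density.first_defined + t + 3k``, k = 0..l-1.
    """
    l = len(y)
    sv = density.values
    n_frag = len(sv) - 3 * (l - 1)
    if n_frag < 1:
        raise ValueError(
            f"genome too short: {len(sv)} smoothed triplet values cannot host "
            f"an l={l} fragment"
        )
    # Center the density track once; Pearson is shift-invariant and this
    # keeps the running sums well conditioned.
    sv = sv - sv.mean()
    out = np.empty(n_frag)
    for f in range(3):
        sub = sv[f::3]
        if len(sub) < l:
            continue
        wins = sliding_window_view(sub, l)
        r = _pearson_vs_fixed(wins, y)
        # window j in frame f is fragment offset t = f + 3j
        t = f + 3 * np.arange(len(r))
        keep = t < n_frag
        out[t[keep]] = r[keep]
    return out


def _centered_values(r_frag: np.ndarray, inner_first: int, l: int) -> tuple[np.ndarray, int]:
    """Assign fragment Rs to central nucleotides; returns (values, first_defined)."""
    span = 3 * l
    if span % 2 == 1:  # odd l: integer centre
        return r_frag, inner_first + (span - 1) // 2
    # even l: integer position i averages the fragments centred at i -/+ 0.5
    if len(r_frag) < 2:
        raise ValueError("genome too short for even-length centre averaging")
    vals = 0.5 * (r_frag[:-1] + r_frag[1:])
    return vals, inner_first + span // 2


def sliding_pearson(gRNA: RnaSequence, protein: ProteinSequence,
                    scale: AffinityScale, base_set: Iterable[str],
                    w: int = 21, drop_initial_met: bool = False) -> MatchProfile:
    """Slide a protein affinity profile along a genome density profile.

    Parameters mirror the field's defaults: 21-unit smoothing for both
    profiles, one amino acid facing three consecutive nucleotides.  Zero
    variance in either window yields NaN at that position rather than an
    error.
    """
    prot = affinity_profile(protein, scale, w=w, drop_initial_met=drop_initial_met)
    dens = density_profile(gRNA, base_set, w=w)
    y = prot.values
    r_frag = _fragment_pearsons(dens, y)
    values, first = _centered_values(r_frag, dens.first_defined, len(y))
    return MatchProfile(
        genome_id=gRNA.id, protein_id=protein.id, scale_name=scale.name,
        direction=scale.direction, values=values, first_defined=first,
        w=w, l=len(y),
    )


def combined_knowledge_profile(gRNA: RnaSequence, protein: ProteinSequence,
                               scales: Mapping[str, AffinityScale],
                               w: int = 21,
                               drop_initial_met: bool = False) -> MatchProfile:
    """Summed four-scale profile: R_GUA + R_CYT + R_URA - R_ADE.

    Each per-base R is computed against the density of that scale's own
    base; the adenine term enters with a minus sign because ADE matching is
    anti-correlated.  Defined exactly where all four constituents are.
    """
    four = require_scales(scales, KNOWLEDGE_BASE_SETS)
    parts = {}
    for name, base in KNOWLEDGE_BASE_SETS.items():
        parts[name] = sliding_pearson(
            gRNA, protein, four[name], base, w=w, drop_initial_met=drop_initial_met
        )
    ref = parts["GUA"]
    combined = (
        parts["GUA"].values + parts["CYT"].values + parts["URA"].values
        - parts["ADE"].values
    )
    return MatchProfile(
        genome_id=gRNA.id, protein_id=protein.id, scale_name="KB4",
        direction="min", values=combined, first_defined=ref.first_defined,
        w=w, l=ref.l,
    )


def call_sites_from_match(profile: MatchProfile, cutoff: float,
                          direction: str | None = None) -> set[int]:
    """Genome positions whose R passes the cutoff.

    ``direction="min"`` calls R <= cutoff (the default convention);
    ``direction="max"`` calls R >= cutoff (adenine).  Undefined (NaN)
    positions are never called.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    direction = direction or profile.direction
    if direction == "min":
        mask = profile.values <= cutoff
    elif direction == "max":
        mask = profile.values >= cutoff
    else:
        raise ValueError(f"direction must be 'min' or 'max', got {direction!r}")
    mask &= np.isfinite(profile.values)
    return set(map(int, profile.positions()[mask]))
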