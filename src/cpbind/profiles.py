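"""Per-position sequence profiles.

Two kinds of smoothed tracks underlie every prediction the package makes:

* **nucleobase-density profiles** over a genomic RNA — for each triplet
  (three consecutive nucleotides) the fraction of its bases belonging to a
  chosen base set, smoothed over ``w`` in-frame triplets (stride 3);
* **nucleobase-affinity profiles** over a protein — per-residue values of an
  :class:`~cpbind.scales.AffinityScale`, smoothed over ``w`` residues.

Smoothing maps the window mean onto the central unit, so the first and last
``(w-1)/2`` units (times the stride, in nucleotide coordinates) carry no
value; all downstream margin bookkeeping follows from that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .scales import AffinityScale

__all__ = [
    "RNA_ALPHABET",
    "PROTEIN_ALPHABET",
    "SequenceError",
    "RnaSequence",
    "ProteinSequence",
    "PositionProfile",
    "normalize_sequence",
    "triplet_density",
    "smooth_strided",
    "affinity_profile",
]

RNA_ALPHABET = frozenset("ACGU")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for empty, ambiguous or otherwise invalid sequences."""


def normalize_sequence(raw: str, alphabet: str) -> str:
    """Uppercase and validate a raw sequence string.

    ``alphabet="rna"`` maps T to U (DNA input is accepted); any character
    outside the strict alphabet — including ambiguity codes such as N, B, Z
    or X — raises :class:`SequenceError` naming the first offending position
    (1-based).  Ambiguous records are meant to be dropped, not repaired.
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper()
    if alphabet == "rna":
        seq = seq.replace("T", "U")
        allowed = RNA_ALPHABET
    elif alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    else:
        raise ValueError(f"alphabet must be 'rna' or 'protein', got {alphabet!r}")
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise SequenceError(
                f"invalid {alphabet} character {ch!r} at position {i}"
            )
    return seq


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence (A/C/G/U), 1-based position convention."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", normalize_sequence(self.bases, "rna"))
        if len(self.bases) < 3:
            raise SequenceError(f"{self.id}: RNA shorter than one triplet")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence over the 20 standard residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_sequence(self.residues, "protein"))

    def __len__(self) -> int:
        return len(self.residues)

    def without_initial_met(self) -> "ProteinSequence":
        """Drop the initiator methionine (mature-protein convention)."""
        if not self.residues.startswith("M"):
            raise SequenceError(f"{self.id}: no N-terminal methionine to drop")
        return ProteinSequence(self.id, self.residues[1:])


@dataclass(frozen=True)
class PositionProfile:
    """A smoothed per-position track with explicit undefined margins.

    ``values[k]`` is the smoothed value at raw-track position
    ``first_defined + k`` (1-based).  For genomic triplet tracks, positions
    index the triplet's first nucleotide; for proteins, the residue.
    """

    sequence_id: str
    values: np.ndarray
    first_defined: int
    w: int
    stride: int = 1

    @property
    def last_defined(self) -> int:
        return self.first_defined + len(self.values) - 1

    def at(self, position: int) -> float:
        """Value at a 1-based position; NaN outside the defined range."""
        if self.first_defined <= position <= self.last_defined:
            return float(self.values[position - self.first_defined])
        return float("nan")

    def positions(self) -> np.ndarray:
        return np.arange(self.first_defined, self.last_defined + 1)


def triplet_density(seq: RnaSequence, base_set: Iterable[str]) -> np.ndarray:
    """Fraction of bases from ``base_set`` in each triplet of the genome.

    Returns a raw track of length ``L - 2``; entry ``i`` (0-based here,
    1-based in profile coordinates) covers nucleotides ``i+1 .. i+3`` and
    takes values in {0, 1/3, 2/3, 1}.
    """
    bases = {b.upper().replace("T", "U") for b in base_set}
    if not bases:
        raise ValueError("base_set must be nonempty")
    if not bases <= RNA_ALPHABET:
        raise ValueError(f"base_set outside A/C/G/U: {sorted(bases - RNA_ALPHABET)}")
    member = np.frombuffer(seq.bases.encode(), dtype=np.uint8)
    mask = np.isin(member, np.frombuffer("".join(sorted(bases)).encode(), dtype=np.uint8))
    counts = mask[:-2].astype(np.int16) + mask[1:-1] + mask[2:]
    return counts / 3.0


def smooth_strided(track: np.ndarray, w: int, stride: int = 1,
                   sequence_id: str = "") -> PositionProfile:
    """Window-average a raw track with window ``w`` units spaced ``stride`` apart.

    The smoothed value at position ``i`` is the mean of the raw values at
    ``i - stride*(w-1)/2, ..., i, ..., i + stride*(w-1)/2`` and is defined
    wherever the full window fits.  ``stride=1`` is plain boxcar smoothing
    (proteins, energy profiles); ``stride=3`` averages in-frame triplets
    (genomic density profiles).
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {w}")
    if stride < 1:
        raise ValueError(f"stride must be positive, got {stride}")
    track = np.asarray(track, dtype=float)
    span = (w - 1) * stride + 1
    if track.ndim != 1 or len(track) < span:
        raise ValueError(
            f"track of length {len(track)} too short for window span {span}"
        )
    if w == 1:
        values = track.copy()
    else:
        values = sliding_window_view(track, span)[:, ::stride].mean(axis=1)
    half = (w - 1) // 2
    return PositionProfile(
        sequence_id=sequence_id, values=values,
        first_defined=1 + half * stride, w=w, stride=stride,
    )


def density_profile(seq: RnaSequence, base_set: Iterable[str],
                    w: int = 21) -> PositionProfile:
    """Smoothed nucleobase-density profile of a genome (stride-3 smoothing).

    The value at nucleotide ``i`` averages ``w`` in-frame, non-overlapping
    triplets centred on the triplet starting at ``i``; the first and last
    ``3*(w-1)/2`` nucleotides of the triplet track are undefined.
    """
    return smooth_strided(triplet_density(seq, base_set), w, stride=3,
                          sequence_id=seq.id)


def affinity_profile(protein: ProteinSequence, scale: AffinityScale,
                     w: int = 21, drop_initial_met: bool = False) -> PositionProfile:
    """Smoothed nucleobase-affinity profile of a protein.

    With ``drop_initial_met`` the initiator methionine is removed first
    (positions then refer to the mature protein), mirroring how mature coat
    proteins lack the start residue.
    """
    if drop_initial_met:
        protein = protein.without_initial_met()
    raw = scale.vector(protein.residues)
    return smooth_strided(raw, w, stride=1, sequence_id=protein.id)
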