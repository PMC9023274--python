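"""Nucleobase/amino-acid affinity scales.

An :class:`AffinityScale` maps each of the 20 standard amino acids to a
relative affinity for one nucleobase (or nucleobase mimetic).  By the sign
convention used throughout, *lower* values mean *stronger* affinity, so a
protein profile that is matched by an RNA density profile yields a negative
Pearson R.  The one exception is adenine (ADE), where matching shows up as
*anti*-correlation of the profiles, i.e. a positive R; such scales carry
``direction="max"``.

The only experimentally determined scale that covers all 20 amino acids is
Woese's polar requirement, measured with substituted pyridines as pyrimidine
mimetics; it ships built in under the name ``PYR'``.  Knowledge-based
per-base scales (ADE/GUA/CYT/URA) are loaded from user-supplied TSV files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "STANDARD_AA",
    "AffinityScale",
    "load_affinity_scale",
    "builtin_polar_requirement",
]

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Woese's polar requirement (pyrimidine-mimetic partitioning scale).
_POLAR_REQUIREMENT = {
    "A": 7.0, "C": 4.8, "D": 13.0, "E": 12.5, "F": 5.0,
    "G": 7.9, "H": 8.4, "I": 4.9, "K": 10.1, "L": 4.9,
    "M": 5.3, "N": 10.0, "P": 6.6, "Q": 8.6, "R": 9.1,
    "S": 7.5, "T": 6.6, "V": 5.6, "W": 5.2, "Y": 5.4,
}


class ScaleError(ValueError):
    """Raised for malformed or incomplete affinity scales."""


@dataclass(frozen=True)
class AffinityScale:
    """A named amino-acid -> relative-affinity map (dimensionless).

    Parameters
    ----------
    name:
        Short identifier (``PYR'``, ``ADE``, ``GUA``, ``CYT``, ``URA``, ...).
    values:
        Mapping from each standard one-letter code to a finite float.
    direction:
        ``"min"`` if matched profiles give minima in Pearson R (the default
        convention), ``"max"`` for adenine-type anti-matching scales.
    """

    name: str
    values: Mapping[str, float]
    direction: str = "min"

    def __post_init__(self) -> None:
        if not self.name:
            raise ScaleError("scale name must be nonempty")
        if self.direction not in ("min", "max"):
            raise ScaleError(f"direction must be 'min' or 'max', got {self.direction!r}")
        vals = {str(k).upper(): float(v) for k, v in self.values.items()}
        extra = sorted(set(vals) - set(STANDARD_AA))
        if extra:
            raise ScaleError(f"non-standard residues in scale {self.name!r}: {extra}")
        missing = sorted(set(STANDARD_AA) - set(vals))
        if missing:
            raise ScaleError(f"scale {self.name!r} is missing residues: {missing}")
        bad = sorted(k for k, v in vals.items() if not math.isfinite(v))
        if bad:
            raise ScaleError(f"scale {self.name!r} has non-finite values for: {bad}")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, aa: str) -> float:
        try:
            return self.values[aa.upper()]
        except KeyError:
            raise ScaleError(f"residue {aa!r} absent from scale {self.name!r}") from None

    def vector(self, residues: str) -> np.ndarray:
        """Per-residue affinity values for a protein sequence."""
        try:
            return np.array([self.values[r] for r in residues.upper()], dtype=float)
        except KeyError as exc:
            raise ScaleError(
                f"residue {exc.args[0]!r} absent from scale {self.name!r}"
            ) from None

    def transformed(self, scale: float = 1.0, shift: float = 0.0,
                    name: str | None = None) -> "AffinityScale":
        """Affinely transformed copy (``scale * value + shift``)."""
        return AffinityScale(
            name=name or self.name,
            values={k: scale * v + shift for k, v in self.values.items()},
            direction=self.direction,
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for aa in STANDARD_AA:
                fh.write(f"{aa}\t{self.values[aa]!r}\n")


def _default_direction(name: str) -> str:
    # Adenine-affinity scales anti-match their density profiles.
    return "max" if name.strip().upper() == "ADE" else "min"


def load_affinity_scale(source: str | Path, name: str,
                        direction: str | None = None) -> AffinityScale:
    """Load a two-column TSV (``aa<TAB>value``, optional header) as a scale.

    ``direction`` defaults to ``"min"`` unless the scale is named ``ADE``.
    Duplicate or missing residues and non-numeric values raise
    :class:`ScaleError` naming the offender.
    """
    if not name:
        raise ScaleError("scale name must be nonempty")
    values: dict[str, float] = {}
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ScaleError(f"{source}, line {lineno}: expected 2 columns, got {len(parts)}")
            aa, raw = parts[0].strip().upper(), parts[1].strip()
            if lineno == 1 and (aa in ("AA", "RESIDUE") or len(aa) > 1):
                continue  # header
            if len(aa) != 1:
                raise ScaleError(f"{source}, line {lineno}: bad residue code {parts[0]!r}")
            try:
                val = float(raw)
            except ValueError:
                raise ScaleError(
                    f"{source}, line {lineno}: non-numeric value {raw!r} for residue {aa}"
                ) from None
            if aa in values:
                raise ScaleError(f"{source}, line {lineno}: duplicate residue {aa!r}")
            values[aa] = val
    return AffinityScale(
        name=name, values=values,
        direction=direction if direction is not None else _default_direction(name),
    )


def builtin_polar_requirement() -> AffinityScale:
    """Woese's polar requirement scale, the built-in PYR-mimetic affinity.

    Low polar requirement (hydrophobic residues) corresponds to strong
    partitioning into the pyridine phase, i.e. strong pyrimidine affinity.
    """
    return AffinityScale(name="PYR'", values=dict(_POLAR_REQUIREMENT), direction="min")


def require_scales(scales: Mapping[str, AffinityScale],
                   names: Iterable[str]) -> dict[str, AffinityScale]:
    """Case-insensitive lookup of required scale names; error if any missing."""
    lookup = {k.upper(): v for k, v in scales.items()}
    out = {}
    for n in names:
        if n.upper() not in lookup:
            raise ScaleError(f"required scale {n!r} not provided")
        out[n] = lookup[n.upper()]
    return out
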