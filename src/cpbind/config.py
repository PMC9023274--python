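"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults for every tunable the pipeline exposes.

    ``window_profiles`` smooths density/affinity profiles (units: triplets
    or residues), ``window_energy`` smooths energy profiles (nucleotides);
    both must be odd.  Predicted regions separated by strictly fewer than
    ``merge_gap`` nucleotides are merged.
    """

    window_profiles: int = 21
    window_energy: int = 63
    merge_gap: int = 10
    n_shuffles: int = 1000
    seed: int | None = None
    base_set: str = "CU"
    coordinate_style: str = "tsv1"  # 'tsv1' (1-based inclusive) or 'bed'

    def __post_init__(self) -> None:
        for name in ("window_profiles", "window_energy"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {w}")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.coordinate_style not in ("tsv1", "bed"):
            raise ValueError("coordinate_style must be 'tsv1' or 'bed'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
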