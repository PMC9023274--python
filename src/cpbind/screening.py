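"""Batch prediction across annotated viral genomes.

Coat-protein candidates are picked from annotated protein / mature-peptide
records by product-name rules (``coat``/``capsid``/``core``, plus the VP
subunit names for picornaviruses), a minimum length and an ambiguity check;
for every accepted genome/CP pair the lowest-percentile interaction-energy
regions are reported as candidate binding sites.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .energy import energy_profile, predict_regions
from .evaluation import IntervalSet
from .profiles import ProteinSequence, RnaSequence, SequenceError, normalize_sequence

__all__ = [
    "AnnotatedProteinRecord",
    "select_cp_records",
    "screen_virus",
    "INCLUSION_TERMS",
    "EXCLUSION_TERMS",
    "PICORNA_TERMS",
]

logger = logging.getLogger(__name__)

INCLUSION_TERMS = ("coat", "capsid", "core")
#: Additional inclusion terms for members of Picornaviridae, whose capsid
#: subunits are annotated as VP0-VP4.
PICORNA_TERMS = ("vp0", "vp1", "vp2", "vp3", "vp4")
EXCLUSION_TERMS = (
    "precursor", "polyprotein", "readthrough", "read-through", "leader",
    "duplicate", "homolog", "coat-like", "extension", "extended",
    "rna replicase",
)
# 'proteins' (plural) is matched as a whole token so that plain 'protein'
# in e.g. 'capsid protein' does not disqualify every record.
_PROTEINS_TOKEN = re.compile(r"\bproteins\b", re.IGNORECASE)

MIN_CP_LENGTH = 50


@dataclass(frozen=True)
class AnnotatedProteinRecord:
    """One annotated protein (or mature peptide / region) of a virus."""

    virus_id: str
    family: str
    product_name: str
    protein_id: str
    sequence: str
    kind: str = "protein"  # 'protein', 'mat_peptide' or 'region'

    def __post_init__(self) -> None:
        if not self.product_name:
            raise ValueError("product_name must be nonempty")


def _rejection_reason(record: AnnotatedProteinRecord) -> str | None:
    name = record.product_name.lower()
    include = INCLUSION_TERMS
    if record.family.strip().lower() == "picornaviridae":
        include = INCLUSION_TERMS + PICORNA_TERMS
    if not any(term in name for term in include):
        return "no inclusion term in product name"
    for term in EXCLUSION_TERMS:
        if term in name:
            return f"exclusion term {term!r} in product name"
    if _PROTEINS_TOKEN.search(record.product_name):
        return "exclusion term 'proteins' in product name"
    try:
        seq = normalize_sequence(record.sequence, "protein")
    except SequenceError as exc:
        return f"ambiguous or invalid sequence ({exc})"
    if len(seq) < MIN_CP_LENGTH:
        return f"sequence shorter than {MIN_CP_LENGTH} aa ({len(seq)})"
    return None


def select_cp_records(records: Iterable[AnnotatedProteinRecord],
                      ) -> tuple[list[AnnotatedProteinRecord], dict[str, str]]:
    """Split records into accepted CP candidates and per-record rejections.

    Protein and mature-peptide records are considered first; annotated
    regions are used as a fallback only when the first pass accepts nothing
    for a virus.  Rejections are data (reason strings keyed by protein id),
    not errors.
    """
    records = list(records)
    rejections: dict[str, str] = {}
    first_pass = [r for r in records if r.kind in ("protein", "mat_peptide")]
    regions = [r for r in records if r.kind == "region"]

    accepted: list[AnnotatedProteinRecord] = []
    accepted_viruses: set[str] = set()
    for rec in first_pass:
        reason = _rejection_reason(rec)
        if reason is None:
            accepted.append(rec)
            accepted_viruses.add(rec.virus_id)
        else:
            rejections[rec.protein_id] = reason
    for rec in regions:
        if rec.virus_id in accepted_viruses:
            rejections[rec.protein_id] = "region record superseded by protein-level hit"
            continue
        reason = _rejection_reason(rec)
        if reason is None:
            accepted.append(rec)
        else:
            rejections[rec.protein_id] = reason
    return accepted, rejections


def screen_virus(genome: RnaSequence, cps: Sequence[ProteinSequence],
                 scales: Mapping[str, "AffinityScale"],
                 pct_levels: Sequence[float] = (1.0, 5.0),
                 merge_gap: int = 10, smoothing_window: int = 63,
                 cp_cds: IntervalSet | None = None) -> pd.DataFrame:
    """Lowest-energy region report for one genome against its CP candidates.

    Returns one row per predicted region with columns ``virus``, ``cp``,
    ``pct_level``, ``start``, ``end``, ``min_z`` and, when CDS intervals are
    supplied, ``overlaps_cp_cds``.  Pairs whose genome is too short for the
    protein are skipped with a logged reason.
    """
    if not cps:
        raise ValueError("need at least one coat-protein candidate")
    rows = []
    cds_positions = cp_cds.positions() if cp_cds is not None else None
    for cp in cps:
        try:
            prof = energy_profile(genome, cp, scales,
                                  smoothing_window=smoothing_window)
        except ValueError as exc:
            logger.warning("skipping %s/%s: %s", genome.id, cp.id, exc)
            continue
        for pct in pct_levels:
            regions = predict_regions(prof, percentile=pct, merge_gap=merge_gap)
            for (start, end), mz in zip(regions.intervals, regions.min_z):
                row = {
                    "virus": genome.id, "cp": cp.id, "pct_level": pct,
                    "start": start, "end": end, "min_z": mz,
                }
                if cds_positions is not None:
                    row["overlaps_cp_cds"] = bool(
                        cds_positions & set(range(start, end + 1)))
                rows.append(row)
    return pd.DataFrame(
        rows, columns=["virus", "cp", "pct_level", "start", "end", "min_z"]
        + (["overlaps_cp_cds"] if cds_positions is not None else []))
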