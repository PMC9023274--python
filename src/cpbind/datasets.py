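"""Bundled reference data and the MS2 headline analysis.

Bacteriophage MS2 is the benchmark system for this framework: its mature
virion structure resolves 15 gRNA stem-loops in contact with coat-protein
dimers at single-nucleotide precision, including the packaging signal.
Those 15 intervals ship with the package; the 3,569-nt genome itself
(RefSeq NC_001417) is not redistributed and must be supplied as a FASTA
file by the user (:func:`ms2_summary` takes its path).
"""

from __future__ import annotations

from pathlib import Path

from Bio.Seq import Seq

from .evaluation import IntervalSet, bsc
from .matching import call_sites_from_match, sliding_pearson
from .profiles import ProteinSequence, RnaSequence
from .scales import builtin_polar_requirement

__all__ = [
    "MS2_STEM_LOOPS",
    "MS2_CP_CDS",
    "MS2_REPLICASE_CDS",
    "MS2_PS_CLUSTER",
    "ms2_stem_loops",
    "ms2_coat_protein",
    "ms2_summary",
    "load_ms2_genome",
]

#: The 15 gRNA stem-loops contacting CP dimers in the MS2 cryo-EM virion
#: (1-based inclusive genome coordinates).
MS2_STEM_LOOPS: tuple[tuple[int, int], ...] = (
    (102, 114), (179, 200), (593, 606), (902, 915), (977, 990),
    (1460, 1470), (1720, 1731), (1747, 1763), (1776, 1791), (2040, 2053),
    (2374, 2387), (2468, 2481), (2781, 2796), (2840, 2852), (3359, 3372),
)

#: RefSeq NC_001417 CDS coordinates (1-based inclusive, incl. stop codon).
MS2_CP_CDS = (1335, 1727)
MS2_REPLICASE_CDS = (1761, 3398)
#: The three spatially clustered stem-loops around the packaging signal.
MS2_PS_CLUSTER = (1720, 1791)

MS2_GENOME_ID = "NC_001417"


def ms2_stem_loops(genome_id: str = MS2_GENOME_ID) -> IntervalSet:
    """The cryo-EM CP-binding stem-loops as a reference interval set."""
    return IntervalSet(genome_id=genome_id, intervals=MS2_STEM_LOOPS,
                       label="cryoEM_stem_loops")


def ms2_coat_protein(genome: RnaSequence, mature: bool = True) -> ProteinSequence:
    """Translate the CP CDS out of the genome (mature = drop initiator Met)."""
    s, e = MS2_CP_CDS
    cds = genome.bases[s - 1: e]
    protein = str(Seq(cds).translate(to_stop=True))
    if mature:
        protein = protein[1:]
    return ProteinSequence("MS2_CP" + ("_mature" if mature else ""), protein)


def ms2_summary(genome: RnaSequence, w: int = 21,
                cutoff: float = -0.6) -> dict[str, float]:
    """Headline MS2 numbers: profile matching of gRNA PYR-density vs CP PYR'-affinity.

    Returns the Pearson R at the in-frame alignment of the mature CP with
    its own CDS, the strongest R inside the packaging-signal stem-loop
    cluster and inside the replicase CDS, and the binding-site coverage of
    the 15 cryo-EM stem-loops at the given R cutoff.
    """
    cp = ms2_coat_protein(genome, mature=True)
    profile = sliding_pearson(genome, cp, builtin_polar_requirement(),
                              base_set=("C", "U"), w=w)
    # mature-CP codons start right after the initiator codon
    cds_frag_start = MS2_CP_CDS[0] + 3
    centre_offset = 3 * ((w - 1) // 2) + (3 * profile.l - 1) // 2
    r_cds = profile.at(cds_frag_start + centre_offset)

    def _min_in(lo: int, hi: int) -> float:
        vals = [profile.at(p) for p in range(max(lo, profile.first_defined),
                                             min(hi, profile.last_defined) + 1)]
        return min(vals)

    r_ps = _min_in(*MS2_PS_CLUSTER)
    r_replicase = _min_in(*MS2_REPLICASE_CDS)
    called = call_sites_from_match(profile, cutoff)
    coverage = bsc(called, ms2_stem_loops(genome.id), profile.defined_positions())
    return {
        "r_cp_cds": float(r_cds),
        "r_packaging_signal": float(r_ps),
        "r_replicase_best": float(r_replicase),
        "bsc_stem_loops": float(coverage),
        "cutoff": float(cutoff),
        "n_defined": int(len(profile.defined_positions())),
    }


def load_ms2_genome(path: str | Path) -> RnaSequence:
    """Load the user-supplied NC_001417 FASTA and sanity-check its length."""
    from .io import read_rna_fasta

    genome = read_rna_fasta(path)[0]
    if len(genome) != 3569:
        raise ValueError(
            f"{path}: expected the 3,569-nt MS2 genome, got {len(genome)} nt"
        )
    return genome
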