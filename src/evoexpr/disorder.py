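"""Region partitioning and structural-disorder ratios (SDR).

The SDR of a protein or region is the fraction of its residues labelled
disordered ('D') by a per-residue predictor. For KZFPs the protein is split
into the KRAB domain, the C2H2 zinc-finger array, other domains, and the
linker — the non-domain stretch between the KRAB domain and the finger
array. Residue indices are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .types import DisorderTrack, GeneRecord

REGIONS = ("KRAB", "C2H2_array", "other_domains", "linker", "whole_protein")

#: Default SDR grade bins: {0}, (0, 0.1], (0.1, 0.5], (0.5, 1].
#: Only "completely structured" = SDR 0 is fixed by definition; the inner
#: edges are conventional and configurable.
DEFAULT_BINS = ((0.1, "weakly_disordered"), (0.5, "moderately_disordered"), (1.0, "highly_disordered"))
COMPLETELY_STRUCTURED = "completely_structured"


@dataclass(frozen=True)
class RegionSDR:
    gene_id: str
    region: str
    n_residues: int
    n_disordered: int
    sdr: float
    sdr_grade: str


def partition_regions(rec: GeneRecord) -> dict[str, set[int]]:
    """Residue index sets per region of a KZFP.

    * KRAB: union of all KRAB domain intervals.
    * C2H2_array: union of all C2H2 finger intervals.
    * other_domains: residues of non-KRAB, non-C2H2 domains outside the above.
    * linker: residues strictly between the last KRAB residue and the first
      C2H2 residue in sequence order (whichever of the two comes first),
      minus residues inside any domain; empty when adjacent.
    * whole_protein: all residues.
    """
    if not rec.is_kzfp:
        raise ValueError(f"{rec.gene_id}: region partition defined for KZFPs only")
    krab = set()
    fingers = set()
    other = set()
    for d in rec.domains:
        res = set(range(d.start, d.end + 1))
        if d.is_krab:
            krab |= res
        elif d.is_c2h2:
            fingers |= res
        else:
            other |= res
    # the linker spans the gap between the KRAB domain and the finger array,
    # in whichever sequence order they occur
    if max(krab) < min(fingers):
        gap = set(range(max(krab) + 1, min(fingers)))
    else:
        gap = set(range(max(fingers) + 1, min(krab)))
    linker = gap - krab - fingers - other
    other -= krab | fingers
    return {
        "KRAB": krab,
        "C2H2_array": fingers,
        "other_domains": other,
        "linker": linker,
        "whole_protein": set(range(1, rec.protein_length + 1)),
    }


def sdr(track: DisorderTrack, residues: set[int]) -> Fraction | None:
    """Disordered fraction over a residue set; ``None`` for an empty set.

    Exact rational arithmetic so that whole-protein SDR equals the
    residue-weighted combination of disjoint region SDRs identically.
    """
    if not residues:
        return None
    if min(residues) < 1 or max(residues) > len(track):
        raise ValueError(
            f"{track.protein_id}: residue indices outside [1, {len(track)}]"
        )
    n_d = sum(1 for i in residues if track.labels[i - 1] == "D")
    return Fraction(n_d, len(residues))


def sdr_grade(value: float, bins=DEFAULT_BINS) -> str:
    """Grade an SDR value; 0 is always 'completely_structured'.

    ``bins`` is a sequence of (upper_edge, label) pairs covering (0, 1];
    each bin is half-open on the left, closed on the right.
    """
    if not 0 <= value <= 1:
        raise ValueError(f"SDR outside [0, 1]: {value}")
    if value == 0:
        return COMPLETELY_STRUCTURED
    for edge, label in bins:
        if value <= edge:
            return label
    raise ValueError("bins do not cover (0, 1]")


def region_sdr_table(
    records: list[GeneRecord],
    tracks: dict[str, DisorderTrack],
    bins=DEFAULT_BINS,
) -> list[RegionSDR]:
    """Per-region SDR rows for every KZFP with a disorder track.

    Non-KZFP records contribute a whole_protein row only. Regions with no
    residues (e.g. an empty linker) are reported as missing (skipped), never
    as SDR zero.
    """
    out: list[RegionSDR] = []
    for rec in records:
        track = tracks.get(rec.protein_id)
        if track is None:
            continue
        if len(track) != rec.protein_length:
            raise ValueError(
                f"{rec.protein_id}: track length {len(track)} != protein length "
                f"{rec.protein_length}"
            )
        if rec.is_kzfp:
            regions = partition_regions(rec)
        else:
            regions = {"whole_protein": set(range(1, rec.protein_length + 1))}
        for name in REGIONS:
            if name not in regions:
                continue
            value = sdr(track, regions[name])
            if value is None:
                continue
            n_res = len(regions[name])
            out.append(
                RegionSDR(
                    gene_id=rec.gene_id,
                    region=name,
                    n_residues=n_res,
                    n_disordered=int(value * n_res),
                    sdr=float(value),
                    sdr_grade=sdr_grade(float(value), bins),
                )
            )
    return out
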