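"""Major-allele IBD haplotype mapping.

All affected animals in the cohort are presumed to carry one copy of a
founder haplotype around the causal locus (a new, fully penetrant dominant
mutation). The allele on that haplotype at each SNP is estimated as the
major allele among cases (counting both chromosomes), and the minimal IBD
region is the contiguous marker run around a seed marker in which every case
carries at least one copy of the major allele — tolerating a configurable
number of discordant cases per interior marker (recombination or genotyping
error can break the rule for a single animal) and terminating where at least
``boundary_min_discordant`` cases are discordant.

The same carrier rule tests whether a putative ancestor carries the founder
haplotype (used to trace the germline origin of the mutation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import Genotype, GenotypeMatrix, MarkerMap, ValidationError

log = logging.getLogger(__name__)


@dataclass
class MajorAllele:
    marker_id: str
    allele: Optional[str]  # None when uninformative (all missing)
    frequency: float
    tie: bool = False
    uninformative: bool = False


@dataclass
class CarrierMatrix:
    """cases x markers carrier flags for the case-major allele.

    ``carries[i, j]`` is True when case i has >=1 copy of the major allele at
    marker j. Missing genotypes and frequency ties are carrier-satisfied
    (they cannot prove discordance); both are tracked separately.
    """

    case_ids: list[str]
    marker_ids: list[str]
    carries: np.ndarray  # bool (n_cases, n_markers)
    major: list[MajorAllele]
    missing: np.ndarray  # bool (n_cases, n_markers)

    @property
    def noncarrier_counts(self) -> np.ndarray:
        return (~self.carries).sum(axis=0)


@dataclass
class IBDRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    start_marker_id: str
    end_marker_id: str
    n_tolerated_discordant: int
    open_left: bool = False
    open_right: bool = False
    boundary_met_left: bool = True
    boundary_met_right: bool = True

    @property
    def width_mb(self) -> float:
        return round((self.end_bp - self.start_bp) / 1e6, 1)


def major_alleles(genotypes: GenotypeMatrix, case_ids: Sequence[str],
                  marker_ids: Optional[Sequence[str]] = None) -> list[MajorAllele]:
    """Per-marker major allele among cases, counting both chromosomes.

    Exact frequency ties are flagged; markers with all genotypes missing are
    flagged uninformative.
    """
    if marker_ids is None:
        marker_ids = genotypes.marker_ids
    out: list[MajorAllele] = []
    for mid in marker_ids:
        counts: dict[str, int] = {}
        for gt in genotypes.column(mid, case_ids):
            if gt is None:
                continue
            for a in gt:
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            out.append(MajorAllele(mid, None, 0.0, uninformative=True))
            continue
        total = sum(counts.values())
        best = max(counts.values())
        winners = sorted(a for a, c in counts.items() if c == best)
        tie = len(winners) > 1
        out.append(MajorAllele(mid, winners[0], best / total, tie=tie))
    return out


def carrier_matrix(genotypes: GenotypeMatrix, case_ids: Sequence[str],
                   marker_ids: Optional[Sequence[str]] = None) -> CarrierMatrix:
    """Build the cases x markers carrier matrix for the case-major alleles."""
    if not case_ids:
        raise ValidationError("no cases")
    if marker_ids is None:
        marker_ids = genotypes.marker_ids
    majors = major_alleles(genotypes, case_ids, marker_ids)
    n, m = len(case_ids), len(marker_ids)
    carries = np.ones((n, m), dtype=bool)
    missing = np.zeros((n, m), dtype=bool)
    for j, (mid, major) in enumerate(zip(marker_ids, majors)):
        col = genotypes.column(mid, case_ids)
        for i, gt in enumerate(col):
            if gt is None:
                missing[i, j] = True  # carrier-satisfied: cannot prove discordance
            elif major.tie or major.uninformative:
                pass  # uninformative marker: carrier-satisfied by convention
            else:
                carries[i, j] = major.allele in gt
    return CarrierMatrix(list(case_ids), list(marker_ids), carries, majors, missing)


def minimal_ibd_region(cm: CarrierMatrix, marker_map: MarkerMap,
                       seed_marker: Optional[str] = None,
                       tolerance: int = 1,
                       boundary_min_discordant: int = 2) -> IBDRegion:
    """Minimal shared haplotype region around a seed marker.

    Starting from ``seed_marker`` (typically the top linkage or association
    marker; when omitted, the midpoint of the longest qualifying run), the
    region is extended over contiguous markers whose non-carrier count stays
    within ``tolerance``; a marker whose count exceeds the tolerance or
    reaches ``boundary_min_discordant`` terminates the run on that side.
    Interior markers with 1..tolerance non-carrier cases are tolerated and
    counted. ``boundary_met_*`` reports whether each terminating marker had
    at least ``boundary_min_discordant`` discordant cases (the preferred
    boundary evidence); a run touching the scanned chromosome end is flagged
    open on that side.
    """
    marker_ids = cm.marker_ids
    chroms = {marker_map.get(mid).chromosome for mid in marker_ids}
    if len(chroms) != 1:
        raise ValidationError("carrier matrix must cover a single chromosome")
    chromosome = chroms.pop()
    positions = [marker_map.get(mid).position_bp for mid in marker_ids]
    if positions != sorted(positions):
        raise ValidationError("carrier matrix markers must be ordered by position")

    counts = cm.noncarrier_counts
    stop_at = np.minimum(tolerance + 1, boundary_min_discordant)
    inside = counts < stop_at
    if not inside.any():
        raise ValidationError("no shared haplotype: no marker satisfies the carrier rule")

    if seed_marker is not None:
        if seed_marker not in marker_ids:
            raise ValidationError(f"seed marker {seed_marker!r} not in carrier matrix")
        seed = marker_ids.index(seed_marker)
        if not inside[seed]:
            raise ValidationError(
                f"seed marker {seed_marker!r} violates the carrier rule "
                f"({counts[seed]} non-carrier cases)"
            )
    else:
        # longest qualifying run; ties broken leftmost
        best_len, best_start, run_start = 0, 0, None
        for j, ok in enumerate(list(inside) + [False]):
            if ok and run_start is None:
                run_start = j
            elif not ok and run_start is not None:
                if j - run_start > best_len:
                    best_len, best_start = j - run_start, run_start
                run_start = None
        seed = best_start + best_len // 2

    lo = seed
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = seed
    while hi < len(marker_ids) - 1 and inside[hi + 1]:
        hi += 1

    open_left = lo == 0
    open_right = hi == len(marker_ids) - 1
    boundary_left = None if open_left else counts[lo - 1]
    boundary_right = None if open_right else counts[hi + 1]
    if open_left or open_right:
        log.warning("minimal_ibd_region: run touches scanned chromosome end "
                    "(open_left=%s, open_right=%s)", open_left, open_right)

    n_tolerated = int((counts[lo:hi + 1] > 0).sum())
    return IBDRegion(
        chromosome=chromosome,
        start_bp=positions[lo],
        end_bp=positions[hi],
        start_marker_id=marker_ids[lo],
        end_marker_id=marker_ids[hi],
        n_tolerated_discordant=n_tolerated,
        open_left=open_left,
        open_right=open_right,
        boundary_met_left=(boundary_left is None
                           or boundary_left >= boundary_min_discordant),
        boundary_met_right=(boundary_right is None
                            or boundary_right >= boundary_min_discordant),
    )


def region_marker_ids(cm: CarrierMatrix, marker_map: MarkerMap,
                      region: IBDRegion) -> list[str]:
    return [mid for mid in cm.marker_ids
            if region.start_bp <= marker_map.get(mid).position_bp <= region.end_bp]


def ancestor_carries_haplotype(ancestor_genotypes: Mapping[str, Genotype],
                               majors: Sequence[MajorAllele],
                               region_markers: Sequence[str],
                               threshold: float = 1.0) -> tuple[bool, int, int]:
    """Does an ancestor carry the case-major (founder) haplotype?

    An informative marker is one inside the region where the ancestor is
    genotyped and the major allele is unique. The ancestor is called a
    carrier when it has >=1 copy of the major allele at at least
    ``threshold`` (default all) of the informative markers. Returns
    (carries, n_concordant, n_informative).
    """
    major_by_id = {m.marker_id: m for m in majors}
    n_informative = 0
    n_concordant = 0
    for mid in region_markers:
        major = major_by_id.get(mid)
        if major is None or major.tie or major.uninformative:
            continue
        gt = ancestor_genotypes.get(mid)
        if gt is None:
            continue
        n_informative += 1
        if major.allele in gt:
            n_concordant += 1
    if n_informative == 0:
        raise ValidationError("ancestor ungenotyped at all informative region markers")
    return (n_concordant / n_informative) >= threshold, n_concordant, n_informative
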