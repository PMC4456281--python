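"""Two-point linkage between a dominant binary trait and SNP markers in a
half-sib family.

In a half-sib design one common sire is mated to many dams; each progeny
contributes one informative paternal meiosis. For every marker at which the
sire is heterozygous, the paternal marker allele transmitted to each progeny
is deduced by Mendelian subtraction of a dam allele, the trait-allele
transmission is read off the phenotype (full penetrance, dams assumed
non-carriers), and recombinants are counted under the better of the two
possible sire phases. The two-point LOD is evaluated at the maximum-
likelihood recombination fraction theta-hat = r/n:

    LOD = log10[ theta^r (1-theta)^(n-r) / 0.5^n ]

so a marker with zero recombinants in n informative meioses attains the
ceiling n*log10(2) (9.63 for n = 32). The critical region is bounded by the
nearest markers on each side of the top zero-recombinant block that show at
least one recombination with the trait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    Genotype,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    ValidationError,
)

log = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"
MISSING = "missing"
INCONSISTENT = "inconsistent"


@dataclass
class MeiosisCall:
    """One paternal meiosis: deduced sire allele plus trait transmission."""

    progeny_id: str
    paternal_allele: str  # allele code, or AMBIGUOUS / MISSING / INCONSISTENT
    trait_transmission: Optional[str] = None  # 'causal' | 'wildtype' | None

    @property
    def informative(self) -> bool:
        return (
            self.paternal_allele not in (AMBIGUOUS, MISSING, INCONSISTENT)
            and self.trait_transmission in ("causal", "wildtype")
        )


@dataclass
class TwoPointResult:
    marker_id: str
    chromosome: str
    position_bp: int
    n_informative: int
    r: int
    theta_hat: float
    lod: float
    n_ambiguous: int = 0
    n_missing: int = 0
    n_inconsistent: int = 0
    uninformative: bool = False


@dataclass
class LinkageRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    start_marker_id: str
    end_marker_id: str
    open_left: bool = False
    open_right: bool = False

    @property
    def width_mb(self) -> float:
        return round((self.end_bp - self.start_bp) / 1e6, 1)


def infer_paternal_allele(sire_gt: Genotype, dam_gt: Genotype,
                          progeny_gt: Genotype) -> str:
    """Deduce which sire allele a progeny received at a sire-heterozygous marker.

    Returns the unique sire allele consistent with Mendelian subtraction of a
    dam allele, ``AMBIGUOUS`` when both sire alleles are consistent,
    ``MISSING`` when the sire or progeny genotype is missing, and
    ``INCONSISTENT`` when no transmission explains the progeny genotype.
    A missing dam genotype (``dam_gt=None``) widens the set of admissible
    maternal alleles to any code.
    """
    if sire_gt is None or progeny_gt is None:
        return MISSING
    if sire_gt[0] == sire_gt[1]:
        raise ValidationError("sire must be heterozygous at the marker")
    consistent = []
    for s in sire_gt:
        dam_alleles = dam_gt if dam_gt is not None else tuple(progeny_gt)
        for d in dam_alleles:
            if tuple(sorted((s, d))) == progeny_gt:
                consistent.append(s)
                break
    if not consistent:
        return INCONSISTENT
    if len(set(consistent)) == 2:
        return AMBIGUOUS
    return consistent[0]


def count_recombinants(calls: Sequence[MeiosisCall]) -> tuple[int, int]:
    """Count recombinant meioses under the better of the two sire phases.

    Only informative calls (unambiguous paternal allele, known trait
    transmission) enter n. Phase is unknown, so r is the minimum over both
    assignments of sire marker alleles to the causal/wild-type haplotypes;
    hence r <= n/2. Returns (r, n); n = 0 marks the marker uninformative.
    """
    informative = [c for c in calls if c.informative]
    n = len(informative)
    if n == 0:
        return 0, 0
    a = sorted({c.paternal_allele for c in informative})[0]
    # phase 1: allele a rides on the causal haplotype; phase 2 is its mirror
    mismatch = sum(
        1 for c in informative
        if (c.paternal_allele == a) != (c.trait_transmission == "causal")
    )
    return min(mismatch, n - mismatch), n


def two_point_lod(r: int, n: int) -> tuple[float, float]:
    """Two-point LOD at the MLE recombination fraction theta-hat = r/n.

    Uses the convention 0^0 = 1 so r = 0 gives exactly n*log10(2).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if r > n:
        raise ValidationError(f"r ({r}) cannot exceed n ({n})")
    theta = min(r / n, 0.5)
    lod = n * math.log10(2.0)
    if r > 0:
        lod += r * math.log10(theta)
    if n - r > 0:
        lod += (n - r) * math.log10(1.0 - theta)
    return theta, lod


def marker_meiosis_calls(pedigree: Pedigree, genotypes: GenotypeMatrix,
                         sire_id: str, marker_id: str) -> list[MeiosisCall]:
    """Build per-progeny meiosis calls at one sire-heterozygous marker."""
    calls: list[MeiosisCall] = []
    sire_gt = genotypes.get(sire_id, marker_id)
    for prog in pedigree.progeny_of(sire_id):
        if not genotypes.has_individual(prog.iid):
            continue
        dam_gt = None
        if prog.dam_id is not None and genotypes.has_individual(prog.dam_id):
            dam_gt = genotypes.get(prog.dam_id, marker_id)
        allele = infer_paternal_allele(sire_gt, dam_gt, genotypes.get(prog.iid, marker_id))
        transmission = {"affected": "causal", "unaffected": "wildtype"}.get(prog.phenotype)
        calls.append(MeiosisCall(prog.iid, allele, transmission))
    return calls


def linkage_scan(pedigree: Pedigree, marker_map: MarkerMap,
                 genotypes: GenotypeMatrix, sire_id: str) -> list[TwoPointResult]:
    """Two-point scan over all markers heterozygous in the sire.

    Markers homozygous or missing in the sire are omitted (count logged).
    Ambiguous, missing and Mendelian-inconsistent meioses are excluded from
    n and reported per marker; inconsistent calls are never auto-corrected.
    """
    if not genotypes.has_individual(sire_id):
        raise ValidationError(f"sire {sire_id!r} absent from genotype matrix")
    results: list[TwoPointResult] = []
    n_skipped = 0
    for marker in marker_map:
        sire_gt = genotypes.get(sire_id, marker.marker_id)
        if sire_gt is None or sire_gt[0] == sire_gt[1]:
            n_skipped += 1
            continue
        calls = marker_meiosis_calls(pedigree, genotypes, sire_id, marker.marker_id)
        r, n = count_recombinants(calls)
        if n == 0:
            theta, lod, uninf = 0.5, 0.0, True
        else:
            theta, lod = two_point_lod(r, n)
            uninf = False
        results.append(TwoPointResult(
            marker_id=marker.marker_id,
            chromosome=marker.chromosome,
            position_bp=marker.position_bp,
            n_informative=n,
            r=r,
            theta_hat=theta,
            lod=lod,
            n_ambiguous=sum(1 for c in calls if c.paternal_allele == AMBIGUOUS),
            n_missing=sum(1 for c in calls if c.paternal_allele == MISSING),
            n_inconsistent=sum(1 for c in calls if c.paternal_allele == INCONSISTENT),
            uninformative=uninf,
        ))
    if n_skipped:
        log.info("linkage_scan: %d markers homozygous/missing in sire omitted", n_skipped)
    if not results:
        log.warning("linkage_scan: sire heterozygous at no markers; empty scan")
    return results


def critical_region(scan_results: Sequence[TwoPointResult],
                    marker_map: MarkerMap) -> LinkageRegion:
    """Extract the critical interval bounded by the nearest flanking
    recombinant markers around the top zero-recombinant block.

    The top marker is the maximal-LOD zero-recombinant marker; when several
    disjoint zero-recombinant blocks tie at the maximum LOD the leftmost
    (lowest position on the lowest-sorted chromosome) is chosen,
    deterministically. A block touching the chromosome end is flagged
    open-ended on that side and bounded by the outermost scanned marker.
    """
    informative = [res for res in scan_results if res.n_informative > 0]
    zero_r = [res for res in informative if res.r == 0]
    if not zero_r:
        raise ValidationError("no zero-recombinant marker in scan results")
    max_lod = max(res.lod for res in zero_r)
    top_candidates = [res for res in zero_r if res.lod == max_lod]
    top = min(top_candidates, key=lambda res: (res.chromosome, res.position_bp))

    chrom = top.chromosome
    chrom_results = sorted(
        (res for res in informative if res.chromosome == chrom),
        key=lambda res: res.position_bp,
    )
    idx = next(i for i, res in enumerate(chrom_results)
               if res.marker_id == top.marker_id)

    lo = idx
    while lo > 0 and chrom_results[lo - 1].r == 0:
        lo -= 1
    hi = idx
    while hi < len(chrom_results) - 1 and chrom_results[hi + 1].r == 0:
        hi += 1

    open_left = lo == 0
    open_right = hi == len(chrom_results) - 1
    left = chrom_results[lo - 1] if not open_left else chrom_results[0]
    right = chrom_results[hi + 1] if not open_right else chrom_results[-1]
    if open_left or open_right:
        log.warning(
            "critical_region: zero-recombinant block touches scanned chromosome "
            "end (open_left=%s, open_right=%s)", open_left, open_right,
        )
    return LinkageRegion(
        chromosome=chrom,
        start_bp=left.position_bp,
        end_bp=right.position_bp,
        start_marker_id=left.marker_id,
        end_marker_id=right.marker_id,
        open_left=open_left,
        open_right=open_right,
    )
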