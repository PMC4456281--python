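"""Shared data model for the mapping pipeline.

The pipeline operates on array genotypes (unphased biallelic SNPs), a
half-sib pedigree with a binary coat-colour phenotype, sequencing variants
annotated with functional consequence, and hair-pigment summary statistics.
All genomic coordinates are 1-based inclusive base pairs; interval widths
are reported in megabases rounded to one decimal (width = end - start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

#: An unphased genotype call: an unordered pair of allele codes, or None if missing.
Genotype = Optional[Tuple[str, str]]

MISSING_ALLELE = "0"

SEXES = ("male", "female", "unknown")
PHENOTYPES = ("affected", "unaffected", "unknown")
CONSEQUENCES = ("missense", "synonymous", "intergenic", "other")
ZYGOSITIES = ("hom_ref", "het", "hom_alt", "missing")

PIGMENT_GROUPS = ("DominantBlack", "DominantRed", "RecessiveRed")

#: Melanin assays reported per group: total melanin (Soluene-350 A500/mg),
#: eumelanin marker PTCA, pheomelanin markers 4-AHP and TTCA, and ratios.
PIGMENT_ASSAYS = (
    "soluene350_a500_per_mg",
    "ptca_ng_per_mg",
    "ahp4_ng_per_mg",
    "ttca_ng_per_mg",
    "ahp4_over_ptca",
    "ttca_over_ptca",
    "a650_over_a500",
)


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str = "", line: int = 0):
        self.path = path
        self.line = line
        prefix = f"{path}:{line}: " if path or line else ""
        super().__init__(prefix + message)


def normalize_genotype(a: str, b: str) -> Genotype:
    """Return the unordered genotype (a, b), or None if either allele is missing."""
    if a in (MISSING_ALLELE, "", None) or b in (MISSING_ALLELE, "", None):
        return None
    return (a, b) if a <= b else (b, a)


def genotype_has_allele(gt: Genotype, allele: str) -> bool:
    return gt is not None and allele in gt


# ---------------------------------------------------------------------------
# Markers and genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    marker_id: str
    chromosome: str
    position_bp: int

    def __post_init__(self):
        if self.position_bp < 1:
            raise ValidationError(
                f"marker {self.marker_id}: position_bp must be >= 1, got {self.position_bp}"
            )


class MarkerMap:
    """An ordered list of biallelic SNP markers with genomic coordinates.

    Positions must be strictly increasing within each chromosome and marker
    ids unique across the map.
    """

    def __init__(self, markers: Sequence[Marker]):
        self.markers: list[Marker] = list(markers)
        seen: set[str] = set()
        last: dict[str, int] = {}
        for m in self.markers:
            if m.marker_id in seen:
                raise ValidationError(f"duplicate marker id {m.marker_id!r}")
            seen.add(m.marker_id)
            prev = last.get(m.chromosome)
            if prev is not None and m.position_bp <= prev:
                raise ValidationError(
                    f"marker {m.marker_id!r}: positions not strictly increasing on "
                    f"chromosome {m.chromosome} ({m.position_bp} after {prev})"
                )
            last[m.chromosome] = m.position_bp
        self._index = {m.marker_id: i for i, m in enumerate(self.markers)}

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, i: int) -> Marker:
        return self.markers[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self.markers == other.markers

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def index(self, marker_id: str) -> int:
        return self._index[marker_id]

    def get(self, marker_id: str) -> Marker:
        return self.markers[self._index[marker_id]]

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if not out or out[-1] != m.chromosome:
                if m.chromosome in out:
                    raise ValidationError("markers of one chromosome must be contiguous")
                out.append(m.chromosome)
        return out

    def chromosome_indices(self, chromosome: str) -> list[int]:
        return [i for i, m in enumerate(self.markers) if m.chromosome == chromosome]


class GenotypeMatrix:
    """Per-(individual, marker) unphased genotype calls.

    Calls are stored in an object array of shape (n_individuals, n_markers)
    holding unordered allele pairs or None for missing. Allele codes at a
    marker are expected to be drawn from at most two symbols plus missing.
    """

    def __init__(self, individuals: Sequence[str], marker_ids: Sequence[str],
                 calls: np.ndarray | None = None):
        self.individuals = list(individuals)
        self.marker_ids = list(marker_ids)
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual ids in genotype matrix")
        n, m = len(self.individuals), len(self.marker_ids)
        if calls is None:
            calls = np.full((n, m), None, dtype=object)
        calls = np.asarray(calls, dtype=object)
        if calls.shape != (n, m):
            raise ValidationError(
                f"genotype matrix shape {calls.shape} does not match "
                f"{n} individuals x {m} markers"
            )
        self.calls = calls
        self._ind_index = {iid: i for i, iid in enumerate(self.individuals)}
        self._marker_index = {mid: j for j, mid in enumerate(self.marker_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def has_individual(self, iid: str) -> bool:
        return iid in self._ind_index

    def get(self, iid: str, marker_id: str) -> Genotype:
        return self.calls[self._ind_index[iid], self._marker_index[marker_id]]

    def set(self, iid: str, marker_id: str, gt: Genotype) -> None:
        self.calls[self._ind_index[iid], self._marker_index[marker_id]] = gt

    def row(self, iid: str) -> list[Genotype]:
        return list(self.calls[self._ind_index[iid], :])

    def column(self, marker_id: str, individuals: Iterable[str] | None = None) -> list[Genotype]:
        j = self._marker_index[marker_id]
        if individuals is None:
            return list(self.calls[:, j])
        return [self.calls[self._ind_index[i], j] for i in individuals]

    def allele_codes(self, marker_id: str) -> set[str]:
        codes: set[str] = set()
        for gt in self.column(marker_id):
            if gt is not None:
                codes.update(gt)
        return codes

    def validate_against(self, marker_map: MarkerMap) -> None:
        if self.marker_ids != marker_map.marker_ids:
            raise ValidationError("genotype matrix markers do not match marker map")
        for mid in self.marker_ids:
            if len(self.allele_codes(mid)) > 2:
                raise ValidationError(f"marker {mid!r} has more than two allele codes")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.individuals == other.individuals
            and self.marker_ids == other.marker_ids
            and bool((self.calls == other.calls).all())
        )


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    iid: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: str = "unknown"
    phenotype: str = "unknown"
    fid: str = "FAM1"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"{self.iid}: bad sex {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(f"{self.iid}: bad phenotype {self.phenotype!r}")


class Pedigree:
    """A set of individuals with optional parent links and binary trait status.

    Invariants: ids unique, referenced parents present in the pedigree (or
    unknown), no individual is its own ancestor.
    """

    def __init__(self, records: Sequence[Individual]):
        self.records = list(records)
        self._index = {}
        for rec in self.records:
            if rec.iid in self._index:
                raise ValidationError(f"duplicate individual id {rec.iid!r}")
            self._index[rec.iid] = rec
        for rec in self.records:
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None and parent not in self._index:
                    raise ValidationError(
                        f"individual {rec.iid!r} references unknown parent {parent!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self._index:
            if start in state:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                iid, phase = stack.pop()
                if phase == 0:
                    if state.get(iid) == 0:
                        raise ValidationError(f"pedigree cycle involving {iid!r}")
                    if state.get(iid) == 1:
                        continue
                    state[iid] = 0
                    stack.append((iid, 1))
                    rec = self._index[iid]
                    for parent in (rec.sire_id, rec.dam_id):
                        if parent is not None and state.get(parent) != 1:
                            if state.get(parent) == 0:
                                raise ValidationError(
                                    f"pedigree cycle involving {parent!r}"
                                )
                            stack.append((parent, 0))
                else:
                    state[iid] = 1

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self.records == other.records

    def get(self, iid: str) -> Individual:
        return self._index[iid]

    def ids(self) -> list[str]:
        return [r.iid for r in self.records]

    def affected_ids(self) -> list[str]:
        return [r.iid for r in self.records if r.phenotype == "affected"]

    def unaffected_ids(self) -> list[str]:
        return [r.iid for r in self.records if r.phenotype == "unaffected"]

    def progeny_of(self, sire_id: str) -> list[Individual]:
        return [r for r in self.records if r.sire_id == sire_id]


# ---------------------------------------------------------------------------
# Sequencing variants
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """A biallelic sequence variant with the annotations the funnel consumes.

    ``consequence`` comes from upstream annotation; ``in_control_db`` flags
    presence in a control sequencing cohort (variants seen in animals without
    the trait cannot be causal for a fully penetrant dominant trait).
    ``truth_label`` is set only by the simulator ('causal', 'true',
    'false_positive') and is never used by the funnel itself.
    """

    chromosome: str
    position_bp: int
    ref_allele: str
    alt_allele: str
    quality: float
    consequence: Optional[str] = "other"
    proband_genotype: Optional[str] = "missing"
    in_control_db: Optional[bool] = False
    validated: Optional[bool] = None
    truth_label: Optional[str] = None

    def __post_init__(self):
        if self.position_bp < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.position_bp}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"variant at {self.chromosome}:{self.position_bp}: ref == alt"
            )
        if self.quality is not None and self.quality < 0:
            raise ValidationError("variant quality must be non-negative")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValidationError(f"bad consequence {self.consequence!r}")
        if self.proband_genotype is not None and self.proband_genotype not in ZYGOSITIES:
            raise ValidationError(f"bad proband genotype {self.proband_genotype!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chromosome}:{self.position_bp}:{self.ref_allele}>{self.alt_allele}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


# ---------------------------------------------------------------------------
# Genomic regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicRegion:
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise ValidationError(
                f"region start {self.start_bp} must be < end {self.end_bp}"
            )

    @property
    def width_mb(self) -> float:
        """Width in Mb, (end - start)/1e6 rounded to one decimal."""
        return round((self.end_bp - self.start_bp) / 1e6, 1)

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return chromosome == self.chromosome and self.start_bp <= position_bp <= self.end_bp


# ---------------------------------------------------------------------------
# Pigment chemistry summaries
# ---------------------------------------------------------------------------

@dataclass
class PigmentGroupStats:
    """Per-group summary (mean, SE) for each melanin assay, with group size n."""

    group: str
    n: int
    assays: Mapping[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in PIGMENT_GROUPS:
            raise ValidationError(f"unknown pigment group {self.group!r}")
        if self.n < 2:
            raise ValidationError(f"group {self.group}: n must be >= 2, got {self.n}")
        for assay, (mean, se) in self.assays.items():
            if assay not in PIGMENT_ASSAYS:
                raise ValidationError(f"unknown assay {assay!r}")
            if se < 0:
                raise ValidationError(f"{self.group}/{assay}: negative SE {se}")
            if mean < 0:
                raise ValidationError(f"{self.group}/{assay}: negative mean {mean}")

    def mean(self, assay: str) -> float:
        return self.assays[assay][0]

    def se(self, assay: str) -> float:
        return self.assays[assay][1]
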