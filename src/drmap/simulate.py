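"""Synthetic datasets with the statistical structure each mapping stage assumes.

Three generators cover the three study designs the pipeline consumes:

* :func:`simulate_half_sib_family` — one sire heterozygous for a fully
  penetrant dominant trait allele, mated to unrelated non-carrier dams;
  each progeny receives a paternal gamete built under a Haldane
  (no-interference) crossover model, so trait status is fully determined by
  which sire haplotype was inherited at the trait locus. Defaults mirror
  the mapping family the pipeline targets: 15 affected and 17 unaffected
  progeny, sire heterozygous at ~40% of markers.

* :func:`simulate_cohort_with_ibd` — a case/control cohort in which every
  case carries one copy of a founder haplotype across a planted IBD segment
  (optionally eroded per case at the ends, with optional planted discordant
  cases); controls are unrelated draws from the population. Defaults: 95
  cases, 555 controls.

* :func:`simulate_variant_callset` — a permissively called variant set
  inside a mapped region mixing true variants (high call quality) and false
  positives (low quality), with exactly one planted causal record: missense,
  heterozygous in the proband, absent from the control database and with the
  highest quality in the region. Panel genotypes for a set of known trait
  heterozygotes and confirmatory-resequencing results can be simulated for
  the same call set.

All generators take a single integer seed and are byte-reproducible for a
fixed config. Truth tables are returned for oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .model import (
    GenomicRegion,
    GenotypeMatrix,
    Individual,
    Marker,
    MarkerMap,
    Pedigree,
    ValidationError,
    VariantRecord,
)

ALLELES = ("A", "B")
BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class MapConfig:
    """Genome map for family simulations: evenly spaced SNPs per chromosome."""

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {str(c): 120_000_000 for c in range(1, 6)})
    markers_per_chromosome: int = 300
    #: expected crossovers per bp per meiosis; 1e-8 ~ 1 cM/Mb
    recomb_rate: float = 1e-8
    #: population frequency bounds for the 'A' allele at each marker
    freq_range: tuple[float, float] = (0.1, 0.9)


@dataclass
class TraitConfig:
    causal_chromosome: str = "3"
    causal_position_bp: int = 9_479_761
    penetrance: float = 1.0
    allele_freq: float = 0.0  # population frequency of the causal allele

    def __post_init__(self):
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValidationError("penetrance must be in [0, 1]")


@dataclass
class FamilyConfig:
    n_affected: int = 15
    n_unaffected: int = 17
    #: when set, progeny statuses are random instead of forced counts
    n_progeny: Optional[int] = None
    sire_het_fraction: float = 0.4
    dams_genotyped: bool = True


@dataclass
class CohortConfig:
    n_cases: int = 95
    n_controls: int = 555
    chromosome: str = "3"
    chromosome_length: int = 30_000_000
    n_markers: int = 400
    ibd_start_bp: int = 7_906_099
    ibd_end_bp: int = 10_462_387
    #: mean erosion (bp) of each case's founder segment at each end; 0 = none
    erosion_mean_bp: float = 0.0
    n_discordant_cases: int = 0
    #: construct the markers flanking the segment with >=3 discordant cases,
    #: giving the segment the sharp boundaries the carrier rule presupposes
    sharp_boundaries: bool = True
    freq_range: tuple[float, float] = (0.1, 0.9)


@dataclass
class QualityModel:
    mean: float
    sd: float
    minimum: float = 1.0


@dataclass
class FunnelSimConfig:
    n_true_variants: int = 24
    n_false_variants: int = 30
    true_quality: QualityModel = field(default_factory=lambda: QualityModel(180.0, 40.0))
    false_quality: QualityModel = field(default_factory=lambda: QualityModel(25.0, 12.0))
    n_panel: int = 20
    false_positive_het_rate: float = 0.3

    def __post_init__(self):
        if self.n_true_variants < 0 or self.n_false_variants < 0:
            raise ValidationError("variant counts must be >= 0")


@dataclass
class SimConfig:
    seed: int = 0
    map: MapConfig = field(default_factory=MapConfig)
    trait: TraitConfig = field(default_factory=TraitConfig)
    family: FamilyConfig = field(default_factory=FamilyConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    funnel: FunnelSimConfig = field(default_factory=FunnelSimConfig)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        def tup(d, key):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        map_raw = raw.get("map", {})
        tup(map_raw, "freq_range")
        cohort_raw = raw.get("cohort", {})
        tup(cohort_raw, "freq_range")
        funnel_raw = dict(raw.get("funnel", {}))
        for key in ("true_quality", "false_quality"):
            if key in funnel_raw and isinstance(funnel_raw[key], dict):
                funnel_raw[key] = QualityModel(**funnel_raw[key])
        return cls(
            seed=raw.get("seed", 0),
            map=MapConfig(**map_raw),
            trait=TraitConfig(**raw.get("trait", {})),
            family=FamilyConfig(**raw.get("family", {})),
            cohort=CohortConfig(**cohort_raw),
            funnel=FunnelSimConfig(**funnel_raw),
        )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class FamilySim:
    pedigree: Pedigree
    marker_map: MarkerMap
    genotypes: GenotypeMatrix
    sire_id: str
    progeny_ids: list[str]
    #: paternal haplotype index (0 = causal haplotype, 1 = wild-type) per
    #: (progeny, marker); shape (n_progeny, n_markers)
    paternal_haplotype: np.ndarray
    #: paternal haplotype index at the trait locus per progeny
    trait_haplotype: np.ndarray
    #: per-marker sire haplotype alleles, shape (n_markers, 2); column h is
    #: the allele carried on sire haplotype h
    sire_haplotypes: np.ndarray


@dataclass
class CohortSim:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    case_ids: list[str]
    control_ids: list[str]
    truth_segment: Optional[GenomicRegion]
    truth_segment_markers: list[str]
    founder_alleles: dict[str, str]
    discordant: list[tuple[str, str]]  # (case_id, marker_id) planted discordances

    @property
    def phenotypes(self) -> dict[str, str]:
        out = {i: "case" for i in self.case_ids}
        out.update({i: "control" for i in self.control_ids})
        return out


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def build_marker_map(config: MapConfig) -> MarkerMap:
    """Evenly spaced markers per chromosome (deterministic)."""
    markers = []
    for chrom, length in config.chromosome_lengths.items():
        spacing = length / (config.markers_per_chromosome + 1)
        for i in range(config.markers_per_chromosome):
            pos = int(round((i + 1) * spacing))
            markers.append(Marker(f"M{chrom}_{i + 1:04d}", chrom, max(pos, 1)))
    return MarkerMap(markers)


def _haldane_switch_prob(distance_bp: float, recomb_rate: float) -> float:
    """P(odd number of crossovers) over a gap, no interference."""
    return 0.5 * (1.0 - math.exp(-2.0 * recomb_rate * distance_bp))


def _pop_genotype(freq_a: float, rng: np.random.Generator) -> tuple[str, str]:
    a1 = ALLELES[0] if rng.random() < freq_a else ALLELES[1]
    a2 = ALLELES[0] if rng.random() < freq_a else ALLELES[1]
    return (a1, a2) if a1 <= a2 else (a2, a1)


# ---------------------------------------------------------------------------
# Half-sib family
# ---------------------------------------------------------------------------

def simulate_half_sib_family(config: SimConfig) -> FamilySim:
    """Gene-drop one half-sib family under a Haldane crossover model.

    The sire carries the causal allele on haplotype 0 of the trait
    chromosome; dams are population draws and non-carriers at the trait
    locus. Trait status is determined by inheritance of haplotype 0 at the
    causal position (subject to penetrance). When affected/unaffected counts
    are forced, paternal gametes are rejection-sampled per progeny, which
    samples exactly from the conditional gamete distribution given status.
    """
    rng = np.random.default_rng(config.seed)
    marker_map = build_marker_map(config.map)
    trait = config.trait
    length = config.map.chromosome_lengths.get(trait.causal_chromosome)
    if length is None or not 1 <= trait.causal_position_bp <= length:
        raise ValidationError("trait locus outside the simulated map")

    n_markers = len(marker_map)
    lo, hi = config.map.freq_range
    freqs = rng.uniform(lo, hi, size=n_markers)

    # Sire haplotypes: column h = allele on haplotype h at each marker.
    sire_haps = np.empty((n_markers, 2), dtype=object)
    for j in range(n_markers):
        if rng.random() < config.family.sire_het_fraction:
            order = rng.permutation(2)
            sire_haps[j, 0] = ALLELES[order[0]]
            sire_haps[j, 1] = ALLELES[order[1]]
        else:
            allele = ALLELES[0] if rng.random() < freqs[j] else ALLELES[1]
            sire_haps[j, :] = allele

    # Site schedule per chromosome: marker indices plus the trait locus.
    chrom_sites: list[tuple[str, list[tuple[int, Optional[int]]]]] = []
    for chrom in config.map.chromosome_lengths:
        sites: list[tuple[int, Optional[int]]] = [
            (marker_map[j].position_bp, j) for j in marker_map.chromosome_indices(chrom)
        ]
        if chrom == trait.causal_chromosome:
            sites.append((trait.causal_position_bp, None))
            sites.sort(key=lambda s: (s[0], -1 if s[1] is None else s[1]))
        chrom_sites.append((chrom, sites))

    def paternal_gamete() -> tuple[np.ndarray, int]:
        hap_at_marker = np.zeros(n_markers, dtype=np.int8)
        hap_at_trait = 0
        for chrom, sites in chrom_sites:
            hap = int(rng.integers(2))
            prev_pos = None
            for pos, j in sites:
                if prev_pos is not None:
                    if rng.random() < _haldane_switch_prob(pos - prev_pos,
                                                          config.map.recomb_rate):
                        hap = 1 - hap
                prev_pos = pos
                if j is None:
                    hap_at_trait = hap
                else:
                    hap_at_marker[j] = hap
        return hap_at_marker, hap_at_trait

    fam = config.family
    if fam.n_progeny is not None:
        targets: list[Optional[str]] = [None] * fam.n_progeny
    else:
        targets = ["affected"] * fam.n_affected + ["unaffected"] * fam.n_unaffected

    progeny_ids = [f"P{k + 1:03d}" for k in range(len(targets))]
    dam_ids = [f"DAM{k + 1:03d}" for k in range(len(targets))]
    sire_id = "SIRE"

    individuals = [Individual(sire_id, sex="male", phenotype="affected")]
    paternal_hap = np.zeros((len(targets), n_markers), dtype=np.int8)
    trait_hap = np.zeros(len(targets), dtype=np.int8)
    dam_gts = np.empty((len(targets), n_markers), dtype=object)
    progeny_gts = np.empty((len(targets), n_markers), dtype=object)
    statuses: list[str] = []

    for k, target in enumerate(targets):
        # Dams: unrelated population draws, non-carriers at the trait locus.
        for j in range(n_markers):
            dam_gts[k, j] = _pop_genotype(freqs[j], rng)

        while True:
            hap_m, hap_t = paternal_gamete()
            carrier = hap_t == 0
            affected = carrier and rng.random() < trait.penetrance
            status = "affected" if affected else "unaffected"
            if target is None or status == target:
                break
        statuses.append(status)
        paternal_hap[k, :] = hap_m
        trait_hap[k] = hap_t
        for j in range(n_markers):
            pat = sire_haps[j, hap_m[j]]
            mat = dam_gts[k, j][int(rng.integers(2))]
            progeny_gts[k, j] = (pat, mat) if pat <= mat else (mat, pat)

    for k in range(len(targets)):
        individuals.append(Individual(dam_ids[k], sex="female", phenotype="unaffected"))
    for k in range(len(targets)):
        individuals.append(Individual(
            progeny_ids[k], sire_id=sire_id, dam_id=dam_ids[k],
            sex="female" if k % 2 else "male", phenotype=statuses[k],
        ))
    pedigree = Pedigree(individuals)

    matrix_ids = [sire_id]
    if fam.dams_genotyped:
        matrix_ids += dam_ids
    matrix_ids += progeny_ids
    calls = np.full((len(matrix_ids), n_markers), None, dtype=object)
    for j in range(n_markers):
        a, b = sire_haps[j, 0], sire_haps[j, 1]
        calls[0, j] = (a, b) if a <= b else (b, a)
    offset = 1
    if fam.dams_genotyped:
        calls[offset:offset + len(targets), :] = dam_gts
        offset += len(targets)
    calls[offset:, :] = progeny_gts
    genotypes = GenotypeMatrix(matrix_ids, marker_map.marker_ids, calls)

    return FamilySim(
        pedigree=pedigree,
        marker_map=marker_map,
        genotypes=genotypes,
        sire_id=sire_id,
        progeny_ids=progeny_ids,
        paternal_haplotype=paternal_hap,
        trait_haplotype=trait_hap,
        sire_haplotypes=sire_haps,
    )


def make_cosegregating_family(n_affected: int = 15, n_unaffected: int = 17,
                              marker_id: str = "DIAG",
                              chromosome: str = "3",
                              position_bp: int = 9_479_761,
                              ) -> tuple[Pedigree, MarkerMap, GenotypeMatrix]:
    """Deterministic textbook family: one marker co-segregating with the trait.

    The sire is A/B with the causal allele in coupling with A; every dam is
    B/B, so each of the ``n_affected + n_unaffected`` meioses is informative:
    affected progeny are A/B (paternal A), unaffected progeny B/B (paternal
    B). Useful as a closed-form check: the marker shows zero recombinants in
    n meioses, so its two-point LOD is exactly n*log10(2).
    """
    marker_map = MarkerMap([Marker(marker_id, chromosome, position_bp)])
    individuals = [Individual("SIRE", sex="male", phenotype="affected")]
    n = n_affected + n_unaffected
    for k in range(n):
        individuals.append(Individual(f"DAM{k + 1:03d}", sex="female",
                                      phenotype="unaffected"))
    statuses = ["affected"] * n_affected + ["unaffected"] * n_unaffected
    for k, status in enumerate(statuses):
        individuals.append(Individual(
            f"P{k + 1:03d}", sire_id="SIRE", dam_id=f"DAM{k + 1:03d}",
            sex="female" if k % 2 else "male", phenotype=status,
        ))
    pedigree = Pedigree(individuals)
    ids = [rec.iid for rec in individuals]
    calls = np.full((len(ids), 1), None, dtype=object)
    gm = GenotypeMatrix(ids, [marker_id], calls)
    gm.set("SIRE", marker_id, ("A", "B"))
    for k in range(n):
        gm.set(f"DAM{k + 1:03d}", marker_id, ("B", "B"))
    for k, status in enumerate(statuses):
        gt = ("A", "B") if status == "affected" else ("B", "B")
        gm.set(f"P{k + 1:03d}", marker_id, gt)
    return pedigree, marker_map, gm


# ---------------------------------------------------------------------------
# Cohort with planted IBD segment
# ---------------------------------------------------------------------------

def simulate_cohort_with_ibd(config: SimConfig,
                             plant_segment: bool = True) -> CohortSim:
    """Simulate a case/control cohort sharing a founder haplotype.

    Cases carry one copy of the founder haplotype across the planted segment
    (optionally eroded at the ends per case); controls are unrelated
    population draws. With ``plant_segment=False`` cases are plain population
    draws too (the null cohort used for type-I calibration).
    """
    c = config.cohort
    if c.n_cases <= 0:
        raise ValidationError("no cases")
    rng = np.random.default_rng(config.seed)

    spacing = c.chromosome_length / (c.n_markers + 1)
    markers = [Marker(f"S{i + 1:04d}", c.chromosome,
                      max(int(round((i + 1) * spacing)), 1))
               for i in range(c.n_markers)]
    marker_map = MarkerMap(markers)
    positions = np.array([m.position_bp for m in markers])

    if plant_segment:
        if not (1 <= c.ibd_start_bp < c.ibd_end_bp <= c.chromosome_length):
            raise ValidationError("IBD segment outside the simulated map")
        in_segment = (positions >= c.ibd_start_bp) & (positions <= c.ibd_end_bp)
        if not in_segment.any():
            raise ValidationError("IBD segment contains no markers")
    else:
        in_segment = np.zeros(len(markers), dtype=bool)

    lo, hi = c.freq_range
    freqs = rng.uniform(lo, hi, size=len(markers))
    founder = np.array([ALLELES[0] if rng.random() < freqs[j] else ALLELES[1]
                        for j in range(len(markers))], dtype=object)

    case_ids = [f"CASE{k + 1:03d}" for k in range(c.n_cases)]
    control_ids = [f"CTRL{k + 1:03d}" for k in range(c.n_controls)]
    ids = case_ids + control_ids
    calls = np.full((len(ids), len(markers)), None, dtype=object)

    for k in range(c.n_cases):
        if plant_segment and c.erosion_mean_bp > 0:
            start = c.ibd_start_bp + rng.exponential(c.erosion_mean_bp)
            end = c.ibd_end_bp - rng.exponential(c.erosion_mean_bp)
        else:
            start, end = c.ibd_start_bp, c.ibd_end_bp
        for j in range(len(markers)):
            if plant_segment and in_segment[j] and start <= positions[j] <= end:
                other = ALLELES[0] if rng.random() < freqs[j] else ALLELES[1]
                a, b = founder[j], other
                calls[k, j] = (a, b) if a <= b else (b, a)
            else:
                calls[k, j] = _pop_genotype(freqs[j], rng)
    for k in range(c.n_controls):
        for j in range(len(markers)):
            calls[c.n_cases + k, j] = _pop_genotype(freqs[j], rng)

    segment_idx = np.flatnonzero(in_segment)
    discordant: list[tuple[str, str]] = []
    if plant_segment and c.n_discordant_cases > 0:
        interior = segment_idx[1:-1] if len(segment_idx) > 2 else segment_idx
        chosen_cases = rng.choice(c.n_cases, size=min(c.n_discordant_cases, c.n_cases),
                                  replace=False)
        for k in chosen_cases:
            j = int(rng.choice(interior))
            non_founder = ALLELES[1] if founder[j] == ALLELES[0] else ALLELES[0]
            calls[k, j] = (non_founder, non_founder)
            discordant.append((case_ids[k], markers[j].marker_id))

    if plant_segment and c.sharp_boundaries and len(segment_idx) > 0:
        # Force >=3 case non-carriers of the case-major allele at the markers
        # immediately flanking the segment, touching as few genotypes as
        # possible so the flank stays association-neutral.
        if c.n_cases < 7:
            raise ValidationError("sharp_boundaries needs >= 7 cases")
        for j in (segment_idx[0] - 1, segment_idx[-1] + 1):
            if not 0 <= j < len(markers):
                continue
            # Three homozygotes of each allele guarantee >=3 non-carriers of
            # whichever allele is major; one extra genotype breaks exact ties.
            for k in range(3):
                calls[k, j] = (ALLELES[0], ALLELES[0])
            for k in range(3, 6):
                calls[k, j] = (ALLELES[1], ALLELES[1])
            counts = {a: 0 for a in ALLELES}
            for k in range(c.n_cases):
                for a in calls[k, j]:
                    counts[a] += 1
            if counts[ALLELES[0]] == counts[ALLELES[1]]:
                calls[6, j] = (ALLELES[0], ALLELES[0])

    genotypes = GenotypeMatrix(ids, marker_map.marker_ids, calls)
    truth_segment = None
    truth_markers: list[str] = []
    founder_alleles: dict[str, str] = {}
    if plant_segment:
        truth_segment = GenomicRegion(c.chromosome, c.ibd_start_bp, c.ibd_end_bp)
        truth_markers = [markers[j].marker_id for j in segment_idx]
        founder_alleles = {markers[j].marker_id: str(founder[j]) for j in segment_idx}

    return CohortSim(
        genotypes=genotypes,
        marker_map=marker_map,
        case_ids=case_ids,
        control_ids=control_ids,
        truth_segment=truth_segment,
        truth_segment_markers=truth_markers,
        founder_alleles=founder_alleles,
        discordant=discordant,
    )


# ---------------------------------------------------------------------------
# Variant call set
# ---------------------------------------------------------------------------

_CONSEQUENCE_PROBS = {
    "missense": 0.15,
    "synonymous": 0.20,
    "intergenic": 0.50,
    "other": 0.15,
}


def _draw_quality(model: QualityModel, rng: np.random.Generator) -> float:
    return float(max(model.minimum, rng.normal(model.mean, model.sd)))


def simulate_variant_callset(config: FunnelSimConfig, region: GenomicRegion,
                             seed: int = 0) -> list[VariantRecord]:
    """Simulate a permissively called variant set inside a mapped region.

    Returns ``n_true_variants + n_false_variants + 1`` records sorted by
    position: true variants with high quality (mostly already known in the
    control database), false positives with low quality, and exactly one
    planted causal variant — missense, heterozygous in the proband, absent
    from the control database, and with the highest quality score in the
    region (enforced by construction). Truth labels ride on
    ``VariantRecord.truth_label``.
    """
    rng = np.random.default_rng(seed)
    span = region.end_bp - region.start_bp
    if span <= 0:
        raise ValidationError("region has zero width")
    n_total = config.n_true_variants + config.n_false_variants
    if n_total == 0:
        return []
    n_records = n_total + 1
    if n_records > span:
        raise ValidationError("region too narrow for the requested variant count")

    offsets: set[int] = set()
    while len(offsets) < n_records:
        offsets.update(int(x) for x in rng.integers(0, span, size=n_records - len(offsets)))
    positions = np.sort(np.fromiter(offsets, dtype=np.int64)) + region.start_bp
    causal_slot = int(rng.integers(n_records))

    labels = ["true"] * config.n_true_variants + ["false_positive"] * config.n_false_variants
    rng.shuffle(labels)
    labels.insert(causal_slot, "causal")

    csq_names = list(_CONSEQUENCE_PROBS)
    csq_p = np.array([_CONSEQUENCE_PROBS[k] for k in csq_names])

    records: list[VariantRecord] = []
    for pos, label in zip(positions, labels):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref, alt = BASES[ref], BASES[alt]
        if label == "causal":
            records.append(VariantRecord(
                chromosome=region.chromosome, position_bp=int(pos),
                ref_allele=ref, alt_allele=alt, quality=0.0,  # set below
                consequence="missense", proband_genotype="het",
                in_control_db=False, truth_label="causal",
            ))
            continue
        csq = csq_names[int(rng.choice(len(csq_names), p=csq_p))]
        if label == "true":
            quality = _draw_quality(config.true_quality, rng)
            zyg = ["het", "hom_alt", "hom_ref"][int(rng.choice(3, p=[0.6, 0.3, 0.1]))]
            in_db = bool(rng.random() < 0.85)
        else:
            quality = _draw_quality(config.false_quality, rng)
            zyg = "het" if rng.random() < 0.8 else "hom_alt"
            in_db = bool(rng.random() < 0.1)
        records.append(VariantRecord(
            chromosome=region.chromosome, position_bp=int(pos),
            ref_allele=ref, alt_allele=alt, quality=quality,
            consequence=csq, proband_genotype=zyg, in_control_db=in_db,
            truth_label=label,
        ))

    top = max((r.quality for r in records if r.truth_label != "causal"), default=10.0)
    for i, r in enumerate(records):
        if r.truth_label == "causal":
            records[i] = replace(r, quality=round(top * 1.02 + 1.0, 2))
    return records


def simulate_panel_genotypes(variants: Sequence[VariantRecord],
                             n_panel: int = 20,
                             false_positive_het_rate: float = 0.3,
                             seed: int = 0) -> dict[str, dict[str, Optional[str]]]:
    """Genotypes of a panel of known trait heterozygotes at each variant.

    The causal variant is heterozygous in every panel member. True
    non-causal variants segregate in the population, so panel members draw
    Hardy–Weinberg genotypes at a random alt frequency — occasionally
    producing alternative-allele homozygotes, which disqualify a candidate.
    False-positive calls replicate as spurious heterozygotes at
    ``false_positive_het_rate``.
    """
    rng = np.random.default_rng(seed)
    members = [f"HET{k + 1:02d}" for k in range(n_panel)]
    out: dict[str, dict[str, Optional[str]]] = {}
    for v in variants:
        panel: dict[str, Optional[str]] = {}
        if v.truth_label == "causal":
            for m in members:
                panel[m] = "het"
        elif v.truth_label == "false_positive":
            for m in members:
                panel[m] = "het" if rng.random() < false_positive_het_rate else "hom_ref"
        else:
            q = rng.uniform(0.05, 0.6)
            for m in members:
                n_alt = int(rng.random() < q) + int(rng.random() < q)
                panel[m] = ("hom_ref", "het", "hom_alt")[n_alt]
        out[v.variant_id] = panel
    return out


def simulate_sanger_results(variants: Sequence[VariantRecord]) -> dict[str, str]:
    """Confirmatory resequencing of the proband: false positives come back absent."""
    return {v.variant_id: ("absent" if v.truth_label == "false_positive" else "present")
            for v in variants}
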