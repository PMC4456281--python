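"""Stage-wise prioritization of sequencing variants inside a mapped region.

The funnel mirrors the filtering logic used to reduce a permissively called
variant set to a single candidate causal mutation for a fully penetrant
dominant trait sequenced in one heterozygous proband:

1. ``region``      — keep variants inside the mapped interval;
2. ``consequence`` — keep amino-acid-changing (by default missense) variants;
3. ``zygosity``    — keep variants heterozygous in the proband;
4. ``control_db``  — drop variants seen in a control sequencing cohort;
5. ``quality``     — rank survivors by call quality (quality is a rank key,
   not a hard filter, by default: calling was deliberately permissive so
   that true variants are not lost);
6. ``panel``       — optional: a candidate must be heterozygous in every
   known trait heterozygote and homozygous in none;
7. ``sanger``      — optional: drop calls not confirmed by conventional
   resequencing of the same animal.

Every input variant ends up exactly once among the survivors or one stage's
exclusion list, so the report's accounting is conservative by construction.
Indels are counted in-region but not scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import GenomicRegion, ValidationError, VariantRecord

log = logging.getLogger(__name__)

CORE_STAGES = ("region", "consequence", "zygosity", "control_db", "quality")


@dataclass
class PanelRules:
    require_het_in_all_known_carriers: bool = True
    exclude_if_any_alt_homozygote: bool = True


@dataclass
class FunnelConfig:
    region: GenomicRegion
    required_consequences: frozenset[str] = frozenset({"missense"})
    required_proband_zygosity: str = "het"
    exclude_in_control_db: bool = True
    min_quality: float = 0.0  # 0 = permissive; quality ranks, it does not filter
    panel_rules: PanelRules = field(default_factory=PanelRules)

    def __post_init__(self):
        if self.min_quality < 0:
            raise ValidationError("min_quality must be >= 0")


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    excluded: list[tuple[VariantRecord, str]] = field(default_factory=list)


@dataclass
class PanelCheck:
    passed: bool
    reason: str = ""
    n_missing: int = 0


@dataclass
class FunnelReport:
    stages: list[FunnelStage]
    survivors: list[VariantRecord]  # ranked by quality, best first
    n_indels_in_region: int = 0

    @property
    def stage_counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]

    @property
    def n_excluded(self) -> int:
        return sum(len(s.excluded) for s in self.stages)

    def all_exclusions(self) -> list[tuple[VariantRecord, str, str]]:
        return [(v, s.name, reason) for s in self.stages for v, reason in s.excluded]


def _unannotatable(variant: VariantRecord, fields: Sequence[str]) -> Optional[str]:
    for name in fields:
        if getattr(variant, name) is None:
            return f"unannotatable:{name}"
    return None


def panel_concordance(variant: VariantRecord,
                      panel_genotypes: Mapping[str, Optional[str]],
                      rules: PanelRules | None = None) -> PanelCheck:
    """Check a candidate against a panel of known trait heterozygotes.

    ``panel_genotypes`` maps panel-member id to the member's zygosity for
    this variant ('hom_ref' | 'het' | 'hom_alt' | None for missing). Every
    panel member is a known heterozygote for the trait, so a causal variant
    must be heterozygous in all non-missing members and homozygous in none.
    The failure reason names the first violated rule and individual.
    """
    if not panel_genotypes:
        raise ValidationError("empty panel")
    rules = rules or PanelRules()
    n_missing = 0
    for member in sorted(panel_genotypes):
        zyg = panel_genotypes[member]
        if zyg is None or zyg == "missing":
            n_missing += 1
            continue
        if zyg == "hom_alt" and rules.exclude_if_any_alt_homozygote:
            return PanelCheck(False, f"alt_homozygote:{member}", n_missing)
        if zyg != "het" and rules.require_het_in_all_known_carriers:
            return PanelCheck(False, f"not_heterozygous:{member}", n_missing)
    return PanelCheck(True, "", n_missing)


def mark_validation(variants: Sequence[VariantRecord],
                    sanger_results: Mapping[str, str]) -> list[VariantRecord]:
    """Apply confirmatory-resequencing results to candidate variants.

    ``sanger_results`` maps ``variant_id`` to 'present' or 'absent'. Variants
    reported absent get ``validated=False`` (false positives of the
    permissive caller); 'present' sets ``validated=True``, overriding a
    conflicting prior flag with a warning. Results for unknown variants are
    warned about and ignored.
    """
    by_id = {v.variant_id: v for v in variants}
    for vid in sanger_results:
        if vid not in by_id:
            log.warning("sanger result for unknown variant %s ignored", vid)
    out = []
    for v in variants:
        result = sanger_results.get(v.variant_id)
        if result is None:
            out.append(v)
            continue
        new_validated = result != "absent"
        if v.validated is not None and v.validated != new_validated:
            log.warning(
                "variant %s: sanger result %r overrides validated=%s",
                v.variant_id, result, v.validated,
            )
        from dataclasses import replace
        out.append(replace(v, validated=new_validated))
    return out


def run_funnel(variants: Sequence[VariantRecord], config: FunnelConfig,
               panel_genotypes: Optional[Mapping[str, Mapping[str, Optional[str]]]] = None,
               sanger_results: Optional[Mapping[str, str]] = None) -> FunnelReport:
    """Run the staged funnel and return the per-stage accounting.

    Stage order is fixed (region, consequence, zygosity, control_db, quality,
    then panel and sanger when their inputs are supplied); stages can only be
    relaxed through the config, never reordered, so reports from different
    runs stay comparable. Variants missing a field a stage needs are routed
    to that stage's exclusion list with reason ``unannotatable:<field>``.
    Survivors are ranked by quality (descending; ties by position).
    """
    current = list(variants)
    stages: list[FunnelStage] = []

    # 1. region (indels counted here, then set aside unscored)
    survivors, excluded = [], []
    n_indels = 0
    for v in current:
        if not config.region.contains(v.chromosome, v.position_bp):
            excluded.append((v, "outside_region"))
        elif v.is_indel:
            n_indels += 1
            excluded.append((v, "indel_not_scored"))
        else:
            survivors.append(v)
    stages.append(FunnelStage("region", len(current), len(survivors), excluded))
    current = survivors

    # 2. consequence
    survivors, excluded = [], []
    for v in current:
        reason = _unannotatable(v, ["consequence"])
        if reason:
            excluded.append((v, reason))
        elif v.consequence not in config.required_consequences:
            excluded.append((v, f"consequence:{v.consequence}"))
        else:
            survivors.append(v)
    stages.append(FunnelStage("consequence", len(current), len(survivors), excluded))
    current = survivors

    # 3. proband zygosity
    survivors, excluded = [], []
    for v in current:
        reason = _unannotatable(v, ["proband_genotype"])
        if reason:
            excluded.append((v, reason))
        elif v.proband_genotype != config.required_proband_zygosity:
            excluded.append((v, f"zygosity:{v.proband_genotype}"))
        else:
            survivors.append(v)
    stages.append(FunnelStage("zygosity", len(current), len(survivors), excluded))
    current = survivors

    # 4. control database
    survivors, excluded = [], []
    for v in current:
        reason = _unannotatable(v, ["in_control_db"])
        if reason:
            excluded.append((v, reason))
        elif config.exclude_in_control_db and v.in_control_db:
            excluded.append((v, "in_control_db"))
        else:
            survivors.append(v)
    stages.append(FunnelStage("control_db", len(current), len(survivors), excluded))
    current = survivors

    # 5. quality: rank; filter only if a positive threshold was configured
    survivors, excluded = [], []
    for v in current:
        reason = _unannotatable(v, ["quality"])
        if reason:
            excluded.append((v, reason))
        elif v.quality < config.min_quality:
            excluded.append((v, f"quality_below:{config.min_quality}"))
        else:
            survivors.append(v)
    survivors.sort(key=lambda v: (-v.quality, v.chromosome, v.position_bp))
    stages.append(FunnelStage("quality", len(current), len(survivors), excluded))
    current = survivors

    # 6. panel concordance (optional)
    if panel_genotypes is not None:
        survivors, excluded = [], []
        for v in current:
            panel = panel_genotypes.get(v.variant_id)
            if panel is None:
                excluded.append((v, "unannotatable:panel_genotypes"))
                continue
            check = panel_concordance(v, panel, config.panel_rules)
            if check.passed:
                survivors.append(v)
            else:
                excluded.append((v, check.reason))
        stages.append(FunnelStage("panel", len(current), len(survivors), excluded))
        current = survivors

    # 7. confirmatory resequencing (optional)
    if sanger_results is not None:
        current_ids = {v.variant_id for v in current}
        marked = mark_validation(
            current, {k: v for k, v in sanger_results.items() if k in current_ids})
        survivors, excluded = [], []
        for v in marked:
            if v.validated is False:
                excluded.append((v, "sanger_false_positive"))
            else:
                survivors.append(v)
        stages.append(FunnelStage("sanger", len(current), len(survivors), excluded))
        current = survivors

    return FunnelReport(stages=stages, survivors=current, n_indels_in_region=n_indels)
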