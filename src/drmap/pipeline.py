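"""End-to-end synthetic pipeline: simulate -> linkage -> association -> IBD ->
variant funnel -> validation, with plain-file handoff between stages.

Deterministic for a fixed seed: every stochastic step derives from the one
integer seed, outputs carry no timestamps, and all tables are written in a
fixed column and row order, so two runs with the same seed are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as io_mod
from .association import association_scan, top_association
from .funnel import FunnelConfig, run_funnel
from .ibd import carrier_matrix, minimal_ibd_region
from .linkage import critical_region, linkage_scan
from .model import GenomicRegion
from .simulate import (
    SimConfig,
    simulate_cohort_with_ibd,
    simulate_half_sib_family,
    simulate_panel_genotypes,
    simulate_sanger_results,
    simulate_variant_callset,
)
from .validate import concordance, fold_change, group_compare, segregation_test


def run_demo(seed: int, out_dir: str | Path,
             config: SimConfig | None = None) -> str:
    """Run the full mapping chain on simulated data; returns a summary string.

    Writes scan/region/funnel TSVs, the simulated PED/MAP and VCF inputs, and
    ``summary.txt`` into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or SimConfig()
    cfg.seed = seed
    lines: list[str] = [f"seed: {seed}"]

    # --- linkage in the half-sib family -----------------------------------
    fam = simulate_half_sib_family(cfg)
    io_mod.write_pedmap(fam.pedigree, fam.marker_map, fam.genotypes,
                        out / "family.ped", out / "family.map")
    scan = linkage_scan(fam.pedigree, fam.marker_map, fam.genotypes, fam.sire_id)
    pd.DataFrame([{
        "marker": r.marker_id, "chr": r.chromosome, "bp": r.position_bp,
        "n": r.n_informative, "r": r.r, "theta_hat": round(r.theta_hat, 6),
        "lod": round(r.lod, 4),
    } for r in scan]).to_csv(out / "linkage_scan.tsv", sep="\t", index=False)
    best = max(scan, key=lambda r: r.lod)
    link_region = critical_region(scan, fam.marker_map)
    lines.append(
        f"linkage: {len(scan)} sire-heterozygous markers scanned; top marker "
        f"{best.marker_id} (chr {best.chromosome}) LOD {best.lod:.2f} "
        f"with r={best.r}/{best.n_informative}"
    )
    lines.append(
        f"linkage critical region: {link_region.chromosome}:"
        f"{link_region.start_bp}-{link_region.end_bp} ({link_region.width_mb} Mb)"
    )
    on_trait_chrom = best.chromosome == cfg.trait.causal_chromosome
    lines.append(f"linkage top marker on trait chromosome: {on_trait_chrom}")

    # --- association + IBD in the cohort ----------------------------------
    cohort = simulate_cohort_with_ibd(cfg)
    assoc = association_scan(cohort.genotypes, cohort.phenotypes, cohort.marker_map)
    pd.DataFrame([{
        "marker": r.marker_id, "chr": r.chromosome, "bp": r.position_bp,
        "chi2": round(r.chi2, 4), "neglog10p": round(r.neglog10p, 4),
        "case_carrier_fraction": round(r.case_carrier_fraction, 4),
        "control_freq": round(r.control_assoc_allele_freq, 4),
    } for r in assoc]).to_csv(out / "association_scan.tsv", sep="\t", index=False)
    top = top_association(assoc)
    seg = cohort.truth_segment
    lines.append(
        f"association: top marker {top.marker_id} @ {top.position_bp} bp, "
        f"-log10P {top.neglog10p:.1f}, case carrier fraction "
        f"{top.case_carrier_fraction:.3f}, control allele freq "
        f"{top.control_assoc_allele_freq:.3f}"
    )
    lines.append(
        f"association top marker inside truth segment: "
        f"{seg.contains(top.chromosome, top.position_bp)}"
    )

    cm = carrier_matrix(cohort.genotypes, cohort.case_ids)
    try:
        ibd_region = minimal_ibd_region(cm, cohort.marker_map,
                                        seed_marker=top.marker_id)
    except Exception:
        # top association marker can sit just outside the shared run
        # (boundary markers are strongly associated too); fall back to the
        # longest qualifying run
        ibd_region = minimal_ibd_region(cm, cohort.marker_map)
        lines.append("note: top association marker outside the shared run; "
                     "IBD region seeded from the longest qualifying run")
    pd.DataFrame([{
        "chr": ibd_region.chromosome, "start_bp": ibd_region.start_bp,
        "end_bp": ibd_region.end_bp, "width_mb": ibd_region.width_mb,
        "n_tolerated_discordant": ibd_region.n_tolerated_discordant,
    }]).to_csv(out / "ibd_region.tsv", sep="\t", index=False)
    covers = (ibd_region.start_bp <= cfg.trait.causal_position_bp <= ibd_region.end_bp)
    lines.append(
        f"IBD region: {ibd_region.chromosome}:{ibd_region.start_bp}-"
        f"{ibd_region.end_bp} ({ibd_region.width_mb} Mb), "
        f"{ibd_region.n_tolerated_discordant} tolerated discordant marker(s); "
        f"covers planted causal position: {covers}"
    )
    if ibd_region.n_tolerated_discordant > 0 and cfg.cohort.n_discordant_cases == 0:
        lines.append("warning: discordant markers tolerated inside IBD region "
                     "without planted discordance")

    # --- variant funnel inside the IBD region -----------------------------
    funnel_region = GenomicRegion(ibd_region.chromosome, ibd_region.start_bp,
                                  ibd_region.end_bp)
    variants = simulate_variant_callset(cfg.funnel, funnel_region, seed=cfg.seed)
    io_mod.write_variants_vcf(variants, out / "variants.vcf")
    panel = simulate_panel_genotypes(variants, cfg.funnel.n_panel,
                                     cfg.funnel.false_positive_het_rate,
                                     seed=cfg.seed)
    sanger = simulate_sanger_results(variants)
    report = run_funnel(variants, FunnelConfig(region=funnel_region),
                        panel_genotypes=panel, sanger_results=sanger)
    pd.DataFrame(report.stage_counts, columns=["stage", "n_in", "n_out"]).to_csv(
        out / "funnel_stages.tsv", sep="\t", index=False)
    pd.DataFrame([{"variant": v.variant_id, "stage": stage, "reason": reason}
                  for v, stage, reason in report.all_exclusions()]).to_csv(
        out / "funnel_exclusions.tsv", sep="\t", index=False)
    io_mod.write_variants_vcf(report.survivors, out / "funnel_survivors.vcf")
    truth_causal = next(v for v in variants if v.truth_label == "causal")
    recovered = (len(report.survivors) >= 1
                 and report.survivors[0].variant_id == truth_causal.variant_id)
    lines.append("funnel stages: " + ", ".join(
        f"{name} {n_in}->{n_out}" for name, n_in, n_out in report.stage_counts))
    lines.append(f"funnel survivors: {len(report.survivors)}; top survivor equals "
                 f"planted causal variant: {recovered}")

    # --- validation statistics --------------------------------------------
    # Diagnostic-variant concordance: genotype all cohort animals at the
    # causal variant (cases are carriers by construction, controls are not).
    genotypes = {i: "het" for i in cohort.case_ids}
    genotypes.update({i: "hom_ref" for i in cohort.control_ids})
    conc = concordance(genotypes, cohort.phenotypes)
    lines.append(
        f"concordance: {conc.n_case_het}/{conc.n_case_total} cases heterozygous, "
        f"{conc.n_control_homwt}/{conc.n_control_total} controls wild-type, "
        f"complete={conc.complete}"
    )
    seg_test = segregation_test(4, 14, 1 / 3)
    lines.append(
        f"segregation (homozygotes among red offspring of carrier x carrier): "
        f"4/14 vs expected 1/3, exact binomial p={seg_test.p_two_sided:.3f}, "
        f"consistent={seg_test.consistent}"
    )
    pigment = io_mod.packaged_pigment_table()
    by_group = {s.group: s for s in pigment}
    ratio_rr, round_rr = fold_change(by_group["DominantBlack"].mean("ptca_ng_per_mg"),
                                     by_group["RecessiveRed"].mean("ptca_ng_per_mg"))
    ratio_dr, round_dr = fold_change(by_group["DominantBlack"].mean("ptca_ng_per_mg"),
                                     by_group["DominantRed"].mean("ptca_ng_per_mg"))
    comparisons, letters = group_compare(pigment, "ptca_ng_per_mg")
    lines.append(
        f"pigment: eumelanin (PTCA) {round_rr}-fold lower in RecessiveRed "
        f"({ratio_rr:.1f}), {round_dr}-fold lower in DominantRed ({ratio_dr:.1f}) "
        f"than DominantBlack; letters {letters}"
    )

    summary = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(summary)
    return summary
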