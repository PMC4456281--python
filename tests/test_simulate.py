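"""Simulators: reproducibility, Mendelian consistency, recombination model."""

import math

import numpy as np
import pytest

from drmap.model import GenomicRegion, ValidationError
from drmap.simulate import (
    CohortConfig,
    FamilyConfig,
    FunnelSimConfig,
    MapConfig,
    SimConfig,
    TraitConfig,
    simulate_cohort_with_ibd,
    simulate_half_sib_family,
    simulate_panel_genotypes,
    simulate_variant_callset,
)

SMALL_MAP = MapConfig(chromosome_lengths={"1": 5e7, "3": 5e7},
                      markers_per_chromosome=20)
SMALL_TRAIT = TraitConfig(causal_chromosome="3", causal_position_bp=25_000_000)


def small_family_cfg(seed, **family_kwargs):
    return SimConfig(seed=seed, map=SMALL_MAP, trait=SMALL_TRAIT,
                     family=FamilyConfig(**family_kwargs))


class TestHalfSibFamily:
    def test_forced_status_counts(self):
        fam = simulate_half_sib_family(small_family_cfg(1))
        assert len(fam.pedigree.affected_ids()) - 1 == 15  # sire is affected too
        assert len(fam.pedigree.unaffected_ids()) == 17 + 32  # dams unaffected
        assert sum(1 for i in fam.progeny_ids
                   if fam.pedigree.get(i).phenotype == "affected") == 15

    def test_reproducibility_identical_config_identical_output(self):
        a = simulate_half_sib_family(small_family_cfg(7))
        b = simulate_half_sib_family(small_family_cfg(7))
        assert a.genotypes == b.genotypes
        assert (a.paternal_haplotype == b.paternal_haplotype).all()
        c = simulate_half_sib_family(small_family_cfg(8))
        assert c.genotypes != a.genotypes

    def test_mendelian_consistency_exhaustive(self):
        """Every progeny allele is traceable to a sire and a dam allele."""
        fam = simulate_half_sib_family(small_family_cfg(3))
        for k, iid in enumerate(fam.progeny_ids):
            dam = fam.pedigree.get(iid).dam_id
            for mid in fam.marker_map.marker_ids:
                prog = fam.genotypes.get(iid, mid)
                sire = fam.genotypes.get(fam.sire_id, mid)
                dam_gt = fam.genotypes.get(dam, mid)
                assert any(
                    tuple(sorted((s, d))) == prog
                    for s in sire for d in dam_gt
                ), (iid, mid)

    def test_truth_table_matches_genotypes(self):
        """The returned paternal-haplotype truth reproduces each paternal allele."""
        fam = simulate_half_sib_family(small_family_cfg(5))
        for k, iid in enumerate(fam.progeny_ids):
            for j, mid in enumerate(fam.marker_map.marker_ids):
                pat = fam.sire_haplotypes[j, fam.paternal_haplotype[k, j]]
                assert pat in fam.genotypes.get(iid, mid)

    def test_zero_recombination_limit(self):
        """With recomb_rate 0, affected progeny all carry the causal-haplotype
        alleles: zero recombinants at every sire-het marker."""
        from drmap.linkage import linkage_scan
        cfg = SimConfig(
            seed=2,
            map=MapConfig(chromosome_lengths={"3": 5e7},
                          markers_per_chromosome=10, recomb_rate=0.0),
            trait=SMALL_TRAIT,
            family=FamilyConfig(n_affected=16, n_unaffected=16),
        )
        fam = simulate_half_sib_family(cfg)
        assert (fam.paternal_haplotype ==
                fam.trait_haplotype[:, None]).all()
        scan = linkage_scan(fam.pedigree, fam.marker_map, fam.genotypes,
                            fam.sire_id)
        assert all(res.r == 0 for res in scan)

    def test_unlinked_chromosome_theta_half(self):
        """Markers on another chromosome recombine freely: fraction ~ 0.5."""
        cfg = SimConfig(
            seed=4,
            map=MapConfig(chromosome_lengths={"1": 1e7, "3": 5e7},
                          markers_per_chromosome=1),
            trait=SMALL_TRAIT,
            family=FamilyConfig(n_progeny=10_000),
        )
        fam = simulate_half_sib_family(cfg)
        j = fam.marker_map.index("M1_0001")
        frac = np.mean(fam.paternal_haplotype[:, j] != fam.trait_haplotype)
        assert abs(frac - 0.5) <= 3 * 0.5 / math.sqrt(10_000)

    def test_recombination_fraction_unbiased(self):
        """Mean recovered recombinant fraction matches the Haldane theta."""
        rate, d = 1e-8, 10_000_000
        theta = 0.5 * (1 - math.exp(-2 * rate * d))
        fracs = []
        for seed in range(200):
            cfg = SimConfig(
                seed=seed,
                map=MapConfig(chromosome_lengths={"3": 4e7},
                              markers_per_chromosome=1, recomb_rate=rate),
                trait=TraitConfig(causal_chromosome="3",
                                  causal_position_bp=10_000_000),
                family=FamilyConfig(n_progeny=32),
            )
            fam = simulate_half_sib_family(cfg)
            # single marker sits at 2e7: 1e7 bp from the trait locus
            fracs.append(np.mean(fam.paternal_haplotype[:, 0]
                                 != fam.trait_haplotype))
        n_meioses = 200 * 32
        mc_err = math.sqrt(theta * (1 - theta) / n_meioses)
        assert abs(np.mean(fracs) - theta) < 4 * mc_err

    def test_trait_locus_outside_map_rejected(self):
        cfg = SimConfig(seed=0, map=SMALL_MAP,
                        trait=TraitConfig(causal_chromosome="9",
                                          causal_position_bp=1))
        with pytest.raises(ValidationError, match="outside"):
            simulate_half_sib_family(cfg)

    def test_ungenotyped_dams_left_out_of_matrix(self):
        fam = simulate_half_sib_family(small_family_cfg(1, dams_genotyped=False))
        assert not any(fam.genotypes.has_individual(f"DAM{k + 1:03d}")
                       for k in range(32))


class TestCohort:
    def test_all_cases_carry_founder_allele_in_segment(self):
        cfg = SimConfig(seed=6, cohort=CohortConfig(n_cases=95, n_controls=30,
                                                    n_markers=150))
        cohort = simulate_cohort_with_ibd(cfg)
        for mid in cohort.truth_segment_markers:
            allele = cohort.founder_alleles[mid]
            for gt in cohort.genotypes.column(mid, cohort.case_ids):
                assert allele in gt

    def test_planted_discordance_count(self):
        cfg = SimConfig(seed=6, cohort=CohortConfig(n_cases=20, n_controls=10,
                                                    n_markers=100,
                                                    n_discordant_cases=1))
        cohort = simulate_cohort_with_ibd(cfg)
        assert len(cohort.discordant) == 1
        case_id, mid = cohort.discordant[0]
        gt = cohort.genotypes.get(case_id, mid)
        assert cohort.founder_alleles[mid] not in gt

    def test_no_cases_rejected(self):
        cfg = SimConfig(seed=6, cohort=CohortConfig(n_cases=0, n_controls=10))
        with pytest.raises(ValidationError, match="no cases"):
            simulate_cohort_with_ibd(cfg)

    def test_segment_outside_map_rejected(self):
        cfg = SimConfig(seed=6, cohort=CohortConfig(
            n_cases=5, n_controls=5, chromosome_length=1_000_000,
            sharp_boundaries=False))
        with pytest.raises(ValidationError, match="segment"):
            simulate_cohort_with_ibd(cfg)

    def test_reproducibility(self):
        cfg = SimConfig(seed=9, cohort=CohortConfig(n_cases=10, n_controls=10,
                                                    n_markers=50))
        a = simulate_cohort_with_ibd(cfg)
        b = simulate_cohort_with_ibd(cfg)
        assert a.genotypes == b.genotypes

    def test_erosion_shrinks_case_segments_not_rule(self):
        cfg = SimConfig(seed=10, cohort=CohortConfig(
            n_cases=40, n_controls=10, n_markers=150, erosion_mean_bp=200_000))
        cohort = simulate_cohort_with_ibd(cfg)
        # interior markers still satisfy the rule for nearly all cases
        from drmap.ibd import carrier_matrix
        cm = carrier_matrix(cohort.genotypes, cohort.case_ids)
        mid = cohort.truth_segment_markers[len(cohort.truth_segment_markers) // 2]
        j = cm.marker_ids.index(mid)
        assert cm.noncarrier_counts[j] <= 2


class TestVariantCallset:
    REGION = GenomicRegion("3", 7_906_099, 10_462_387)

    def test_count_and_single_causal(self):
        variants = simulate_variant_callset(
            FunnelSimConfig(n_true_variants=24, n_false_variants=30),
            self.REGION, seed=7)
        assert len(variants) == 55
        assert sum(v.truth_label == "causal" for v in variants) == 1

    def test_causal_has_top_quality(self):
        variants = simulate_variant_callset(FunnelSimConfig(), self.REGION, seed=3)
        causal = next(v for v in variants if v.truth_label == "causal")
        assert causal.quality >= max(v.quality for v in variants)
        assert causal.consequence == "missense"
        assert causal.proband_genotype == "het"
        assert not causal.in_control_db

    def test_empty_mixture_gives_empty_list(self):
        assert simulate_variant_callset(
            FunnelSimConfig(n_true_variants=0, n_false_variants=0),
            self.REGION, seed=0) == []

    def test_zero_width_region_rejected(self):
        with pytest.raises(ValidationError):
            GenomicRegion("3", 100, 100)

    def test_panel_genotypes_structure(self):
        variants = simulate_variant_callset(FunnelSimConfig(), self.REGION, seed=5)
        panel = simulate_panel_genotypes(variants, n_panel=20, seed=5)
        causal = next(v for v in variants if v.truth_label == "causal")
        assert all(z == "het" for z in panel[causal.variant_id].values())
        assert all(len(panel[v.variant_id]) == 20 for v in variants)


class TestSimConfigYaml:
    def test_round_trip(self, tmp_path):
        cfg = SimConfig(seed=123, map=SMALL_MAP, trait=SMALL_TRAIT,
                        cohort=CohortConfig(n_cases=12, n_controls=7))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back == cfg
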