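"""Two-point linkage: Mendelian deduction, recombinant counting, LOD, regions."""

import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from drmap.linkage import (
    AMBIGUOUS,
    INCONSISTENT,
    MISSING,
    LinkageRegion,
    MeiosisCall,
    TwoPointResult,
    count_recombinants,
    critical_region,
    infer_paternal_allele,
    linkage_scan,
    two_point_lod,
)
from drmap.model import Marker, MarkerMap, ValidationError
from drmap.simulate import (
    FamilyConfig,
    MapConfig,
    SimConfig,
    TraitConfig,
    simulate_half_sib_family,
)
from conftest import build_family

GTS = [("A", "A"), ("A", "B"), ("B", "B"), None]


def mendelian_oracle(dam_gt, progeny_gt):
    """Brute-force set of sire alleles consistent with the trio."""
    if progeny_gt is None:
        return None
    dam_alleles = dam_gt if dam_gt is not None else ("A", "B")
    consistent = set()
    for s in ("A", "B"):
        for d in dam_alleles:
            if tuple(sorted((s, d))) == progeny_gt:
                consistent.add(s)
    return consistent


class TestInferPaternalAllele:
    def test_forced_subtraction(self):
        assert infer_paternal_allele(("A", "B"), ("A", "A"), ("A", "B")) == "B"
        assert infer_paternal_allele(("A", "B"), ("B", "B"), ("B", "B")) == "B"
        assert infer_paternal_allele(("A", "B"), ("A", "A"), ("A", "A")) == "A"

    def test_both_phases_consistent_is_ambiguous(self):
        assert infer_paternal_allele(("A", "B"), ("A", "B"), ("A", "B")) == AMBIGUOUS

    def test_exhaustive_against_mendelian_oracle(self):
        """All dam x progeny genotype combinations match brute-force subtraction."""
        for dam_gt, prog_gt in itertools.product(GTS, GTS):
            got = infer_paternal_allele(("A", "B"), dam_gt, prog_gt)
            expected = mendelian_oracle(dam_gt, prog_gt)
            if prog_gt is None:
                assert got == MISSING
            elif not expected:
                assert got == INCONSISTENT
            elif len(expected) == 2:
                assert got == AMBIGUOUS
            else:
                assert got == expected.pop()

    def test_homozygous_sire_rejected(self):
        with pytest.raises(ValidationError):
            infer_paternal_allele(("A", "A"), ("A", "A"), ("A", "A"))


def brute_force_r(calls):
    """Minimum mismatch count over both explicit phase assignments."""
    informative = [c for c in calls if c.informative]
    best = None
    for causal_allele in ("A", "B"):
        m = sum(1 for c in informative
                if (c.paternal_allele == causal_allele)
                != (c.trait_transmission == "causal"))
        best = m if best is None else min(best, m)
    return best or 0, len(informative)


class TestCountRecombinants:
    def test_perfect_cosegregation(self):
        calls = [MeiosisCall(f"p{k}", "A", "causal") for k in range(15)]
        calls += [MeiosisCall(f"q{k}", "B", "wildtype") for k in range(17)]
        assert count_recombinants(calls) == (0, 32)

    def test_half_mismatches_give_theta_half(self):
        calls = [MeiosisCall(f"p{k}", "A", "causal") for k in range(5)]
        calls += [MeiosisCall(f"q{k}", "A", "wildtype") for k in range(5)]
        # 5 mismatches under either phase
        assert count_recombinants(calls) == (5, 10)

    @given(st.lists(st.tuples(st.sampled_from(["A", "B", AMBIGUOUS, MISSING]),
                              st.sampled_from(["causal", "wildtype", None])),
                    min_size=1, max_size=12))
    def test_matches_brute_force_over_both_phases(self, table):
        calls = [MeiosisCall(f"p{k}", a, t) for k, (a, t) in enumerate(table)]
        assert count_recombinants(calls) == brute_force_r(calls)

    @given(st.lists(st.tuples(st.sampled_from(["A", "B"]),
                              st.sampled_from(["causal", "wildtype"])),
                    min_size=1, max_size=20))
    def test_phase_symmetry_under_allele_relabeling(self, table):
        calls = [MeiosisCall(f"p{k}", a, t) for k, (a, t) in enumerate(table)]
        swapped = [MeiosisCall(c.progeny_id, "A" if c.paternal_allele == "B" else "B",
                               c.trait_transmission) for c in calls]
        assert count_recombinants(calls) == count_recombinants(swapped)


class TestTwoPointLod:
    def test_complete_linkage_in_32_meioses(self):
        theta, lod = two_point_lod(0, 32)
        assert theta == 0.0
        assert lod == pytest.approx(32 * math.log10(2), abs=1e-12)
        assert round(lod, 1) == 9.6

    def test_one_recombinant_closed_form(self):
        # log10[(1/32)(31/32)^31 / 0.5^32] evaluated independently
        theta, lod = two_point_lod(1, 32)
        assert theta == pytest.approx(1 / 32)
        assert lod == pytest.approx(7.7004, abs=5e-4)

    def test_free_recombination_gives_zero(self):
        assert two_point_lod(5, 10)[1] == pytest.approx(0.0, abs=1e-12)

    def test_r_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            two_point_lod(5, 4)

    @pytest.mark.parametrize("n", [1, 2, 7, 16, 33, 64])
    def test_lod_strictly_decreasing_in_r(self, n):
        lods = [two_point_lod(r, n)[1] for r in range(n // 2 + 1)]
        assert all(a > b for a, b in zip(lods, lods[1:]))
        assert lods[0] == pytest.approx(n * math.log10(2))


def scan_oracle(pedigree, marker_map, genotypes, sire_id):
    """Exhaustive per-marker enumeration independent of linkage_scan."""
    out = {}
    for marker in marker_map:
        sire_gt = genotypes.get(sire_id, marker.marker_id)
        if sire_gt is None or sire_gt[0] == sire_gt[1]:
            continue
        informative = []
        for prog in pedigree.progeny_of(sire_id):
            if prog.phenotype not in ("affected", "unaffected"):
                continue
            prog_gt = genotypes.get(prog.iid, marker.marker_id)
            dam_gt = (genotypes.get(prog.dam_id, marker.marker_id)
                      if prog.dam_id and genotypes.has_individual(prog.dam_id)
                      else None)
            possible = mendelian_oracle(dam_gt, prog_gt)
            if possible is None or len(possible) != 1:
                continue
            informative.append((possible.pop(), prog.phenotype == "affected"))
        n = len(informative)
        best = None
        for phase in ("A", "B"):
            m = sum(1 for allele, affected in informative
                    if (allele == phase) != affected)
            best = m if best is None else min(best, m)
        out[marker.marker_id] = (best or 0, n)
    return out


class TestLinkageScan:
    def test_matches_enumeration_oracle_on_small_families(self):
        """Scan (r, n) equals exhaustive enumeration on 12 progeny x 6 markers."""
        import numpy as np
        rng = np.random.default_rng(7)
        for rep in range(25):
            specs = [(f"M{j}", "1", 1000 * (j + 1)) for j in range(6)]
            sire_gt = {f"M{j}": ("A", "B") if rng.random() < 0.8
                       else (("A", "A") if rng.random() < 0.5 else ("B", "B"))
                       for j in range(6)}
            def rand_gt():
                k = rng.integers(4)
                return GTS[k]
            dams = {f"D{i}": {f"M{j}": rand_gt() for j in range(6)}
                    for i in range(12)}
            progeny = [(f"P{i}", "affected" if rng.random() < 0.5 else "unaffected",
                        {f"M{j}": rand_gt() for j in range(6)})
                       for i in range(12)]
            pedigree, marker_map, gm = build_family(specs, sire_gt, progeny, dams)
            expected = scan_oracle(pedigree, marker_map, gm, "SIRE")
            results = linkage_scan(pedigree, marker_map, gm, "SIRE")
            got = {r.marker_id: (r.r, r.n_informative) for r in results}
            assert got == expected

    def test_sire_homozygous_everywhere_gives_empty_scan(self, toy_family):
        pedigree, marker_map, gm = toy_family
        gm.set("SIRE", "M1", ("A", "A"))
        gm.set("SIRE", "M2", ("B", "B"))
        assert linkage_scan(pedigree, marker_map, gm, "SIRE") == []

    def test_missing_sire_rejected(self, toy_family):
        pedigree, marker_map, gm = toy_family
        with pytest.raises(ValidationError, match="NOSIRE"):
            linkage_scan(pedigree, marker_map, gm, "NOSIRE")

    def test_simulated_top_marker_is_truth_linked(self):
        cfg = SimConfig(seed=11, map=MapConfig(
            chromosome_lengths={"1": 6e7, "2": 6e7, "3": 6e7},
            markers_per_chromosome=40),
            trait=TraitConfig(causal_chromosome="3", causal_position_bp=30_000_000))
        fam = simulate_half_sib_family(cfg)
        scan = linkage_scan(fam.pedigree, fam.marker_map, fam.genotypes, fam.sire_id)
        best = max(scan, key=lambda r: r.lod)
        assert best.chromosome == "3"
        assert abs(best.position_bp - 30_000_000) < 10_000_000

    def test_genome_scale_scan_covers_all_het_markers(self):
        """Genome-scale family: one result per sire-heterozygous marker."""
        cfg = SimConfig(seed=3)
        fam = simulate_half_sib_family(cfg)
        n_het = sum(
            1 for mid in fam.marker_map.marker_ids
            if (gt := fam.genotypes.get(fam.sire_id, mid)) and gt[0] != gt[1]
        )
        scan = linkage_scan(fam.pedigree, fam.marker_map, fam.genotypes, fam.sire_id)
        assert len(scan) == n_het > 0

    def test_recovery_rate_over_replicates(self):
        """The truth-linked block tops the genome-wide scan in >=95% of sims."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = SimConfig(seed=seed, map=MapConfig(
                chromosome_lengths={"1": 6e7, "2": 6e7, "3": 6e7},
                markers_per_chromosome=30),
                trait=TraitConfig(causal_chromosome="3",
                                  causal_position_bp=30_000_000))
            fam = simulate_half_sib_family(cfg)
            scan = linkage_scan(fam.pedigree, fam.marker_map, fam.genotypes,
                                fam.sire_id)
            best = max(scan, key=lambda r: r.lod)
            if best.chromosome == "3" and abs(best.position_bp - 30_000_000) < 1.5e7:
                hits += 1
        assert hits >= 0.95 * n_rep


def _result(mid, chrom, pos, r, n=32):
    theta, lod = two_point_lod(r, n)
    return TwoPointResult(mid, chrom, pos, n, r, theta, lod)


class TestCriticalRegion:
    def test_printed_flank_coordinates_give_10_7_mb(self):
        scan = [
            _result("BTA-21472-no-rs", "3", 5_886_143, 1),
            _result("mid1", "3", 8_000_000, 0),
            _result("mid2", "3", 12_000_000, 0),
            _result("ARS-BFGL-NGS-20167", "3", 16_557_950, 1),
        ]
        marker_map = MarkerMap([Marker(r.marker_id, "3", r.position_bp) for r in scan])
        region = critical_region(scan, marker_map)
        assert (region.start_marker_id, region.end_marker_id) == \
            ("BTA-21472-no-rs", "ARS-BFGL-NGS-20167")
        assert region.width_mb == 10.7

    def test_single_zero_marker_spans_its_neighbors(self):
        scan = [_result("L", "3", 1_000_000, 2), _result("C", "3", 2_000_000, 0),
                _result("R", "3", 3_000_000, 1)]
        marker_map = MarkerMap([Marker(r.marker_id, "3", r.position_bp) for r in scan])
        region = critical_region(scan, marker_map)
        assert (region.start_bp, region.end_bp) == (1_000_000, 3_000_000)

    def test_equal_lod_blocks_resolve_to_leftmost(self):
        scan = [
            _result("A1", "3", 1_000_000, 1), _result("A2", "3", 2_000_000, 0),
            _result("A3", "3", 3_000_000, 1), _result("B1", "3", 4_000_000, 0),
            _result("B2", "3", 5_000_000, 1),
        ]
        marker_map = MarkerMap([Marker(r.marker_id, "3", r.position_bp) for r in scan])
        region = critical_region(scan, marker_map)
        assert (region.start_marker_id, region.end_marker_id) == ("A1", "A3")

    def test_block_touching_chromosome_end_flagged_open(self):
        scan = [_result("M1", "3", 1_000_000, 0), _result("M2", "3", 2_000_000, 0),
                _result("M3", "3", 3_000_000, 1)]
        marker_map = MarkerMap([Marker(r.marker_id, "3", r.position_bp) for r in scan])
        region = critical_region(scan, marker_map)
        assert region.open_left and not region.open_right
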