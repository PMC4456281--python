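"""Two-point linkage in a simulated half-sib family.

Simulates one sire heterozygous for a fully penetrant dominant coat-colour
allele with 15 affected and 17 unaffected genotyped progeny (plus dams),
scans every sire-heterozygous marker, and extracts the critical region
bounded by the nearest flanking recombinant markers.
"""

from drmap.linkage import critical_region, linkage_scan, two_point_lod
from drmap.simulate import SimConfig, simulate_half_sib_family

cfg = SimConfig(seed=1)
fam = simulate_half_sib_family(cfg)
scan = linkage_scan(fam.pedigree, fam.marker_map, fam.genotypes, fam.sire_id)
best = max(scan, key=lambda r: r.lod)
region = critical_region(scan, fam.marker_map)

print(f"scanned {len(scan)} sire-heterozygous markers")
print(f"top marker {best.marker_id} on chromosome {best.chromosome} at "
      f"{best.position_bp:,} bp: LOD {best.lod:.2f} "
      f"({best.r} recombinants in {best.n_informative} informative meioses)")
print(f"critical region {region.chromosome}:{region.start_bp:,}-"
      f"{region.end_bp:,} ({region.width_mb} Mb), bounded by "
      f"{region.start_marker_id} and {region.end_marker_id}")

# The LOD ceiling for a marker with zero recombinants in n meioses is
# n*log10(2); ambiguous meioses (dam shares the sire's genotype) reduce n
# below the 32 progeny, which is why the top LOD can sit below the ceiling.
theta, ceiling = two_point_lod(0, 32)
print(f"for comparison, a fully informative co-segregating marker in all "
      f"32 meioses would reach LOD {ceiling:.2f}")
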