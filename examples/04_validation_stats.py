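"""Validation statistics: concordance, segregation, pigment chemistry.

Checks complete genotype-phenotype concordance of a diagnostic variant
(78 heterozygous cases, 283 wild-type controls), tests observed homozygote
counts against Mendelian expectation, and analyses the packaged hair-pigment
summary table (fold changes of group means and pairwise Welch t tests).
"""

from drmap.io import packaged_pigment_table
from drmap.validate import concordance, fold_change, group_compare, segregation_test

# diagnostic-marker concordance
genotypes = {f"DR{k}": "het" for k in range(78)}
genotypes.update({f"WT{k}": "hom_ref" for k in range(283)})
phenotypes = {iid: ("case" if iid.startswith("DR") else "control")
              for iid in genotypes}
report = concordance(genotypes, phenotypes)
print(f"concordance: {report.n_case_het}/{report.n_case_total} cases het, "
      f"{report.n_control_homwt}/{report.n_control_total} controls wild-type, "
      f"complete = {report.complete}")

# homozygote viability: among red offspring of two carriers, 1/3 of red
# animals are expected homozygous; 4 of 14 observed.
seg = segregation_test(4, 14, 1 / 3)
print(f"segregation: 4/14 homozygotes vs expected 1/3 -> exact binomial "
      f"p = {seg.p_two_sided:.3f} (consistent at alpha 0.05: {seg.consistent})")

# pigment chemistry from the packaged summary table
stats = packaged_pigment_table()
by_group = {s.group: s for s in stats}
db, dr, rr = (by_group[g] for g in
              ("DominantBlack", "DominantRed", "RecessiveRed"))
for label, num, den in (
    ("RecessiveRed", db, rr),
    ("DominantRed", db, dr),
):
    ratio, rounded = fold_change(num.mean("ptca_ng_per_mg"),
                                 den.mean("ptca_ng_per_mg"))
    print(f"eumelanin marker (PTCA) {rounded}-fold lower in {label} "
          f"than DominantBlack ({ratio:.1f})")

comparisons, letters = group_compare(stats, "ptca_ng_per_mg")
print(f"PTCA letter display (groups sharing no letter differ at P<0.05): "
      f"{letters}")
for c in comparisons:
    print(f"  {c.group_i} vs {c.group_j}: t = {c.t:.2f}, df = {c.df:.1f}, "
          f"p = {c.p:.4f}")
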