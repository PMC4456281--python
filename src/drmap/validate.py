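"""Post-mapping validation statistics.

Three independent lines of evidence are quantified here: (1) complete
genotype–phenotype concordance of the diagnostic SNP (every affected animal
heterozygous, every control homozygous wild-type); (2) Mendelian
segregation — exact binomial tests against the expected transmission ratio
(1/2 for carrier x wild-type matings; among red offspring of carrier x
carrier matings the expected homozygote fraction is 1/3, which is the test
used to establish homozygote viability); and (3) hair pigment chemistry —
fold changes of group means and pairwise Welch t tests computed from the
published summary statistics (mean, SE, n per group), with a compact letter
display marking groups that differ at P < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
from scipy import stats

from .model import PigmentGroupStats, ValidationError


@dataclass
class ConcordanceReport:
    n_case_total: int
    n_case_het: int
    n_control_total: int
    n_control_homwt: int
    violations: list[tuple[str, str, str]] = field(default_factory=list)
    untyped: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.violations


@dataclass
class SegregationTest:
    n_observed: int
    n_total: int
    expected_proportion: float
    p_two_sided: float
    alpha: float = 0.05

    @property
    def consistent(self) -> bool:
        return self.p_two_sided >= self.alpha


@dataclass
class PairwiseComparison:
    group_i: str
    group_j: str
    t: float
    df: float
    p: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def concordance(genotypes: Mapping[str, Optional[str]],
                phenotypes: Mapping[str, str],
                case_expected: str = "het",
                control_expected: str = "hom_ref") -> ConcordanceReport:
    """Exact genotype–phenotype concordance of a diagnostic marker.

    ``genotypes`` maps individual id to zygosity at the diagnostic variant
    ('hom_ref' | 'het' | 'hom_alt' | None); ``phenotypes`` maps id to
    'case'/'affected' or 'control'/'unaffected'. Individuals with a
    phenotype but no genotype are listed as untyped, not as violations.
    """
    report = ConcordanceReport(0, 0, 0, 0)
    n_typed = 0
    for iid, pheno in phenotypes.items():
        if pheno in ("case", "affected"):
            expected, is_case = case_expected, True
        elif pheno in ("control", "unaffected"):
            expected, is_case = control_expected, False
        else:
            continue
        zyg = genotypes.get(iid)
        if zyg is None or zyg == "missing":
            report.untyped.append(iid)
            continue
        n_typed += 1
        if is_case:
            report.n_case_total += 1
            if zyg == expected:
                report.n_case_het += 1
            else:
                report.violations.append((iid, zyg, pheno))
        else:
            report.n_control_total += 1
            if zyg == expected:
                report.n_control_homwt += 1
            else:
                report.violations.append((iid, zyg, pheno))
    if n_typed == 0:
        raise ValidationError("no typed individuals")
    return report


def segregation_test(n_observed: int, n_total: int, expected_proportion: float,
                     alpha: float = 0.05) -> SegregationTest:
    """Exact two-sided binomial test of an observed segregation count.

    Two-sided p = sum of probabilities of all outcomes no more likely than
    the observed count under Binomial(n_total, expected_proportion). The
    exact test is used because segregation counts here are small.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    if not 0 <= n_observed <= n_total:
        raise ValidationError("need 0 <= n_observed <= n_total")
    if not 0 < expected_proportion < 1:
        raise ValidationError("expected_proportion must be in (0, 1)")
    p = stats.binomtest(n_observed, n_total, expected_proportion).pvalue
    return SegregationTest(n_observed, n_total, expected_proportion,
                           float(min(p, 1.0)), alpha)


def fold_change(mean_numerator: float, mean_denominator: float) -> tuple[float, int]:
    """Ratio of two group means and its nearest-integer rounding."""
    if mean_denominator <= 0:
        raise ValidationError("denominator mean must be > 0")
    ratio = mean_numerator / mean_denominator
    return ratio, round(ratio)


def welch_from_summary(m1: float, se1: float, n1: int,
                       m2: float, se2: float, n2: int) -> PairwiseComparison:
    """Welch t test from summary statistics (group means and SEs).

    t = (m1 - m2) / sqrt(se1^2 + se2^2); df by Welch–Satterthwaite on the
    squared SEs. Only summary statistics are needed, which is what published
    pigment tables provide.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    v1, v2 = se1 ** 2, se2 ** 2
    if v1 + v2 == 0:
        return PairwiseComparison("", "", 0.0, float(n1 + n2 - 2), 1.0)
    t = (m1 - m2) / (v1 + v2) ** 0.5
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairwiseComparison("", "", t, df, min(p, 1.0))


def compact_letter_display(groups: Sequence[str],
                           comparisons: Sequence[PairwiseComparison],
                           alpha: float = 0.05) -> dict[str, str]:
    """Assign letters so that groups sharing no letter differ at P < alpha.

    Letters correspond to maximal cliques of the non-significance graph, so
    two groups share a letter exactly when their pairwise p >= alpha.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for c in comparisons:
        if not c.significant(alpha):
            g.add_edge(c.group_i, c.group_j)
    order = {name: k for k, name in enumerate(groups)}
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(order[x] for x in c))
    letters: dict[str, str] = {name: "" for name in groups}
    for k, clique in enumerate(cliques):
        letter = chr(ord("a") + k)
        for name in clique:
            letters[name] += letter
    return letters


def group_compare(pigment_stats: Sequence[PigmentGroupStats], assay: str,
                  alpha: float = 0.05) -> tuple[list[PairwiseComparison], dict[str, str]]:
    """All pairwise Welch t tests for one assay, plus the letter display.

    No multiple-testing correction is applied: the published letters are
    unadjusted pairwise comparisons.
    """
    if len(pigment_stats) < 2:
        raise ValidationError("need at least two groups")
    comparisons: list[PairwiseComparison] = []
    for i in range(len(pigment_stats)):
        for j in range(i + 1, len(pigment_stats)):
            a, b = pigment_stats[i], pigment_stats[j]
            c = welch_from_summary(a.mean(assay), a.se(assay), a.n,
                                   b.mean(assay), b.se(assay), b.n)
            c.group_i, c.group_j = a.group, b.group
            comparisons.append(c)
    letters = compact_letter_display([s.group for s in pigment_stats],
                                     comparisons, alpha)
    return comparisons, letters
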