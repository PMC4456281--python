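"""Case/control allelic association scan with carrier diagnostics.

Each marker is tested with a 1-df chi-square on the 2x2 allele-count table
(cases/controls x allele A/B, continuity correction off, missing genotypes
excluded). The per-marker report also carries the fraction of cases that
carry at least one copy of the case-enriched allele and that allele's
frequency in controls — the diagnostics that reveal whether a top marker
would work as a genetic test (a high control frequency means many false
positives even under complete case carriage).

An optional permutation p-value (phenotype labels permuted, within sibship
clusters when given) is available for designs where the plain allelic test's
independence assumption is questionable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import Genotype, GenotypeMatrix, MarkerMap, ValidationError


@dataclass
class AssocResult:
    marker_id: str
    chromosome: str
    position_bp: int
    allele_counts: np.ndarray  # 2x2: rows case/control, cols allele A/B
    alleles: tuple[str, ...]
    chi2: float
    p: float
    neglog10p: float
    assoc_allele: Optional[str]
    case_carrier_fraction: float
    control_assoc_allele_freq: float
    monomorphic: bool = False
    n_missing: int = 0
    perm_p: Optional[float] = None


def _allele_counts(genotypes: Sequence[Genotype],
                   alleles: Sequence[str]) -> np.ndarray:
    counts = np.zeros(len(alleles), dtype=int)
    index = {a: i for i, a in enumerate(alleles)}
    for gt in genotypes:
        if gt is None:
            continue
        for a in gt:
            counts[index[a]] += 1
    return counts


def _chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if n == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, 1.0
    expected = np.outer(row, col) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, max(p, np.finfo(float).tiny)


def allelic_test(case_genotypes: Sequence[Genotype],
                 control_genotypes: Sequence[Genotype],
                 marker_id: str = "", chromosome: str = "",
                 position_bp: int = 1) -> AssocResult:
    """1-df allelic chi-square on the case/control x allele 2x2 table.

    Requires at least one non-missing case and control genotype. Monomorphic
    markers are flagged and given chi2 = 0, p = 1.
    """
    n_missing = sum(1 for gt in list(case_genotypes) + list(control_genotypes)
                    if gt is None)
    cases = [gt for gt in case_genotypes if gt is not None]
    controls = [gt for gt in control_genotypes if gt is not None]
    if not cases or not controls:
        raise ValidationError("need >=1 non-missing case and control genotype")
    alleles = sorted({a for gt in cases + controls for a in gt})
    if len(alleles) > 2:
        raise ValidationError(f"marker {marker_id!r}: more than two alleles {alleles}")

    if len(alleles) == 1:
        counts = np.array([[2 * len(cases), 0], [2 * len(controls), 0]], dtype=int)
        return AssocResult(
            marker_id=marker_id, chromosome=chromosome, position_bp=position_bp,
            allele_counts=counts, alleles=(alleles[0],), chi2=0.0, p=1.0,
            neglog10p=0.0, assoc_allele=None, case_carrier_fraction=1.0,
            control_assoc_allele_freq=1.0, monomorphic=True, n_missing=n_missing,
        )

    case_counts = _allele_counts(cases, alleles)
    control_counts = _allele_counts(controls, alleles)
    table = np.vstack([case_counts, control_counts])
    chi2, p = _chi2_2x2(table)

    case_freq = case_counts / case_counts.sum()
    control_freq = control_counts / control_counts.sum()
    assoc_idx = int(np.argmax(case_freq - control_freq))
    assoc_allele = alleles[assoc_idx]
    carriers = sum(1 for gt in cases if assoc_allele in gt)
    return AssocResult(
        marker_id=marker_id, chromosome=chromosome, position_bp=position_bp,
        allele_counts=table, alleles=tuple(alleles), chi2=chi2, p=p,
        neglog10p=-np.log10(p), assoc_allele=assoc_allele,
        case_carrier_fraction=carriers / len(cases),
        control_assoc_allele_freq=float(control_freq[assoc_idx]),
        monomorphic=False,
        n_missing=n_missing,
    )


def carrier_check(case_genotypes: Sequence[Genotype],
                  allele: str) -> tuple[bool, int, int]:
    """Do all cases carry >=1 copy of ``allele``?

    Missing genotypes count as neither carrier nor non-carrier; they are
    returned as ``n_missing``. Returns (all_cases_carry, n_noncarriers,
    n_missing); raises if every case genotype is missing.
    """
    typed = [gt for gt in case_genotypes if gt is not None]
    n_missing = len(list(case_genotypes)) - len(typed)
    if not typed:
        raise ValidationError("all case genotypes missing")
    n_noncarriers = sum(1 for gt in typed if allele not in gt)
    return n_noncarriers == 0, n_noncarriers, n_missing


def association_scan(genotypes: GenotypeMatrix,
                     phenotypes: Mapping[str, str],
                     marker_map: MarkerMap) -> list[AssocResult]:
    """Per-marker allelic tests over a cohort, sorted by genome position.

    ``phenotypes`` maps individual id to 'case'/'affected' or
    'control'/'unaffected'; other labels are ignored.
    """
    case_ids = [i for i in genotypes.individuals
                if phenotypes.get(i) in ("case", "affected")]
    control_ids = [i for i in genotypes.individuals
                   if phenotypes.get(i) in ("control", "unaffected")]
    if not case_ids:
        raise ValidationError("no cases in cohort")
    if not control_ids:
        raise ValidationError("no controls in cohort")
    results = []
    for marker in marker_map:
        results.append(allelic_test(
            genotypes.column(marker.marker_id, case_ids),
            genotypes.column(marker.marker_id, control_ids),
            marker_id=marker.marker_id,
            chromosome=marker.chromosome,
            position_bp=marker.position_bp,
        ))
    return sorted(results, key=lambda res: (res.chromosome, res.position_bp))


def top_association(results: Sequence[AssocResult]) -> AssocResult:
    """The most significant marker of a scan (ties: lowest position)."""
    if not results:
        raise ValidationError("empty scan")
    return min(results, key=lambda res: (res.p, res.chromosome, res.position_bp))


def permutation_pvalue(genotypes: GenotypeMatrix, phenotypes: Mapping[str, str],
                       marker_id: str, n_permutations: int = 999,
                       clusters: Optional[Mapping[str, str]] = None,
                       seed: int = 0) -> float:
    """Permutation p-value for one marker's allelic chi-square.

    Phenotype labels are permuted across individuals, or within the clusters
    (e.g. sibships) given by ``clusters``, which preserves family structure
    the plain allelic test ignores. Returns (1 + #{chi2_perm >= chi2_obs}) /
    (1 + n_permutations).
    """
    rng = np.random.default_rng(seed)
    ids = [i for i in genotypes.individuals
           if phenotypes.get(i) in ("case", "affected", "control", "unaffected")]
    labels = np.array([phenotypes[i] in ("case", "affected") for i in ids])
    gts = genotypes.column(marker_id, ids)

    def chi2_of(mask: np.ndarray) -> float:
        cases = [gt for gt, m in zip(gts, mask) if m]
        controls = [gt for gt, m in zip(gts, mask) if not m]
        if not any(gt is not None for gt in cases) or \
           not any(gt is not None for gt in controls):
            return 0.0
        return allelic_test(cases, controls).chi2

    observed = chi2_of(labels)
    if clusters is None:
        groups = {None: np.arange(len(ids))}
    else:
        groups = {}
        for k, iid in enumerate(ids):
            groups.setdefault(clusters.get(iid), []).append(k)
        groups = {c: np.asarray(v) for c, v in groups.items()}

    n_extreme = 0
    for _ in range(n_permutations):
        perm = labels.copy()
        for idxs in groups.values():
            perm[idxs] = perm[rng.permutation(idxs)]
        if chi2_of(perm) >= observed - 1e-12:
            n_extreme += 1
    return (1 + n_extreme) / (1 + n_permutations)
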