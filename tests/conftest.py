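import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from drmap.model import GenotypeMatrix, Individual, Marker, MarkerMap, Pedigree


def build_family(marker_specs, sire_gt, progeny, dams=None):
    """Assemble a tiny half-sib family for linkage tests.

    marker_specs: list of (marker_id, chrom, pos)
    sire_gt: dict marker_id -> genotype tuple
    progeny: list of (iid, phenotype, dict marker_id -> genotype)
    dams: optional dict iid -> dict marker_id -> genotype (one dam per progeny)
    """
    marker_map = MarkerMap([Marker(*spec) for spec in marker_specs])
    dams = dams or {}
    individuals = [Individual("SIRE", sex="male", phenotype="affected")]
    for dam_id in dams:
        individuals.append(Individual(dam_id, sex="female", phenotype="unaffected"))
    dam_of = {}
    for k, (iid, pheno, _) in enumerate(progeny):
        dam_id = list(dams)[k] if k < len(dams) else None
        dam_of[iid] = dam_id
        individuals.append(Individual(iid, sire_id="SIRE", dam_id=dam_id,
                                      phenotype=pheno))
    pedigree = Pedigree(individuals)
    ids = [rec.iid for rec in individuals]
    gm = GenotypeMatrix(ids, marker_map.marker_ids,
                        np.full((len(ids), len(marker_map)), None, dtype=object))
    for mid, gt in sire_gt.items():
        gm.set("SIRE", mid, gt)
    for dam_id, gts in dams.items():
        for mid, gt in gts.items():
            gm.set(dam_id, mid, gt)
    for iid, _, gts in progeny:
        for mid, gt in gts.items():
            gm.set(iid, mid, gt)
    return pedigree, marker_map, gm


@pytest.fixture
def toy_family():
    """Two markers, four progeny, fully informative (dams homozygous)."""
    dams = {f"D{k}": {"M1": ("B", "B"), "M2": ("B", "B")} for k in range(1, 5)}
    progeny = [
        ("P1", "affected", {"M1": ("A", "B"), "M2": ("A", "B")}),
        ("P2", "affected", {"M1": ("A", "B"), "M2": ("B", "B")}),
        ("P3", "unaffected", {"M1": ("B", "B"), "M2": ("B", "B")}),
        ("P4", "unaffected", {"M1": ("B", "B"), "M2": ("A", "B")}),
    ]
    return build_family(
        [("M1", "3", 1_000_000), ("M2", "3", 2_000_000)],
        {"M1": ("A", "B"), "M2": ("A", "B")},
        progeny, dams,
    )
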