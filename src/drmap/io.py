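"""Readers and writers for the formats the pipeline touches.

Array genotypes travel as PLINK-style PED/MAP text (alleles as pairs, ``0``
missing; the MAP cM column is ignored), sequencing variants as VCF v4.2
(consequence class in INFO/CSQCLASS, control-database presence as the
INFO/INCTRLDB flag, proband zygosity from FORMAT/GT), and pigment summary
statistics as TSV. A published hair-pigment summary table for the three
Holstein coat-colour groups ships as package data
(``data/holstein_hair_pigment.tsv``).
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .model import (
    CONSEQUENCES,
    Genotype,
    GenotypeMatrix,
    Individual,
    Marker,
    MarkerMap,
    ParseError,
    Pedigree,
    PigmentGroupStats,
    PIGMENT_ASSAYS,
    ValidationError,
    VariantRecord,
    normalize_genotype,
)

log = logging.getLogger(__name__)

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_PHENO_FROM_PED = {"1": "unaffected", "2": "affected"}
_PHENO_TO_PED = {"unaffected": "1", "affected": "2", "unknown": "0"}

#: INFO key carrying the functional-consequence class of each variant.
VCF_CONSEQUENCE_KEY = "CSQCLASS"
#: INFO flag marking variants present in the control sequencing cohort.
VCF_CONTROL_DB_KEY = "INCTRLDB"


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> MarkerMap:
    """Read a PLINK MAP file (CHR ID [cM] POS; the cM column is ignored)."""
    markers: list[Marker] = []
    path = str(map_path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 4:
                chrom, mid, _cm, pos = fields
            elif len(fields) == 3:
                chrom, mid, pos = fields
            else:
                raise ParseError(
                    f"expected 3 or 4 columns, got {len(fields)}", path, lineno
                )
            try:
                position = int(pos)
            except ValueError:
                raise ParseError(f"bad position {pos!r}", path, lineno) from None
            markers.append(Marker(mid, chrom, position))
    return MarkerMap(markers)


def read_pedmap(ped_path: str | Path,
                map_path: str | Path) -> tuple[Pedigree, MarkerMap, GenotypeMatrix]:
    """Read a PED/MAP pair into the shared data model.

    Missing genotypes (allele code ``0``) are preserved as missing; a
    half-missing pair is treated as fully missing. Malformed lines raise
    :class:`ParseError` with the line number; duplicate individual ids or
    parents absent from the file raise :class:`ValidationError`.
    """
    marker_map = read_map(map_path)
    n_markers = len(marker_map)

    individuals: list[Individual] = []
    rows: list[list[Genotype]] = []
    iids: list[str] = []
    path = str(ped_path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_markers:
                raise ParseError(
                    f"expected {6 + 2 * n_markers} columns "
                    f"(6 + 2 x {n_markers} markers), got {len(fields)}",
                    path, lineno,
                )
            fid, iid, pat, mat, sex, pheno = fields[:6]
            individuals.append(Individual(
                iid=iid,
                sire_id=None if pat == "0" else pat,
                dam_id=None if mat == "0" else mat,
                sex=_SEX_FROM_PED.get(sex, "unknown"),
                phenotype=_PHENO_FROM_PED.get(pheno, "unknown"),
                fid=fid,
            ))
            iids.append(iid)
            alleles = fields[6:]
            rows.append([
                normalize_genotype(alleles[2 * j], alleles[2 * j + 1])
                for j in range(n_markers)
            ])

    pedigree = Pedigree(individuals)  # validates ids, parents, cycles
    calls = np.full((len(iids), n_markers), None, dtype=object)
    for i, row in enumerate(rows):
        calls[i, :] = row
    genotypes = GenotypeMatrix(iids, marker_map.marker_ids, calls)
    genotypes.validate_against(marker_map)
    return pedigree, marker_map, genotypes


def write_pedmap(pedigree: Pedigree, marker_map: MarkerMap, genotypes: GenotypeMatrix,
                 ped_path: str | Path, map_path: str | Path) -> None:
    """Write the data model back to a PED/MAP pair (round-trip safe)."""
    with open(map_path, "w") as fh:
        for m in marker_map:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\n")
    with open(ped_path, "w") as fh:
        for rec in pedigree:
            fields = [
                rec.fid, rec.iid,
                rec.sire_id or "0", rec.dam_id or "0",
                _SEX_TO_PED[rec.sex], _PHENO_TO_PED[rec.phenotype],
            ]
            if genotypes.has_individual(rec.iid):
                for gt in genotypes.row(rec.iid):
                    fields.extend(gt if gt is not None else ("0", "0"))
            else:
                fields.extend(["0"] * (2 * len(marker_map)))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _zygosity_from_gt(gt: tuple, alt_index: int) -> str:
    if gt is None or any(a is None for a in gt):
        return "missing"
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == 0:
        return "hom_ref"
    if n_alt >= len(gt):
        return "hom_alt"
    return "het"


def read_variants_vcf(vcf_path: str | Path, proband_id: str,
                      on_multiallelic: str = "split") -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects for one proband sample.

    One record is emitted per biallelic ALT. Multiallelic sites are split
    per ALT (``on_multiallelic='split'``) or rejected (``'reject'``).
    A missing CSQCLASS INFO key downgrades the consequence to ``other``
    with a logged warning.
    """
    if on_multiallelic not in ("split", "reject"):
        raise ValueError("on_multiallelic must be 'split' or 'reject'")
    records: list[VariantRecord] = []
    missing_csq = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if proband_id not in list(vcf.header.samples):
            raise ValidationError(
                f"proband {proband_id!r} not among VCF samples "
                f"{list(vcf.header.samples)}"
            )
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1 and on_multiallelic == "reject":
                raise ValidationError(
                    f"multiallelic record at {rec.chrom}:{rec.pos} rejected"
                )
            csq = rec.info.get(VCF_CONSEQUENCE_KEY)
            if isinstance(csq, tuple):
                csq = csq[0] if csq else None
            if csq is None:
                missing_csq += 1
                csq = "other"
            elif csq not in CONSEQUENCES:
                csq = "other"
            in_db = bool(rec.info.get(VCF_CONTROL_DB_KEY, False))
            gt = rec.samples[proband_id].get("GT")
            for alt_offset, alt in enumerate(alts, start=1):
                records.append(VariantRecord(
                    chromosome=str(rec.chrom),
                    position_bp=int(rec.pos),
                    ref_allele=str(rec.ref),
                    alt_allele=str(alt),
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                    consequence=csq,
                    proband_genotype=_zygosity_from_gt(gt, alt_offset),
                    in_control_db=in_db,
                ))
    if missing_csq:
        log.warning(
            "%d VCF records lacked INFO/%s; consequence set to 'other'",
            missing_csq, VCF_CONSEQUENCE_KEY,
        )
    return records


_GT_FROM_ZYGOSITY = {
    "hom_ref": (0, 0),
    "het": (0, 1),
    "hom_alt": (1, 1),
    "missing": (None, None),
}


def write_variants_vcf(variants: Sequence[VariantRecord], vcf_path: str | Path,
                       proband_id: str = "PROBAND") -> None:
    """Write variants to an uncompressed single-sample VCF v4.2."""
    header = pysam.VariantHeader()
    header.add_line(f'##INFO=<ID={VCF_CONSEQUENCE_KEY},Number=1,Type=String,'
                    'Description="Functional consequence class">')
    header.add_line(f'##INFO=<ID={VCF_CONTROL_DB_KEY},Number=0,Type=Flag,'
                    'Description="Present in control sequencing cohort">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chrom_max: dict[str, int] = {}
    for v in variants:
        chrom_max[v.chromosome] = max(chrom_max.get(v.chromosome, 0), v.position_bp)
    for chrom in sorted(chrom_max):
        header.contigs.add(chrom, length=chrom_max[chrom] + 1_000_000)
    header.add_sample(proband_id)

    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chromosome,
                start=v.position_bp - 1,
                stop=v.position_bp - 1 + len(v.ref_allele),
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.qual = v.quality
            rec.info[VCF_CONSEQUENCE_KEY] = v.consequence or "other"
            if v.in_control_db:
                rec.info[VCF_CONTROL_DB_KEY] = True
            rec.samples[proband_id]["GT"] = _GT_FROM_ZYGOSITY[v.proband_genotype or "missing"]
            out.write(rec)


# ---------------------------------------------------------------------------
# Pigment summary tables
# ---------------------------------------------------------------------------

def read_pigment_table(tsv_path: str | Path) -> list[PigmentGroupStats]:
    """Read a pigment summary TSV (columns: group, n, <assay>_mean, <assay>_se)."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"group", "n"}
    if not required.issubset(df.columns):
        raise ValidationError(f"pigment table must have columns {sorted(required)}")
    out: list[PigmentGroupStats] = []
    for _, row in df.iterrows():
        assays = {}
        for assay in PIGMENT_ASSAYS:
            mcol, scol = f"{assay}_mean", f"{assay}_se"
            if mcol in df.columns and scol in df.columns:
                assays[assay] = (float(row[mcol]), float(row[scol]))
        out.append(PigmentGroupStats(group=str(row["group"]), n=int(row["n"]),
                                     assays=assays))
    return out


def write_pigment_table(stats: Iterable[PigmentGroupStats], tsv_path: str | Path) -> None:
    rows = []
    for s in stats:
        row: dict[str, object] = {"group": s.group, "n": s.n}
        for assay, (mean, se) in s.assays.items():
            row[f"{assay}_mean"] = mean
            row[f"{assay}_se"] = se
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def packaged_pigment_table() -> list[PigmentGroupStats]:
    """Load the packaged Holstein hair-pigment summary table."""
    ref = resources.files("drmap.data").joinpath("holstein_hair_pigment.tsv")
    with resources.as_file(ref) as path:
        return read_pigment_table(path)
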