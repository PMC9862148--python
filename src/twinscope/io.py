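"""File interchange: VCF 4.2 genotypes (FORMAT fields GT and GC), a
PED-like pedigree sidecar, and the morphometry TSV dialect.

The VCF carries the per-call confidence score in a ``GC`` FORMAT field
(GenCall semantics) and the simulator's annotations in ``GENE`` /
``FCLASS`` INFO fields, so a written file round-trips to an identical
in-memory genotype table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .cohort import FamilyCohort, Subject
from .errors import ValidationError
from .genetics import GenotypeTable

_GC_DECIMALS = 4


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a genotype table as uncompressed VCF 4.2."""
    path = str(path)
    header = pysam.VariantHeader()
    header.add_meta(
        "INFO",
        items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
               ("Description", "Panel gene symbol")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "FCLASS"), ("Number", "1"), ("Type", "String"),
               ("Description", "Functional class annotation")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "GC"), ("Number", "1"), ("Type", "Float"),
               ("Description", "Per-call confidence score (no-call at <= 0.15)")],
    )
    for chrom, sub in table.df.groupby("chrom", sort=True):
        header.contigs.add(str(chrom), length=int(sub.pos.max()) + 10_000)
    for s in table.subjects:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as vf:
        for row in table.df.itertuples():
            rec = vf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
                id=row.snp_id,
            )
            if isinstance(row.gene_symbol, str) and row.gene_symbol:
                rec.info["GENE"] = row.gene_symbol
            if isinstance(row.functional_class, str) and row.functional_class:
                rec.info["FCLASS"] = row.functional_class
            allele_index = {row.ref: 0, row.alt: 1}
            for s in table.subjects:
                gt = getattr(row, table.gt_col(s))
                if gt is None or (isinstance(gt, float) and np.isnan(gt)):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    a, b = str(gt).split("/")
                    rec.samples[s]["GT"] = tuple(sorted((allele_index[a], allele_index[b])))
                rec.samples[s].phased = False
                rec.samples[s]["GC"] = float(getattr(row, table.gc_col(s)))
            vf.write(rec)


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a VCF written by :func:`write_vcf` (or any biallelic VCF with a
    GC FORMAT field) into a genotype table."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        subjects = list(vf.header.samples)
        for rec in vf:
            if len(rec.alts or ()) != 1:
                raise ValidationError(f"{rec.id}: only biallelic records are supported")
            row = {
                "snp_id": rec.id,
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "gene_symbol": rec.info.get("GENE", ""),
                "functional_class": rec.info.get("FCLASS", ""),
            }
            alleles = (rec.ref, rec.alts[0])
            for s in subjects:
                call = rec.samples[s]
                gt_idx = call.get("GT")
                if gt_idx is None or any(i is None for i in gt_idx):
                    row[GenotypeTable.gt_col(s)] = None
                else:
                    row[GenotypeTable.gt_col(s)] = "/".join(sorted(alleles[i] for i in gt_idx))
                gc = call.get("GC")
                row[GenotypeTable.gc_col(s)] = (
                    float("nan") if gc is None else round(float(gc), _GC_DECIMALS)
                )
            rows.append(row)
    if not rows:
        raise ValidationError(f"no records in {path}")
    return GenotypeTable(pd.DataFrame(rows), subjects)


# ---------------------------------------------------------------------------
# pedigree sidecar
# ---------------------------------------------------------------------------

_ROLE_BY_ID = {"mother": "parent", "father": "parent"}


def write_ped(cohort: FamilyCohort, path: str | Path) -> None:
    """PED-like TSV: the six classic pedigree columns plus role/affected."""
    parents = cohort.parents
    mother = next((p for p in parents if p.sex == "F"), parents[0])
    father = next((p for p in parents if p.sex == "M"), parents[-1])
    with open(path, "w") as fh:
        fh.write("family_id\tsubject_id\tfather_id\tmother_id\tsex\taffected\trole\n")
        for s in cohort.subjects:
            fa = "0" if s.role == "parent" else father.subject_id
            mo = "0" if s.role == "parent" else mother.subject_id
            sex = "1" if s.sex == "M" else "2"
            aff = "2" if s.affected else "1"
            fh.write(
                f"{cohort.family_id}\t{s.subject_id}\t{fa}\t{mo}\t{sex}\t{aff}\t{s.role}\n"
            )


def read_ped(path: str | Path) -> FamilyCohort:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "subject_id", "sex", "affected", "role"}
    if not required.issubset(df.columns):
        raise ValidationError(f"pedigree file missing columns: {required - set(df.columns)}")
    subjects = [
        Subject(
            subject_id=row.subject_id,
            role=row.role,
            affected=row.affected == "2",
            sex="M" if row.sex == "1" else "F",
        )
        for row in df.itertuples()
    ]
    return FamilyCohort(subjects=subjects, family_id=df.family_id.iloc[0])
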