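"""Genotype QC and discordant-sibling co-segregation analysis.

The filter pipeline is fixed and order-sensitive:

1. ``apply_gencall_qc`` — genotype calls with a GenCall-style confidence
   score at or below the no-call threshold (default 0.15) are set missing,
   per sample independently.
2. ``drop_family_invariant_snps`` — SNPs whose called genotype is identical
   across all listed family members (default: all five) are removed, as are
   SNPs with a missing call in any listed member.
3. ``find_cosegregating_snps`` — among the remaining SNPs, keep those where
   the two affected siblings share a genotype (unordered allele pair) that
   differs from the unaffected twin's.

Genotypes are diploid, unphased and biallelic; equality always compares
unordered allele pairs.  Coordinates are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TwinscopeError, ValidationError
from .panel import GenePanel

FUNCTIONAL_CLASSES = ("intronic", "exonic", "utr3", "intergenic", "unannotated")

GENCALL_NO_CALL_THRESHOLD = 0.15

_CORE_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "gene_symbol", "functional_class"]


def normalize_genotype(gt: str | None) -> str | None:
    """Canonical unordered representation of a diploid genotype ("A/G")."""
    if gt is None or (isinstance(gt, float) and np.isnan(gt)):
        return None
    alleles = sorted(str(gt).replace("|", "/").split("/"))
    if len(alleles) != 2:
        raise ValidationError(f"expected a diploid genotype, got {gt!r}")
    return "/".join(alleles)


@dataclass
class GenotypeTable:
    """SNP x subject genotype calls with per-call confidence scores.

    ``df`` holds one row per SNP with columns ``snp_id, chrom, pos, ref,
    alt, gene_symbol, functional_class`` plus, for each subject ``s``,
    ``gt_<s>`` (canonical "A/G" string or None when missing) and ``gc_<s>``
    (confidence score in [0, 1]).
    """

    df: pd.DataFrame
    subjects: list[str]

    def __post_init__(self):
        missing = [c for c in _CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"genotype table missing columns: {missing}")
        for s in self.subjects:
            for c in (self.gt_col(s), self.gc_col(s)):
                if c not in self.df.columns:
                    raise ValidationError(f"genotype table missing column {c}")
        self.df = self.df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        dup = self.df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            where = self.df.loc[dup, ["chrom", "pos"]].iloc[0]
            raise ValidationError(
                f"duplicate position {where.chrom}:{where.pos}; "
                "positions must be strictly increasing within a chromosome"
            )

    @staticmethod
    def gt_col(subject: str) -> str:
        return f"gt_{subject}"

    @staticmethod
    def gc_col(subject: str) -> str:
        return f"gc_{subject}"

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.df.copy(), list(self.subjects))

    def genotypes(self, subject: str) -> pd.Series:
        return self.df[self.gt_col(subject)]

    def subset(self, mask) -> "GenotypeTable":
        return GenotypeTable(self.df.loc[mask].reset_index(drop=True), list(self.subjects))


@dataclass
class CosegregationResult:
    """Outcome of the co-segregation pattern filter on one SNP set."""

    matching_snps: list[str]
    per_gene_counts: dict[str, int]
    per_class_counts: dict[str, int]
    n_panel_variable: int
    #: SNPs actually evaluated (no missing sibling call); <= n_panel_variable
    n_pattern_evaluated: int
    panel_proportion: float | None
    background_proportion: float | None = None

    def __post_init__(self):
        n = len(self.matching_snps)
        if sum(self.per_gene_counts.values()) != n:
            raise TwinscopeError("per-gene tallies do not sum to the match count")
        if sum(self.per_class_counts.values()) != n:
            raise TwinscopeError("per-class tallies do not sum to the match count")

    def to_dict(self) -> dict:
        return {
            "n_matching": len(self.matching_snps),
            "n_panel_variable": self.n_panel_variable,
            "n_pattern_evaluated": self.n_pattern_evaluated,
            "panel_proportion": self.panel_proportion,
            "background_proportion": self.background_proportion,
            "per_gene_counts": dict(sorted(self.per_gene_counts.items())),
            "per_class_counts": dict(sorted(self.per_class_counts.items())),
            "matching_snps": list(self.matching_snps),
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_gencall_qc(
    table: GenotypeTable, threshold: float = GENCALL_NO_CALL_THRESHOLD
) -> GenotypeTable:
    """Set every call with confidence score <= ``threshold`` to missing.

    Applied per sample independently; idempotent on already-missing calls.
    """
    if not (0.0 <= threshold <= 1.0):
        raise TwinscopeError(f"threshold must be in [0, 1], got {threshold}")
    out = table.copy()
    for s in out.subjects:
        low = out.df[out.gc_col(s)] <= threshold
        col = out.df[out.gt_col(s)].astype(object)
        col[low.to_numpy()] = None
        out.df[out.gt_col(s)] = col
    return out


def drop_family_invariant_snps(
    table: GenotypeTable, subject_ids: list[str] | None = None
) -> GenotypeTable:
    """Remove SNPs that are identical across all listed family members.

    A SNP is retained only when at least two listed subjects carry
    different called genotypes; SNPs with a missing call in any listed
    subject are dropped.
    """
    if subject_ids is None:
        subject_ids = list(table.subjects)
    if len(subject_ids) == 0:
        raise TwinscopeError("subject_ids must be non-empty")
    unknown = set(subject_ids) - set(table.subjects)
    if unknown:
        raise TwinscopeError(f"unknown subjects: {sorted(unknown)}")

    gts = [table.df[table.gt_col(s)] for s in subject_ids]
    any_missing = np.column_stack([g.isna() for g in gts]).any(axis=1)
    n_distinct = pd.concat(gts, axis=1).nunique(axis=1, dropna=True)
    keep = (~any_missing) & (n_distinct >= 2)
    return table.subset(keep)


def find_cosegregating_snps(
    table: GenotypeTable,
    affected_ids: tuple[str, str],
    discordant_id: str,
) -> CosegregationResult:
    """Apply the discordant-sibling co-segregation pattern.

    A SNP matches when the two affected siblings carry equal genotypes
    (as unordered allele pairs) and the unaffected twin's called genotype
    differs from that shared genotype.  SNPs with a missing call in any of
    the three siblings are excluded from evaluation.  The input table is
    expected to be QC'd and invariant-filtered already.
    """
    if len(affected_ids) != 2:
        raise TwinscopeError("affected_ids must contain exactly two subject ids")
    ids = (*affected_ids, discordant_id)
    if len(set(ids)) != 3:
        raise TwinscopeError("affected and discordant subject ids must be distinct")

    a1 = table.df[table.gt_col(affected_ids[0])]
    a2 = table.df[table.gt_col(affected_ids[1])]
    d = table.df[table.gt_col(discordant_id)]

    evaluable = ~(a1.isna() | a2.isna() | d.isna())
    match = evaluable & (a1 == a2) & (a1 != d)

    matched = table.df.loc[match]
    per_gene: dict[str, int] = {}
    per_class: dict[str, int] = {}
    for row in matched.itertuples():
        gene = row.gene_symbol if isinstance(row.gene_symbol, str) and row.gene_symbol else "(none)"
        per_gene[gene] = per_gene.get(gene, 0) + 1
        fc = row.functional_class if isinstance(row.functional_class, str) and row.functional_class else "unannotated"
        per_class[fc] = per_class.get(fc, 0) + 1

    n_variable = len(table)
    return CosegregationResult(
        matching_snps=list(matched.snp_id),
        per_gene_counts=per_gene,
        per_class_counts=per_class,
        n_panel_variable=n_variable,
        n_pattern_evaluated=int(evaluable.sum()),
        panel_proportion=(len(matched) / n_variable) if n_variable > 0 else None,
    )


def annotate_snps(table: GenotypeTable, panel: GenePanel) -> GenotypeTable:
    """Assign panel gene symbols by interval containment (with flank).

    A pre-existing ``functional_class`` annotation is honoured; where it is
    absent the interval fallback is used and is only approximate: positions
    inside a gene body are labelled intronic, flank-only hits intergenic,
    and everything else unannotated.
    """
    out = table.copy()
    symbols, classes = [], []
    for row in out.df.itertuples():
        sym = panel.assign(str(row.chrom), int(row.pos))
        symbols.append(sym or "")
        existing = row.functional_class
        if isinstance(existing, str) and existing in FUNCTIONAL_CLASSES and existing != "unannotated":
            classes.append(existing)
        elif sym is not None:
            in_body = any(
                g.symbol == sym and g.contains(str(row.chrom), int(row.pos), flank_bp=0)
                for g in panel.genes
            )
            classes.append("intronic" if in_body else "intergenic")
        else:
            classes.append("unannotated")
    out.df["gene_symbol"] = symbols
    out.df["functional_class"] = classes
    return out


def background_comparison(
    panel_result: CosegregationResult,
    genome_table: GenotypeTable,
    affected_ids: tuple[str, str],
    discordant_id: str,
) -> tuple[float | None, float | None]:
    """Compare the panel's co-segregation proportion against the genome
    background, computed identically on a table that excludes panel SNPs.

    Returns ``(panel_proportion, background_proportion)``; a proportion is
    None when its denominator (variable SNP count) is zero.
    """
    bg = find_cosegregating_snps(genome_table, affected_ids, discordant_id)
    panel_result.background_proportion = bg.panel_proportion
    return panel_result.panel_proportion, bg.panel_proportion


def split_panel_background(
    table: GenotypeTable, panel: GenePanel
) -> tuple[GenotypeTable, GenotypeTable]:
    """Split a table into panel SNPs (assigned a panel gene) and the rest."""
    in_panel = table.df["gene_symbol"].apply(lambda s: isinstance(s, str) and s != "")
    return table.subset(in_panel), table.subset(~in_panel)
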