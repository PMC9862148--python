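"""Simulated family genotypes with planted ground truth.

Each SNP falls into one of three categories, drawn without replacement:

* *planted co-segregating*: the two affected siblings share a genotype the
  unaffected twin does not carry;
* *invariant*: all five family members carry the same genotype;
* *variable background*: genotypes vary in the family but, by rejection
  sampling, never satisfy the co-segregation pattern.

All child genotypes are valid Mendelian transmissions from the simulated
parents, so the planted pattern set is exactly what the downstream filter
should recover when no calls are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import datasets
from ..cohort import FamilyCohort
from ..config import SimulationConfig
from ..errors import CohortError, ConfigError
from ..genetics import GenotypeTable
from ..panel import GenePanel

_BASES = np.array(list("ACGT"))

#: chromosomes used for background (off-panel) SNPs
_BACKGROUND_CHROMS = ("1", "8", "9", "10", "11")

#: functional-class frequencies mirroring the study's co-segregating set
_CLASS_NAMES = ("intronic", "exonic", "utr3", "intergenic")
_CLASS_WEIGHTS = np.array([57, 1, 1, 20], dtype=float) / 79.0


@dataclass
class SimulatedGenotypes:
    """A genotype table plus the generator's ground-truth ledger."""

    table: GenotypeTable
    planted_panel: list[str] = field(default_factory=list)
    planted_background: list[str] = field(default_factory=list)
    invariant_snps: list[str] = field(default_factory=list)
    missing_calls: list[tuple[str, str]] = field(default_factory=list)

    def ground_truth(self) -> dict:
        return {
            "planted_panel": list(self.planted_panel),
            "planted_background": list(self.planted_background),
            "invariant_snps": list(self.invariant_snps),
            "missing_calls": [list(t) for t in self.missing_calls],
        }


def _sorted_pair(a: str, b: str) -> str:
    return "/".join(sorted((a, b)))


def _possible_children(gm: tuple[str, str], gf: tuple[str, str]) -> list[str]:
    return sorted({_sorted_pair(a, b) for a in gm for b in gf})


def _sample_child(rng, gm, gf) -> str:
    return _sorted_pair(gm[rng.integers(2)], gf[rng.integers(2)])


def _coseg_genotypes(rng, ref: str, alt: str) -> tuple[str, str, str, str, str]:
    """Parents + (proband, td twin, older sibling) satisfying the pattern."""
    gm = (ref, alt)  # heterozygous mother guarantees >= 2 possible children
    gf = [(ref, ref), (ref, alt), (alt, alt)][rng.integers(3)]
    possible = _possible_children(gm, gf)
    g_aff = possible[rng.integers(len(possible))]
    others = [g for g in possible if g != g_aff]
    g_td = others[rng.integers(len(others))]
    return _sorted_pair(*gm), _sorted_pair(*gf), g_aff, g_td, g_aff


def _invariant_genotypes(rng, ref: str, alt: str) -> tuple[str, ...]:
    kind = rng.integers(3)
    if kind == 0:
        g = _sorted_pair(ref, ref)
    elif kind == 1:
        g = _sorted_pair(alt, alt)
    else:
        g = _sorted_pair(ref, alt)
    return (g,) * 5


def _variable_genotypes(rng, ref: str, alt: str) -> tuple[str, ...]:
    """Family-variable genotypes that do not satisfy the pattern."""
    gm = (ref, alt)
    gf = [(ref, ref), (ref, alt), (alt, alt)][rng.integers(3)]
    g_mo, g_fa = _sorted_pair(*gm), _sorted_pair(*gf)
    for _ in range(100):
        c = [_sample_child(rng, gm, gf) for _ in range(3)]
        is_pattern = c[0] == c[2] and c[0] != c[1]
        all_same = len({g_mo, g_fa, *c}) == 1
        if not is_pattern and not all_same:
            return (g_mo, g_fa, *c)
    # fall back deterministically: twin copies the proband (kills the pattern)
    c = [_sample_child(rng, gm, gf) for _ in range(3)]
    c[1] = c[0]
    if len({g_mo, g_fa, *c}) == 1:
        possible = _possible_children(gm, gf)
        c[2] = next(g for g in possible if g != c[0])
    return (g_mo, g_fa, *c)


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of `total` items over weights."""
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def simulate_genotypes(
    cohort: FamilyCohort, panel: GenePanel, cfg: SimulationConfig
) -> SimulatedGenotypes:
    """Generate biallelic SNP calls for the five family members."""
    cfg.validate()
    if len(cohort.subjects) != 5:  # FamilyCohort enforces this, but be explicit
        raise CohortError("genotype simulation requires the five-member family")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))

    subjects = [
        next(p for p in cohort.parents if p.sex == "F").subject_id,
        next(p for p in cohort.parents if p.sex == "M").subject_id,
        cohort.proband.subject_id,
        cohort.td_twin.subject_id,
        cohort.older_sibling.subject_id,
    ]

    # -- lay out positions -------------------------------------------------
    lengths = np.array([g.length for g in panel.genes], dtype=float)
    if len(panel.genes) == 0:
        raise ConfigError("gene panel is empty")
    per_gene = _allocate(cfg.n_snps_panel, lengths)
    loci: list[tuple[str, int, str]] = []  # (chrom, pos, gene_symbol)
    for gene, n in zip(panel.genes, per_gene):
        if n == 0:
            continue
        offsets = np.sort(rng.choice(gene.length, size=int(n), replace=False))
        loci.extend((gene.chrom, int(gene.start + o), gene.symbol) for o in offsets)
    n_bg_per_chrom = _allocate(cfg.n_snps_background, np.ones(len(_BACKGROUND_CHROMS)))
    for chrom, n in zip(_BACKGROUND_CHROMS, n_bg_per_chrom):
        offsets = np.sort(rng.choice(50_000_000, size=int(n), replace=False))
        loci.extend((chrom, int(1_000_000 + o), "") for o in offsets)

    df = pd.DataFrame(loci, columns=["chrom", "pos", "gene_symbol"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df["snp_id"] = [f"snp{i:06d}" for i in range(len(df))]
    in_panel = (df.gene_symbol != "").to_numpy()

    # -- assign categories -------------------------------------------------
    panel_idx = np.flatnonzero(in_panel)
    bg_idx = np.flatnonzero(~in_panel)
    coseg_panel = rng.choice(panel_idx, size=cfg.n_coseg_panel, replace=False)
    rest_panel = np.setdiff1d(panel_idx, coseg_panel)
    inv_panel = rng.choice(rest_panel, size=cfg.n_invariant_panel, replace=False)
    coseg_bg = rng.choice(bg_idx, size=cfg.n_coseg_background, replace=False)
    rest_bg = np.setdiff1d(bg_idx, coseg_bg)
    inv_bg = rng.choice(rest_bg, size=cfg.n_invariant_background, replace=False)
    coseg_set = set(coseg_panel) | set(coseg_bg)
    inv_set = set(inv_panel) | set(inv_bg)

    # -- alleles, classes, genotypes ---------------------------------------
    n = len(df)
    ref_idx = rng.integers(4, size=n)
    alt_shift = 1 + rng.integers(3, size=n)
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[(ref_idx + alt_shift) % 4]
    classes = np.where(
        in_panel,
        rng.choice(_CLASS_NAMES, size=n, p=_CLASS_WEIGHTS),
        "intergenic",
    )
    df["functional_class"] = classes

    gts = {s: [] for s in subjects}
    for i, row in enumerate(df.itertuples()):
        if i in coseg_set:
            g = _coseg_genotypes(rng, row.ref, row.alt)
        elif i in inv_set:
            g = _invariant_genotypes(rng, row.ref, row.alt)
        else:
            g = _variable_genotypes(rng, row.ref, row.alt)
        for s, gt in zip(subjects, g):
            gts[s].append(gt)

    # -- confidence scores and missingness ----------------------------------
    gc = np.round(rng.uniform(0.1501, 0.99, size=(n, 5)), 4)
    missing_calls: list[tuple[str, str]] = []
    n_missing = round(cfg.missing_rate * n * 5)
    if n_missing > 0:
        flat = rng.choice(n * 5, size=n_missing, replace=False)
        for f in np.sort(flat):
            i, j = divmod(int(f), 5)
            gc[i, j] = round(float(rng.uniform(0.0, 0.15)), 4)
            missing_calls.append((df.snp_id.iloc[i], subjects[j]))

    for j, s in enumerate(subjects):
        df[GenotypeTable.gt_col(s)] = gts[s]
        df[GenotypeTable.gc_col(s)] = gc[:, j]

    table = GenotypeTable(df, subjects)
    sid = df.snp_id
    return SimulatedGenotypes(
        table=table,
        planted_panel=sorted(sid.iloc[i] for i in coseg_panel),
        planted_background=sorted(sid.iloc[i] for i in coseg_bg),
        invariant_snps=sorted(sid.iloc[i] for i in np.concatenate([inv_panel, inv_bg])),
        missing_calls=missing_calls,
    )
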