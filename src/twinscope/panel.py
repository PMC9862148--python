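"""The reading-gene SNP panel: 28 genes repeatedly implicated in reading
(dys)ability, from the classical DYX-locus candidates (DCDC2, KIAA0319,
ROBO1, DNAAF4) through language genes (FOXP2, CNTNAP2) to more recent
GWAS/linkage hits (FGF18, LPHN3, MSI2, RBFOX2, ...).

Coordinates are approximate GRCh37 gene footprints. They only serve to lay
out simulated SNPs and to assign SNPs to genes by interval containment; no
external annotation database is queried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import TwinscopeError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneInterval:
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self):
        if self.start > self.end:
            raise TwinscopeError(f"{self.symbol}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, chrom: str, pos: int, flank_bp: int = 0) -> bool:
        return chrom == self.chrom and (self.start - flank_bp) <= pos <= (self.end + flank_bp)


@dataclass
class GenePanel:
    """A set of genes with genomic intervals (1-based inclusive)."""

    genes: list[GeneInterval] = field(default_factory=list)
    flank_bp: int = 10_000

    def __post_init__(self):
        if self.flank_bp < 0:
            raise TwinscopeError("flank_bp must be non-negative")
        # intervals of one gene must not overlap each other
        by_symbol: dict[str, list[GeneInterval]] = {}
        for g in self.genes:
            by_symbol.setdefault(g.symbol, []).append(g)
        for sym, ivals in by_symbol.items():
            ivals = sorted(ivals, key=lambda g: (g.chrom, g.start))
            for a, b in zip(ivals, ivals[1:]):
                if a.chrom == b.chrom and b.start <= a.end:
                    raise TwinscopeError(f"overlapping intervals within gene {sym}")

    @property
    def symbols(self) -> list[str]:
        return list(dict.fromkeys(g.symbol for g in self.genes))

    def __len__(self) -> int:
        return len(self.symbols)

    def assign(self, chrom: str, pos: int) -> str | None:
        """Gene symbol for a position, honouring the flank; ties between
        overlapping genes resolve toward the nearest gene midpoint."""
        hits = [g for g in self.genes if g.contains(chrom, pos, self.flank_bp)]
        if not hits:
            return None
        if len(hits) > 1:
            hits.sort(key=lambda g: abs(pos - g.midpoint))
            log.info(
                "position %s:%d inside several panel genes; assigned to %s by midpoint",
                chrom, pos, hits[0].symbol,
            )
        return hits[0].symbol

    def contains(self, chrom: str, pos: int) -> bool:
        return self.assign(chrom, pos) is not None

    # -- TSV round trip (BED-derived: half-open 0-based start on disk) -----
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("symbol\tchrom\tstart\tend\n")
            for g in self.genes:
                fh.write(f"{g.symbol}\t{g.chrom}\t{g.start - 1}\t{g.end}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, flank_bp: int = 10_000) -> "GenePanel":
        genes = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["symbol", "chrom", "start", "end"]:
                raise TwinscopeError(f"unexpected panel header in {path}")
            for line in fh:
                sym, chrom, start, end = line.rstrip("\n").split("\t")[:4]
                # BED half-open, 0-based start -> 1-based inclusive
                genes.append(GeneInterval(sym, chrom, int(start) + 1, int(end)))
        log.info("read %d gene intervals from %s (BED half-open converted to 1-based)", len(genes), path)
        return cls(genes=genes, flank_bp=flank_bp)


#: Approximate GRCh37 footprints for the 28-gene reading panel.
_DEFAULT_GENES: list[tuple[str, str, int, int]] = [
    ("MRPL19",  "2",  75_583_000,  75_594_000),
    ("ZNF385D", "3",  21_412_000,  22_381_000),
    ("ROBO1",   "3",  78_646_000,  79_817_000),
    ("VEPH1",   "3", 156_987_000, 157_222_000),
    ("LPHN3",   "4",  61_953_000,  62_534_000),
    ("FGF18",   "5", 170_846_000, 170_884_000),
    ("DCDC2",   "6",  24_171_000,  24_384_000),
    ("KIAA0319","6",  24_541_000,  24_645_000),
    ("TTRAP",   "6",  24_649_000,  24_667_000),
    ("THEM2",   "6",  24_667_500,  24_705_000),
    ("RIPOR2",  "6",  24_800_000,  24_960_000),
    ("CMAHP",   "6",  25_068_000,  25_200_000),
    ("FOXP2",   "7", 114_055_000, 114_333_000),
    ("CCDC136", "7", 128_431_000, 128_462_000),
    ("CNTNAP2", "7", 145_813_000, 148_118_000),
    ("SLC2A3", "12",   8_071_000,   8_088_000),
    ("COL4A2", "13", 110_958_000, 111_165_000),
    ("NOP9",   "14",  24_324_000,  24_331_000),
    ("TUBGCP5","15",  22_833_000,  22_873_000),
    ("CYFIP1", "15",  22_892_000,  23_003_000),
    ("NIPA2",  "15",  23_004_000,  23_034_000),
    ("SEMA6D", "15",  47_476_000,  48_066_000),
    ("DNAAF4", "15",  55_709_000,  55_790_000),
    ("CMIP",   "16",  81_477_000,  81_746_000),
    ("ATP2C2", "16",  84_402_000,  84_497_000),
    ("MSI2",   "17",  55_333_000,  55_760_000),
    ("MYO18B", "22",  26_112_000,  26_404_000),
    ("RBFOX2", "22",  36_134_000,  36_424_000),
]


def default_panel(flank_bp: int = 10_000) -> GenePanel:
    """The 28-gene reading panel used throughout the case-study analysis."""
    return GenePanel(
        genes=[GeneInterval(s, c, a, b) for s, c, a, b in _DEFAULT_GENES],
        flank_bp=flank_bp,
    )
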