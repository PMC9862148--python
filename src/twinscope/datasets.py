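"""Reference values from the published family case study.

These small tables are shipped with the package for three purposes: they
parameterise the synthetic-data generator so that simulated families
reproduce the study's reported structure; they provide the worked example
in the documentation; and internal-consistency checks (tally sums,
round-trip of the asymmetry formula) are run against them in the test
suite.  They are *reported* numbers, not something this package computes
from raw data — the underlying MRI and genotype data were never released.
"""

from __future__ import annotations

import pandas as pd

from .cohort import PAIR_SRD, PAIR_TD_OS, PAIR_TWINS

#: Co-segregating SNP counts per gene: SNPs at which the two affected
#: siblings shared a genotype that differed from the unaffected twin's.
COSEG_GENE_COUNTS: dict[str, int] = {
    "ZNF385D": 33,
    "LPHN3": 17,
    "CNTNAP2": 9,
    "FGF18": 2,
    "NOP9": 2,
    "CMIP": 11,
    "MYO18B": 4,
    "RBFOX2": 1,
}

#: Functional-class breakdown of the same co-segregating SNP set.
COSEG_CLASS_COUNTS: dict[str, int] = {
    "intronic": 57,
    "exonic": 1,
    "utr3": 1,
    "intergenic": 20,
}

#: Variable (non-family-invariant) SNPs within the reading-gene panel after QC.
N_PANEL_VARIABLE = 684
#: Co-segregating SNPs among them.
N_PANEL_COSEG = 79

#: Pairwise intraclass correlations between sibling morphometry vectors,
#: by phenotype and region set.
ICC_REFERENCE = pd.DataFrame(
    [
        ("thickness", "whole_cortex", PAIR_TWINS, 0.85),
        ("thickness", "whole_cortex", PAIR_SRD, 0.87),
        ("thickness", "whole_cortex", PAIR_TD_OS, 0.82),
        ("thickness", "reading", PAIR_TWINS, 0.66),
        ("thickness", "reading", PAIR_SRD, 0.76),
        ("thickness", "reading", PAIR_TD_OS, 0.54),
        ("volume", "whole_cortex", PAIR_TWINS, 0.97),
        ("volume", "whole_cortex", PAIR_SRD, 0.98),
        ("volume", "whole_cortex", PAIR_TD_OS, 0.97),
        ("volume", "reading", PAIR_TWINS, 0.97),
        ("volume", "reading", PAIR_SRD, 0.99),
        ("volume", "reading", PAIR_TD_OS, 0.95),
        ("area", "whole_cortex", PAIR_TWINS, 0.97),
        ("area", "whole_cortex", PAIR_SRD, 0.99),
        ("area", "whole_cortex", PAIR_TD_OS, 0.96),
        ("area", "reading", PAIR_TWINS, 0.96),
        ("area", "reading", PAIR_SRD, 0.99),
        ("area", "reading", PAIR_TD_OS, 0.95),
    ],
    columns=["phenotype", "region_set", "pair", "icc"],
)

# Hemispheric asymmetry indices (L - R) / ((L + R) / 2) per sibling, ROI and
# phenotype, for the seven tabulated reading-related parcels.  Subjects are
# keyed by the canonical cohort ids.
_ASYM_ROIS = (
    "fusiform",
    "banks_superior_temporal",
    "pars_opercularis",
    "pars_triangularis",
    "supramarginal",
    "transverse_temporal",
    "superior_temporal",
)

_ASYM_ROWS = {
    ("thickness", "proband"): (-0.008, -0.113, -0.022, 0.021, -0.018, 0.020, -0.008),
    ("thickness", "td_twin"): (0.027, -0.012, -0.022, 0.043, 0.019, -0.217, -0.078),
    ("thickness", "older_sibling"): (0.047, 0.009, 0.027, -0.001, 0.012, 0.084, -0.006),
    ("volume", "proband"): (-0.075, -0.079, 0.042, -0.117, 0.185, 0.126, 0.043),
    ("volume", "td_twin"): (0.037, -0.240, 0.083, 0.004, 0.593, 0.247, 0.141),
    ("volume", "older_sibling"): (-0.078, 0.123, 0.051, -0.136, 0.082, 0.359, 0.117),
    ("area", "proband"): (-0.084, -0.007, 0.072, -0.121, 0.225, 0.203, 0.024),
    ("area", "td_twin"): (-0.016, -0.213, 0.113, 0.015, 0.551, 0.435, 0.203),
    ("area", "older_sibling"): (-0.113, 0.077, 0.076, -0.105, 0.054, 0.320, 0.127),
}


def asymmetry_reference() -> pd.DataFrame:
    """Tidy table of reference asymmetry indices.

    Columns: subject_id, roi, phenotype, index.
    """
    rows = []
    for (phenotype, sid), values in _ASYM_ROWS.items():
        for roi, idx in zip(_ASYM_ROIS, values):
            rows.append((sid, roi, phenotype, idx))
    return pd.DataFrame(rows, columns=["subject_id", "roi", "phenotype", "index"])


def asymmetry_profile() -> dict[tuple[str, str, str], float]:
    """Reference asymmetries keyed (subject_id, roi, phenotype) — the format
    consumed by the morphometry simulator's planting step."""
    return {
        (row.subject_id, row.roi, row.phenotype): row.index
        for row in asymmetry_reference().itertuples()
    }


def similarity_profile() -> dict[str, dict[str, float]]:
    """Reading-region ICC targets per phenotype, keyed phenotype -> pair label.

    These are the default pairwise-similarity targets of the morphometry
    simulator.
    """
    sub = ICC_REFERENCE[ICC_REFERENCE.region_set == "reading"]
    out: dict[str, dict[str, float]] = {}
    for row in sub.itertuples():
        out.setdefault(row.phenotype, {})[row.pair] = row.icc
    return out


#: Word-level behavioral scores for the three siblings (standard scores);
#: carried as metadata only, never analysed by this package.
BEHAVIORAL_SCORES = pd.DataFrame(
    [
        ("proband", 82, 90, 82, 106),
        ("td_twin", 105, 113, 103, 109),
        ("older_sibling", 90, 84, 83, 93),
    ],
    columns=[
        "subject_id",
        "letter_word_identification",
        "nonsense_word_decoding",
        "reading_comprehension",
        "listening_comprehension",
    ],
)
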