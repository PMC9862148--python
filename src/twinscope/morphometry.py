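"""ROI morphometry: pairwise intraclass correlations and hemispheric
asymmetry indices.

The similarity of two siblings' morphometry is summarised by an intraclass
correlation over the vector of per-(ROI, hemisphere) average values, the
two siblings acting as the two "raters" of each item.  The default form is
ICC(2,1) — two-way random effects, absolute agreement, single measure —
because the siblings are interchangeable measurements of the same regions
and a constant offset between siblings should count against similarity.
ICC(1,1) and ICC(3,1) are selectable.

Asymmetry of a region is (L - R) / ((L + R) / 2): positive values mean the
left-hemisphere structure is larger (leftward asymmetry), negative values
rightward; the index is bounded in (-2, 2) for positive inputs and is
invariant to rescaling both hemispheres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .config import PHENOTYPES
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    TwinscopeError,
    ValidationError,
)
from .regions import RegionSet, canonical_roi

log = logging.getLogger(__name__)

HEMIS = ("lh", "rh")

ICC_FORMS = ("ICC(1,1)", "ICC(2,1)", "ICC(3,1)")

_WIDE_COLUMNS = ["subject_id", "hemi", "roi", "thickness_mm", "area_mm2", "volume_mm3"]
_PHENO_TO_COLUMN = {"thickness": "thickness_mm", "area": "area_mm2", "volume": "volume_mm3"}


@dataclass
class MorphometryTable:
    """Long-format table: one row per (subject, hemi, roi, phenotype)."""

    df: pd.DataFrame

    def __post_init__(self):
        required = {"subject_id", "hemi", "roi", "phenotype", "value"}
        if not required.issubset(self.df.columns):
            raise ValidationError(f"morphometry table missing columns {required - set(self.df.columns)}")
        self.df = self.df.copy()
        self.df["roi"] = self.df["roi"].map(canonical_roi)
        bad_hemi = set(self.df.hemi) - set(HEMIS)
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        bad_ph = set(self.df.phenotype) - set(PHENOTYPES)
        if bad_ph:
            raise ValidationError(f"unknown phenotypes: {sorted(bad_ph)}")
        if (self.df.value <= 0).any():
            raise ValidationError("morphometry values must be strictly positive")
        key = ["subject_id", "hemi", "roi", "phenotype"]
        dup = self.df.duplicated(subset=key)
        if dup.any():
            first = self.df.loc[dup, key].iloc[0].tolist()
            raise ValidationError(f"duplicate morphometry row for {tuple(first)}")
        counts = self.df.groupby(["subject_id", "roi", "phenotype"])["hemi"].nunique()
        lonely = counts[counts < 2]
        if len(lonely) > 0:
            rois = sorted({k[1] for k in lonely.index})
            raise ValidationError(f"rois missing a hemisphere counterpart: {rois}")
        self.df = self.df.sort_values(key, kind="stable").reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df.subject_id.unique())

    @property
    def rois(self) -> list[str]:
        return sorted(self.df.roi.unique())

    def value(self, subject: str, hemi: str, roi: str, phenotype: str) -> float:
        sel = self.df[
            (self.df.subject_id == subject)
            & (self.df.hemi == hemi)
            & (self.df.roi == canonical_roi(roi))
            & (self.df.phenotype == phenotype)
        ]
        if len(sel) != 1:
            raise KeyError((subject, hemi, roi, phenotype))
        return float(sel.value.iloc[0])

    def item_vector(self, subject: str, phenotype: str, rois: list[str]) -> pd.Series:
        """Values indexed by (roi, hemi), in a fixed sorted item order."""
        sub = self.df[(self.df.subject_id == subject) & (self.df.phenotype == phenotype)]
        sub = sub[sub.roi.isin(rois)]
        s = sub.set_index(["roi", "hemi"]).value.sort_index()
        return s

    def restrict(self, region_set: RegionSet) -> "MorphometryTable":
        return MorphometryTable(self.df[self.df.roi.isin(region_set.rois)])


def read_morphometry(path: str | Path) -> MorphometryTable:
    """Read the wide TSV dialect (one row per subject/hemi/roi, one column
    per phenotype) and return a validated long-format table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _WIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["subject_id", "hemi", "roi"])
    if dup.any():
        first = df.loc[dup, ["subject_id", "hemi", "roi"]].iloc[0].tolist()
        raise ValidationError(f"{path}: duplicated row for {tuple(first)}")
    long = df.melt(
        id_vars=["subject_id", "hemi", "roi"],
        value_vars=list(_PHENO_TO_COLUMN.values()),
        var_name="column",
        value_name="value",
    )
    inv = {v: k for k, v in _PHENO_TO_COLUMN.items()}
    long["phenotype"] = long["column"].map(inv)
    return MorphometryTable(long.drop(columns=["column"]))


def write_morphometry(table: MorphometryTable, path: str | Path) -> None:
    wide = table.df.pivot_table(
        index=["subject_id", "hemi", "roi"], columns="phenotype", values="value"
    ).reset_index()
    wide = wide.rename(columns=_PHENO_TO_COLUMN)
    wide[_WIDE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    pair: tuple[str, str]
    phenotype: str
    region_set: str
    icc: float
    icc_form: str
    n_items: int
    ci95: tuple[float, float] | None = None
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "phenotype": self.phenotype,
            "region_set": self.region_set,
            "icc_form": self.icc_form,
            "icc": self.icc,
            "n_items": self.n_items,
            "ci95": list(self.ci95) if self.ci95 else None,
            "p_value": self.p_value,
        }


def _mean_squares(Y: np.ndarray):
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = ss_within / (n * (k - 1))
    return msr, msc, mse, msw


def icc_from_matrix(Y: np.ndarray, form: str = "ICC(2,1)", alpha: float = 0.05):
    """Single-measure ICC of an items x raters matrix, with an F-test
    p-value and a 95% confidence interval (Shrout-Fleiss / McGraw-Wong).

    Returns ``(icc, (lo, hi), p_value)``.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    if n < 3:
        raise InsufficientDataError(f"need at least 3 items, got {n}")
    if form not in ICC_FORMS:
        raise TwinscopeError(f"unknown ICC form {form!r}; choose from {ICC_FORMS}")
    msr, msc, mse, msw = _mean_squares(Y)
    if msr <= 1e-30:
        raise DegenerateDataError("zero variance across items; ICC undefined")
    # sums-of-squares cancellation can leave tiny negative residuals
    tol = 1e-12 * msr
    msc, mse, msw = (0.0 if m < tol else m for m in (msc, mse, msw))

    if form == "ICC(1,1)":
        if msw == 0:  # perfect within-item agreement
            return 1.0, (1.0, 1.0), 0.0
        icc = (msr - msw) / (msr + (k - 1) * msw)
        fvalue = msr / msw
        df1, df2 = n - 1, n * (k - 1)
        fl = fvalue / f_dist.ppf(1 - alpha / 2, df1, df2)
        fu = fvalue * f_dist.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        p = float(f_dist.sf(fvalue, df1, df2))
        return float(icc), (float(lo), float(hi)), p

    fvalue = msr / mse if mse > 0 else math.inf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(f_dist.sf(fvalue, df1, df2)) if math.isfinite(fvalue) else 0.0

    if form == "ICC(3,1)":
        if mse == 0:  # columns agree up to a constant: consistency is exact
            return 1.0, (1.0, 1.0), 0.0
        icc = (msr - mse) / (msr + (k - 1) * mse)
        fl = fvalue / f_dist.ppf(1 - alpha / 2, df1, df2)
        fu = fvalue * f_dist.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(icc), (float(lo), float(hi)), p

    # ICC(2,1)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 1.0
    if mse == 0 and msc == 0:
        return 1.0, (1.0, 1.0), 0.0
    if mse > 0:
        fj = msc / mse
        vn = df2 * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = df1 * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f3u = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f3l = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f3u * mse) / (f3u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f3l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f3l * msr)
        ci = (float(lo), float(hi))
    else:
        ci = None  # mse = 0 with a column offset: interval undefined
    return float(icc), ci, p


def pairwise_icc(
    table: MorphometryTable,
    pair: tuple[str, str],
    phenotype: str,
    region_set: RegionSet,
    icc_form: str = "ICC(2,1)",
) -> ICCResult:
    """ICC between two subjects over (roi, hemisphere) items of a region set.

    Hemispheres are kept as separate items (they are not averaged), so the
    item vector of a 7-ROI set has 14 entries.
    """
    a, b = pair
    present = set(table.rois)
    rois = [r for r in region_set.rois if r in present]
    skipped = [r for r in region_set.rois if r not in present]
    if skipped:
        log.info("region set %s: %d rois absent from table: %s", region_set.name, len(skipped), skipped)
    va = table.item_vector(a, phenotype, rois)
    vb = table.item_vector(b, phenotype, rois)
    if not va.index.equals(vb.index):
        raise ValidationError(f"subjects {a} and {b} have mismatched items")
    Y = np.column_stack([va.to_numpy(), vb.to_numpy()])
    if Y.shape[0] < 3:
        raise InsufficientDataError(
            f"need at least 3 (roi, hemi) items, got {Y.shape[0]}"
        )
    icc, ci, p = icc_from_matrix(Y, form=icc_form)
    return ICCResult(
        pair=pair,
        phenotype=phenotype,
        region_set=region_set.name,
        icc=icc,
        icc_form=icc_form,
        n_items=Y.shape[0],
        ci95=ci,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# asymmetry
# ---------------------------------------------------------------------------

DIRECTION_LEFTWARD = "leftward"
DIRECTION_RIGHTWARD = "rightward"
DIRECTION_SYMMETRIC = "symmetric"


def asymmetry_index(L: float, R: float) -> float:
    """(L - R) / ((L + R) / 2); antisymmetric under swapping L and R."""
    if L <= 0 or R <= 0:
        raise TwinscopeError(f"hemisphere values must be positive, got L={L}, R={R}")
    return 2.0 * (L - R) / (L + R)


def classify_direction(index: float, epsilon: float = 0.01) -> str:
    """Label an asymmetry index: leftward (> eps), rightward (< -eps), else
    symmetric.  The default tolerance treats |index| <= 0.01 as symmetric."""
    if not math.isfinite(index):
        raise TwinscopeError(f"index must be finite, got {index}")
    if index > epsilon:
        return DIRECTION_LEFTWARD
    if index < -epsilon:
        return DIRECTION_RIGHTWARD
    return DIRECTION_SYMMETRIC


@dataclass
class AsymmetryRecord:
    subject_id: str
    roi: str
    phenotype: str
    L: float
    R: float
    index: float
    direction: str


def asymmetry_table(
    table: MorphometryTable,
    region_set: RegionSet,
    phenotype: str,
    epsilon: float = 0.01,
) -> list[AsymmetryRecord]:
    """One asymmetry record per subject x ROI of the region set.

    ROIs absent from the table are logged and skipped, not fatal.
    """
    present = set(table.rois)
    skipped = [r for r in region_set.rois if r not in present]
    if skipped:
        log.info("asymmetry: skipping rois absent from table: %s", skipped)
    records = []
    for subject in table.subjects:
        for roi in region_set.rois:
            if roi in skipped:
                continue
            L = table.value(subject, "lh", roi, phenotype)
            R = table.value(subject, "rh", roi, phenotype)
            idx = asymmetry_index(L, R)
            records.append(
                AsymmetryRecord(subject, roi, phenotype, L, R, idx, classify_direction(idx, epsilon))
            )
    return records


def asymmetry_frame(records: list[AsymmetryRecord]) -> pd.DataFrame:
    """Wide export: subjects as rows, ROIs as columns, one frame per
    phenotype caller-side."""
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.pivot(index=["phenotype", "subject_id"], columns="roi", values="index")
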