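"""Mask-luminosity composites and Q-Q comparison.

A binary ROI mask on the shared template grid is sliced along one
anatomical axis into 2-D binary images.  Layering the slices of one
(subject, ROI, axis) with a uniform opacity produces a grayscale composite
in which a pixel's luminosity is proportional to the number of slices that
contain it — brighter pixels mark "thicker" cortex along that axis:

    luminosity(x, y) = min(255, round(255 * c(x, y) / alpha_ref))

where c(x, y) counts the slices in which (x, y) is foreground and
``alpha_ref`` is a reference slice count shared by all subjects for one
(ROI, axis), which standardises the opacity step so luminosities are
comparable between subjects.  The multiset of foreground luminosities is
the ROI's luminosity distribution; two distributions are compared by
matched quantiles (a Q-Q curve), summarised by the mean absolute quantile
difference normalised by 255.  The divergence scalar is a convenience of
this package — the published analysis reads the Q-Q plots visually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .cohort import PAIR_LABELS, PAIR_SRD, PAIR_TD_OS, PAIR_TWINS, FamilyCohort
from .errors import (
    CohortError,
    EmptyDistributionError,
    EmptyMaskError,
    StandardizationError,
    TwinscopeError,
)
from .regions import DEFAULT_PATHWAYS, PathwayDefinition  # re-exported

__all__ = [
    "AXES",
    "MaskVolume",
    "CompositeImage",
    "LuminosityDistribution",
    "QQCurve",
    "PairSelection",
    "PathwayDefinition",
    "DEFAULT_PATHWAYS",
    "slice_mask",
    "build_composite",
    "composite_from_mask",
    "extract_distribution",
    "qq_compare",
    "enumerate_subject_pairs",
    "enumerate_roi_pairs",
    "most_similar_pair",
    "alpha_references",
    "save_mask",
    "load_mask",
    "save_composite_png",
]

#: anatomical axes bound to grid dimensions on a RAS+ grid:
#: x = sagittal, y = coronal, z = axial
AXES = ("sagittal", "coronal", "axial")


@dataclass
class MaskVolume:
    """Binary ROI mask on the shared template grid."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str
    roi: str
    axes: tuple[str, str, str] = AXES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise TwinscopeError("mask data must be 3-D")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise TwinscopeError("mask voxels must be binary {0, 1}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def axis_index(self, axis: str) -> int:
        if axis not in self.axes:
            raise TwinscopeError(f"unknown axis {axis!r}; expected one of {self.axes}")
        return self.axes.index(axis)


@dataclass
class CompositeImage:
    pixels: np.ndarray  # 2-D uint8 luminosities
    axis: str
    subject_id: str
    roi: str
    n_slices_used: int
    alpha_ref: int


@dataclass
class LuminosityDistribution:
    values: np.ndarray  # 1-D luminosities of foreground pixels
    subject_id: str
    roi: str
    axis: str
    background_rule: str = "exclude_zero"


@dataclass
class QQCurve:
    probs: np.ndarray
    qx: np.ndarray
    qy: np.ndarray
    labels: tuple[str, str]
    divergence: float


@dataclass
class PairSelection:
    label: str
    divergence: float
    margin: float
    tie: bool


# ---------------------------------------------------------------------------
# slicing and composites
# ---------------------------------------------------------------------------

def slice_mask(volume: MaskVolume, axis: str) -> list[np.ndarray]:
    """Nonzero 2-D slices of a mask along an anatomical axis, in order."""
    dim = volume.axis_index(axis)
    if volume.n_voxels == 0:
        raise EmptyMaskError(f"mask {volume.subject_id}/{volume.roi} is empty")
    stack = [
        np.take(volume.data, i, axis=dim)
        for i in range(volume.data.shape[dim])
    ]
    return [s for s in stack if s.any()]


def build_composite(
    stack: list[np.ndarray],
    alpha_ref: int,
    axis: str = "",
    subject_id: str = "",
    roi: str = "",
) -> CompositeImage:
    """Layer binary slices into an alpha-standardised luminosity composite."""
    if len(stack) == 0:
        raise EmptyMaskError("cannot build a composite from an empty stack")
    if alpha_ref < len(stack):
        raise StandardizationError(
            f"alpha_ref {alpha_ref} is smaller than the stack size {len(stack)}; "
            "luminosities would saturate asymmetrically between subjects"
        )
    counts = np.sum(np.stack(stack, axis=0).astype(np.int64), axis=0)
    lum = np.minimum(255, np.rint(255.0 * counts / alpha_ref)).astype(np.uint8)
    return CompositeImage(
        pixels=lum,
        axis=axis,
        subject_id=subject_id,
        roi=roi,
        n_slices_used=len(stack),
        alpha_ref=int(alpha_ref),
    )


def composite_from_mask(volume: MaskVolume, axis: str, alpha_ref: int) -> CompositeImage:
    stack = slice_mask(volume, axis)
    return build_composite(
        stack, alpha_ref, axis=axis, subject_id=volume.subject_id, roi=volume.roi
    )


def alpha_references(
    masks: dict[tuple[str, str], MaskVolume], axes: tuple[str, ...] = AXES
) -> dict[tuple[str, str], int]:
    """Per-(roi, axis) reference slice count: the maximum stack size over
    subjects, shared so that luminosities are comparable between subjects."""
    refs: dict[tuple[str, str], int] = {}
    for (subject, roi), vol in masks.items():
        for axis in axes:
            n = len(slice_mask(vol, axis))
            key = (roi, axis)
            refs[key] = max(refs.get(key, 0), n)
    return refs


def extract_distribution(
    image: CompositeImage, background_rule: str = "exclude_zero"
) -> LuminosityDistribution:
    """Multiset of luminosities over pixels passing the background rule.

    The default excludes zero-luminosity pixels (pixels absent from every
    slice); ``include_zero`` keeps the full pixel grid.
    """
    if background_rule == "exclude_zero":
        values = image.pixels[image.pixels > 0]
    elif background_rule == "include_zero":
        values = image.pixels.ravel()
    else:
        raise TwinscopeError(f"unknown background_rule {background_rule!r}")
    if values.size == 0:
        raise EmptyDistributionError(
            f"no pixels left for {image.subject_id}/{image.roi}/{image.axis}"
        )
    return LuminosityDistribution(
        values=np.sort(values.astype(np.float64)),
        subject_id=image.subject_id,
        roi=image.roi,
        axis=image.axis,
        background_rule=background_rule,
    )


# ---------------------------------------------------------------------------
# Q-Q comparison
# ---------------------------------------------------------------------------

def qq_compare(
    dA: LuminosityDistribution,
    dB: LuminosityDistribution,
    n_quantiles: int = 99,
) -> QQCurve:
    """Matched quantiles of two luminosity distributions.

    Quantile levels are k/(n_quantiles+1) for k = 1..n_quantiles, with
    linear interpolation between order statistics.  The divergence score is
    mean(|qx - qy|) / 255, zero iff the curve lies on the identity line.
    """
    if n_quantiles < 1:
        raise TwinscopeError("n_quantiles must be >= 1")
    probs = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    qx = np.quantile(dA.values, probs, method="linear")
    qy = np.quantile(dB.values, probs, method="linear")
    divergence = float(np.mean(np.abs(qx - qy)) / 255.0)
    return QQCurve(
        probs=probs,
        qx=qx,
        qy=qy,
        labels=(
            f"{dA.subject_id}:{dA.roi}:{dA.axis}",
            f"{dB.subject_id}:{dB.roi}:{dB.axis}",
        ),
        divergence=divergence,
    )


def enumerate_subject_pairs(cohort: FamilyCohort) -> dict[str, tuple[str, str]]:
    """The three labelled sibling pairs compared per ROI."""
    if len(cohort.siblings) != 3:
        raise CohortError("expected exactly 3 imaged siblings")
    return cohort.sibling_pairs()


def enumerate_roi_pairs(pathway: PathwayDefinition) -> list[tuple[str, str]]:
    """All unordered ROI pairs of a pathway: n(n-1)/2 combinations."""
    rois = list(pathway.rois)
    if len(rois) < 2:
        raise TwinscopeError(f"pathway {pathway.name!r} needs at least 2 rois")
    return [(a, b) for i, a in enumerate(rois) for b in rois[i + 1 :]]


def most_similar_pair(curves: dict[str, QQCurve], tol: float = 1e-12) -> PairSelection:
    """The sibling pair with minimal Q-Q divergence.

    Ties break toward the twin-twin pair (the declared baseline), then the
    SRD pair; the tie flag and the margin to the runner-up are reported.
    """
    if set(curves) != set(PAIR_LABELS):
        raise TwinscopeError(
            f"expected curves labelled {PAIR_LABELS}, got {sorted(curves)}"
        )
    priority = {PAIR_TWINS: 0, PAIR_SRD: 1, PAIR_TD_OS: 2}
    ranked = sorted(curves.items(), key=lambda kv: (kv[1].divergence, priority[kv[0]]))
    best_label, best = ranked[0]
    runner = ranked[1][1]
    margin = runner.divergence - best.divergence
    return PairSelection(
        label=best_label,
        divergence=best.divergence,
        margin=float(margin),
        tie=bool(margin <= tol),
    )


def most_similar_pair_pooled(
    curves: dict[str, list[QQCurve]], tol: float = 1e-12
) -> PairSelection:
    """Most similar sibling pair over several curves per pair (typically the
    three anatomical axes of one ROI), by summed divergence."""
    if set(curves) != set(PAIR_LABELS):
        raise TwinscopeError(
            f"expected curves labelled {PAIR_LABELS}, got {sorted(curves)}"
        )
    priority = {PAIR_TWINS: 0, PAIR_SRD: 1, PAIR_TD_OS: 2}
    totals = {label: float(sum(c.divergence for c in cs)) for label, cs in curves.items()}
    ranked = sorted(totals.items(), key=lambda kv: (kv[1], priority[kv[0]]))
    margin = ranked[1][1] - ranked[0][1]
    return PairSelection(
        label=ranked[0][0],
        divergence=ranked[0][1],
        margin=float(margin),
        tie=bool(margin <= tol),
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def save_mask(volume: MaskVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.uint8), volume.affine)
    nib.save(img, str(path))


def load_mask(path: str | Path, subject_id: str, roi: str) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return MaskVolume(data=data, affine=img.affine, subject_id=subject_id, roi=roi)


def save_composite_png(image: CompositeImage, path: str | Path) -> None:
    """8-bit grayscale PNG; byte-identical for identical inputs."""
    Image.fromarray(image.pixels, mode="L").save(str(path), format="PNG")
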