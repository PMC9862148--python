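"""Simulated ROI masks: ellipsoid-like slabs on a shared template grid.

Masks are deliberately simple geometry — connected ellipsoids whose
per-axis extents are drawn from the configured slice range — because the
luminosity analysis only consumes slice stacks, not realistic cortical
shape.  The per-axis nonzero slice count of a generated mask equals the
requested extent exactly, which makes slice-count behaviour testable by
construction.  Per-subject shape perturbations control how similar the
sibling masks are; optionally two designated siblings share their
perturbation so that a known most-similar pair is planted.
"""

from __future__ import annotations

import numpy as np

from ..cohort import FamilyCohort
from ..config import SimulationConfig
from ..errors import GeometryError
from ..luminosity import MaskVolume
from ..regions import canonical_roi


def ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    center: tuple[float, float, float],
    extents: tuple[int, int, int],
) -> np.ndarray:
    """Binary ellipsoid whose nonzero slice count along each axis equals
    ``extents`` exactly.

    The ellipsoid is centred on the middle of an ``extents``-sized bounding
    box anchored near ``center``; a slab exceeding the grid raises a
    geometry error.
    """
    extents = tuple(int(e) for e in extents)
    if any(e < 1 for e in extents):
        raise GeometryError(f"extents must be >= 1, got {extents}")
    starts = []
    for dim, (c, e) in enumerate(zip(center, extents)):
        start = int(round(c - (e - 1) / 2.0))
        if start < 0 or start + e > grid_shape[dim]:
            raise GeometryError(
                f"extent {e} at center {c} exceeds grid dimension {grid_shape[dim]}"
            )
        starts.append(start)

    coords = np.indices(grid_shape, dtype=np.float64)
    q = np.zeros(grid_shape, dtype=np.float64)
    for dim, (start, e) in enumerate(zip(starts, extents)):
        ceff = start + (e - 1) / 2.0
        q += ((coords[dim] - ceff) / (e / 2.0)) ** 2
    mask = (q < 1.0).astype(np.uint8)

    # Guarantee the extreme planes of very anisotropic slabs: an empty plane
    # inside the bounding box gets its central voxel set, keeping the
    # per-axis slice count exactly at the requested extent.
    center_voxel = [int(round(s + (e - 1) / 2.0)) for s, e in zip(starts, extents)]
    for dim, (start, e) in enumerate(zip(starts, extents)):
        for plane in range(start, start + e):
            sl = [slice(None)] * 3
            sl[dim] = plane
            if not mask[tuple(sl)].any():
                idx = list(center_voxel)
                idx[dim] = plane
                mask[tuple(idx)] = 1
    return mask


def simulate_masks(
    cohort: FamilyCohort, roi_set: list[str], cfg: SimulationConfig
) -> dict[tuple[str, str], MaskVolume]:
    """Per-(subject, roi) masks for the three imaged siblings."""
    cfg.validate()
    rois = [canonical_roi(r) for r in roi_set]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    lo, hi = cfg.mask_slices_per_axis
    grid = tuple(cfg.grid_shape)
    max_extent = min(min(grid) - 2, hi)
    if max_extent < lo:
        raise GeometryError(
            f"slice range {cfg.mask_slices_per_axis} does not fit grid {grid}"
        )

    sibs = [
        cohort.proband.subject_id,
        cohort.td_twin.subject_id,
        cohort.older_sibling.subject_id,
    ]
    similar_ids: tuple[str, str] | None = None
    if cfg.mask_similar_pair is not None:
        pairs = cohort.sibling_pairs()
        if cfg.mask_similar_pair not in pairs:
            raise GeometryError(f"unknown pair label {cfg.mask_similar_pair!r}")
        similar_ids = pairs[cfg.mask_similar_pair]

    affine = np.eye(4)  # RAS+, 1 mm isotropic template grid
    out: dict[tuple[str, str], MaskVolume] = {}
    for roi in rois:
        base = rng.integers(lo, max_extent + 1, size=3).astype(float)
        center = tuple(g / 2.0 + rng.uniform(-2, 2) for g in grid)
        shared_dev = rng.normal(0.0, cfg.mask_jitter, size=3)
        for sid in sibs:
            if similar_ids is not None and sid in similar_ids:
                dev = shared_dev + rng.normal(0.0, cfg.mask_pair_jitter, size=3)
            else:
                dev = rng.normal(0.0, cfg.mask_jitter, size=3)
            extents = np.clip(np.rint(base + dev), lo, max_extent).astype(int)
            data = ellipsoid_mask(grid, center, tuple(extents))
            out[(sid, roi)] = MaskVolume(
                data=data, affine=affine, subject_id=sid, roi=roi
            )
    return out
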