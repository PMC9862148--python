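"""Simulated sibling morphometry with controllable pairwise similarity and
planted hemispheric asymmetry.

Per phenotype, the three sibling item vectors (one value per ROI x
hemisphere) are correlated Gaussians whose 3x3 correlation matrix is built
from the configured pair targets, so the across-item Pearson correlation —
and hence the pairwise ICC, since means and variances match — approaches
the target as the ROI set grows.  Thickness values are Gaussian around a
cortex-typical 2.6 mm; area and volume are log-normal.  Entries of the
asymmetry profile are then planted exactly by solving (L, R) from the index
and the pair mean, which leaves the mean untouched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..cohort import PAIR_SRD, PAIR_TD_OS, PAIR_TWINS, FamilyCohort
from ..config import PHENOTYPES, SimulationConfig
from ..errors import ConfigError
from ..morphometry import HEMIS, MorphometryTable
from ..regions import canonical_roi

#: distribution of each phenotype on its natural scale
_SCALES = {
    "thickness": ("normal", 2.6, 0.30),   # mm
    "area": ("lognormal", np.log(600.0), 0.35),    # mm^2
    "volume": ("lognormal", np.log(1800.0), 0.35),  # mm^3
}

#: similarity applied to phenotypes absent from the profile
_DEFAULT_TARGET = 0.9


def _correlation_factor(targets: dict[str, float]):
    """Lower factor L with L L^T = R for the 3-subject correlation matrix
    in (proband, td_twin, older_sibling) order."""
    r_tw = targets.get(PAIR_TWINS, _DEFAULT_TARGET)
    r_srd = targets.get(PAIR_SRD, _DEFAULT_TARGET)
    r_tdos = targets.get(PAIR_TD_OS, _DEFAULT_TARGET)
    R = np.array([[1.0, r_tw, r_srd], [r_tw, 1.0, r_tdos], [r_srd, r_tdos, 1.0]])
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise ConfigError(
            f"similarity targets {targets} are not jointly attainable "
            "(correlation matrix not positive semidefinite)"
        )
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_morphometry(
    cohort: FamilyCohort, roi_set: list[str], cfg: SimulationConfig
) -> MorphometryTable:
    """Generate the three siblings' ROI morphometry table."""
    cfg.validate()
    if len(roi_set) == 0:
        raise ConfigError("roi_set must be non-empty")
    rois = [canonical_roi(r) for r in roi_set]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    sibs = [
        cohort.proband.subject_id,
        cohort.td_twin.subject_id,
        cohort.older_sibling.subject_id,
    ]
    items = [(r, h) for r in rois for h in HEMIS]

    rows = []
    values: dict[tuple[str, str, str, str], float] = {}
    for phenotype in PHENOTYPES:
        targets = cfg.similarity_profile.get(phenotype, {})
        L = _correlation_factor(targets)
        z = rng.standard_normal((len(items), 3)) @ L.T
        kind, mu, sigma = _SCALES[phenotype]
        if kind == "normal":
            vals = np.clip(mu + sigma * z, 0.5, None)
        else:
            vals = np.exp(mu + sigma * z)
        for (roi, hemi), row in zip(items, vals):
            for sid, v in zip(sibs, row):
                values[(sid, hemi, roi, phenotype)] = float(v)

    # plant the configured asymmetry indices exactly, preserving the mean
    for (sid, roi, phenotype), a in cfg.asymmetry_profile.items():
        roi = canonical_roi(roi)
        if sid not in sibs or roi not in rois or phenotype not in PHENOTYPES:
            continue
        l_key = (sid, "lh", roi, phenotype)
        r_key = (sid, "rh", roi, phenotype)
        m = (values[l_key] + values[r_key]) / 2.0
        values[l_key] = m * (1.0 + a / 2.0)
        values[r_key] = m * (1.0 - a / 2.0)

    for (sid, hemi, roi, phenotype), v in values.items():
        rows.append((sid, hemi, roi, phenotype, v))
    return MorphometryTable(
        pd.DataFrame(rows, columns=["subject_id", "hemi", "roi", "phenotype", "value"])
    )
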