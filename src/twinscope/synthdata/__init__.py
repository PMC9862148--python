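"""Synthetic family data with known ground truth.

Everything downstream of raw data acquisition is exercisable from this
module alone: a five-member nuclear family, a reading-gene SNP panel with
planted co-segregation structure, sibling morphometry with controllable
pairwise similarity and planted asymmetry, and template-space ROI masks.
All randomness derives from ``SimulationConfig.seed``; regenerating any
artifact from the same config is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from ..cohort import FamilyCohort
from ..config import SimulationConfig
from ..io import write_ped, write_vcf
from ..morphometry import write_morphometry
from ..luminosity import save_mask
from ..panel import GenePanel, default_panel
from ..regions import PATHWAY_ROIS, WHOLE_CORTEX_SET
from .genotypes import SimulatedGenotypes, simulate_genotypes
from .masks import ellipsoid_mask, simulate_masks
from .morphometry import simulate_morphometry

__all__ = [
    "SimulatedGenotypes",
    "simulate_genotypes",
    "simulate_morphometry",
    "simulate_masks",
    "ellipsoid_mask",
    "generate_fixtures",
]


def generate_fixtures(
    cfg: SimulationConfig,
    outdir: str | Path,
    cohort: FamilyCohort | None = None,
    panel: GenePanel | None = None,
    morphometry_rois: list[str] | None = None,
    mask_rois: list[str] | None = None,
) -> dict:
    """Write the full fixture set (VCF, pedigree, morphometry TSV, NIfTI
    masks) plus a ground-truth ledger JSON; returns the ledger."""
    cohort = cohort or FamilyCohort.default()
    panel = panel or default_panel()
    morphometry_rois = morphometry_rois or list(WHOLE_CORTEX_SET.rois)
    mask_rois = mask_rois or list(PATHWAY_ROIS)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim = simulate_genotypes(cohort, panel, cfg)
    write_vcf(sim.table, outdir / "family.vcf")
    write_ped(cohort, outdir / "family.ped")
    panel.to_tsv(outdir / "panel.tsv")

    morpho = simulate_morphometry(cohort, morphometry_rois, cfg)
    write_morphometry(morpho, outdir / "morphometry.tsv")

    masks = simulate_masks(cohort, mask_rois, cfg)
    mask_dir = outdir / "masks"
    mask_dir.mkdir(exist_ok=True)
    for (sid, roi), vol in masks.items():
        save_mask(vol, mask_dir / f"{sid}__{roi}.nii.gz")

    ledger = {
        "seed": cfg.seed,
        "genotypes": sim.ground_truth(),
        "morphometry_rois": morphometry_rois,
        "mask_rois": mask_rois,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
    return ledger
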