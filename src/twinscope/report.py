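"""End-to-end orchestration: genetics -> morphometry -> luminosity ->
structured summary.

A single :class:`PipelineConfig` drives the run.  Each data class
(genotypes, morphometry, masks) comes either from files or from the
synthetic generator — exactly one source per class.  The rendered summary
mirrors the case study's result structure: a genetics section (per-gene and
functional-class tallies with the genome-background comparison), an
asymmetry section (ICCs and asymmetry directions), and an image-analysis
section (most-similar sibling pair per ROI, per pathway).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohort import FamilyCohort
from .config import PHENOTYPES, SimulationConfig
from .errors import ConfigError, TwinscopeError
from .genetics import (
    CosegregationResult,
    annotate_snps,
    apply_gencall_qc,
    background_comparison,
    drop_family_invariant_snps,
    find_cosegregating_snps,
    split_panel_background,
)
from .io import read_ped, read_vcf, write_ped, write_vcf
from .luminosity import (
    AXES,
    DEFAULT_PATHWAYS,
    alpha_references,
    composite_from_mask,
    enumerate_roi_pairs,
    enumerate_subject_pairs,
    extract_distribution,
    load_mask,
    most_similar_pair,
    qq_compare,
    save_composite_png,
    save_mask,
)
from .morphometry import (
    ICCResult,
    MorphometryTable,
    asymmetry_table,
    pairwise_icc,
    read_morphometry,
    write_morphometry,
)
from .panel import GenePanel, default_panel
from .regions import (
    ASYMMETRY_ROIS,
    PATHWAY_ROIS,
    READING_SET,
    WHOLE_CORTEX_SET,
    RegionSet,
)
from .synthdata import simulate_genotypes, simulate_masks, simulate_morphometry

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: Path = Path("twinscope_out")
    # real-data inputs; when None the corresponding class is simulated
    vcf_path: Path | None = None
    ped_path: Path | None = None
    morphometry_path: Path | None = None
    masks_dir: Path | None = None
    # analysis options
    gc_threshold: float = 0.15
    icc_form: str = "ICC(2,1)"
    epsilon: float = 0.01
    n_quantiles: int = 99
    background_rule: str = "exclude_zero"
    axes: tuple[str, ...] = AXES
    mask_rois: tuple[str, ...] = PATHWAY_ROIS
    make_plots: bool = False

    def validate(self) -> None:
        self.sim.validate()
        if (self.vcf_path is None) != (self.ped_path is None):
            raise ConfigError("vcf_path and ped_path must be given together")
        if not (0 <= self.gc_threshold <= 1):
            raise ConfigError("gc_threshold must be in [0, 1]")

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        payload = _jsonable(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (PipelineConfig, SimulationConfig)):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {
            ("|".join(map(str, k)) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


@dataclass
class StudyReport:
    genetics: dict
    icc: list[dict]
    asymmetry: list[dict]
    image: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "genetics": self.genetics,
            "icc": self.icc,
            "asymmetry": self.asymmetry,
            "image": self.image,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _genetics_stage(cfg: PipelineConfig, cohort: FamilyCohort, panel: GenePanel, outdir: Path) -> dict:
    if cfg.vcf_path is not None:
        table = read_vcf(cfg.vcf_path)
        sim_truth = None
    else:
        sim = simulate_genotypes(cohort, panel, cfg.sim)
        table = sim.table
        write_vcf(table, outdir / "family.vcf")
        write_ped(cohort, outdir / "family.ped")
        sim_truth = sim.ground_truth()

    table = annotate_snps(table, panel)
    qcd = apply_gencall_qc(table, cfg.gc_threshold)
    variable = drop_family_invariant_snps(qcd, cohort.subject_ids)
    panel_table, bg_table = split_panel_background(variable, panel)
    result = find_cosegregating_snps(
        panel_table, cohort.affected_sibling_ids, cohort.discordant_id
    )
    background_comparison(
        result, bg_table, cohort.affected_sibling_ids, cohort.discordant_id
    )
    out = result.to_dict()
    out["n_snps_input"] = len(table)
    out["n_background_variable"] = len(bg_table)
    out["gc_threshold"] = cfg.gc_threshold
    if sim_truth is not None:
        out["ground_truth"] = sim_truth
    with open(outdir / "coseg_results.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    sub = panel_table.df[panel_table.df.snp_id.isin(result.matching_snps)]
    sub[["snp_id", "chrom", "pos", "ref", "alt", "gene_symbol", "functional_class"]].to_csv(
        outdir / "coseg_snps.tsv", sep="\t", index=False
    )
    return out


def _morphometry_stage(cfg: PipelineConfig, cohort: FamilyCohort, outdir: Path):
    if cfg.morphometry_path is not None:
        table = read_morphometry(cfg.morphometry_path)
    else:
        table = simulate_morphometry(cohort, list(WHOLE_CORTEX_SET.rois), cfg.sim)
        write_morphometry(table, outdir / "morphometry.tsv")

    pairs = cohort.sibling_pairs()
    whole = RegionSet("whole_cortex", tuple(table.rois))
    icc_results: list[ICCResult] = []
    for region_set in (whole, READING_SET):
        for phenotype in PHENOTYPES:
            for label, pair in pairs.items():
                res = pairwise_icc(table, pair, phenotype, region_set, cfg.icc_form)
                d = res.to_dict()
                d["pair_label"] = label
                icc_results.append(d)

    asym_set = RegionSet("asymmetry", ASYMMETRY_ROIS)
    asym_records = []
    for phenotype in PHENOTYPES:
        for rec in asymmetry_table(table, asym_set, phenotype, cfg.epsilon):
            asym_records.append(rec.__dict__)

    icc_df_rows = [
        "\t".join(
            str(x)
            for x in (
                d["pair_label"], d["pair"][0], d["pair"][1], d["phenotype"],
                d["region_set"], d["icc_form"], f"{d['icc']:.6f}", d["n_items"],
            )
        )
        for d in icc_results
    ]
    (outdir / "icc_results.tsv").write_text(
        "pair_label\tsubject_a\tsubject_b\tphenotype\tregion_set\ticc_form\ticc\tn_items\n"
        + "\n".join(icc_df_rows)
        + "\n"
    )
    import pandas as pd

    pd.DataFrame(asym_records).to_csv(outdir / "asymmetry_table.tsv", sep="\t", index=False)
    return icc_results, asym_records, table


def _luminosity_stage(cfg: PipelineConfig, cohort: FamilyCohort, outdir: Path) -> dict:
    if cfg.masks_dir is not None:
        masks = {}
        for p in sorted(Path(cfg.masks_dir).glob("*.nii*")):
            stem = p.name.split(".")[0]
            sid, roi = stem.split("__", 1)
            masks[(sid, roi)] = load_mask(p, sid, roi)
    else:
        masks = simulate_masks(cohort, list(cfg.mask_rois), cfg.sim)
        mask_dir = outdir / "masks"
        mask_dir.mkdir(exist_ok=True)
        for (sid, roi), vol in masks.items():
            save_mask(vol, mask_dir / f"{sid}__{roi}.nii.gz")

    rois = sorted({roi for (_, roi) in masks})
    refs = alpha_references(masks, cfg.axes)
    comp_dir = outdir / "composites"
    comp_dir.mkdir(exist_ok=True)
    distributions = {}
    for (sid, roi), vol in sorted(masks.items()):
        for axis in cfg.axes:
            comp = composite_from_mask(vol, axis, refs[(roi, axis)])
            save_composite_png(comp, comp_dir / f"{sid}__{roi}__{axis}.png")
            distributions[(sid, roi, axis)] = extract_distribution(comp, cfg.background_rule)

    subject_pairs = enumerate_subject_pairs(cohort)
    qq_dir = outdir / "qq"
    qq_dir.mkdir(exist_ok=True)
    inter = {}
    for roi in rois:
        for axis in cfg.axes:
            curves = {}
            for label, (a, b) in subject_pairs.items():
                curve = qq_compare(
                    distributions[(a, roi, axis)],
                    distributions[(b, roi, axis)],
                    cfg.n_quantiles,
                )
                curves[label] = curve
                with open(qq_dir / f"{roi}__{axis}__{label}.tsv", "w") as fh:
                    fh.write("prob\tqx\tqy\n")
                    for p_, x, y in zip(curve.probs, curve.qx, curve.qy):
                        fh.write(f"{p_:.6f}\t{x:.6f}\t{y:.6f}\n")
            pick = most_similar_pair(curves)
            inter[f"{roi}|{axis}"] = {
                "divergence": {k: c.divergence for k, c in curves.items()},
                "most_similar_pair": pick.label,
                "margin": pick.margin,
                "tie": pick.tie,
            }

    intra = {}
    for pathway in DEFAULT_PATHWAYS:
        available = [r for r in pathway.rois if r in rois]
        pw = {"rois": available, "n_pairs": 0, "comparisons": {}}
        if len(available) >= 2:
            roi_pairs = enumerate_roi_pairs(
                type(pathway)(pathway.name, pathway.function, tuple(available))
            )
            pw["n_pairs"] = len(roi_pairs)
            for ra, rb in roi_pairs:
                for axis in cfg.axes:
                    entry = {}
                    for sid in (s.subject_id for s in cohort.siblings):
                        curve = qq_compare(
                            distributions[(sid, ra, axis)],
                            distributions[(sid, rb, axis)],
                            cfg.n_quantiles,
                        )
                        entry[sid] = curve.divergence
                    pw["comparisons"][f"{ra}~{rb}|{axis}"] = entry
        intra[pathway.name] = pw

    summary = {
        "alpha_references": {f"{r}|{a}": v for (r, a), v in sorted(refs.items())},
        "inter_subject": inter,
        "intra_subject": intra,
    }
    with open(outdir / "qq_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, cohort: FamilyCohort | None = None) -> StudyReport:
    """Execute synthdata (where requested) -> genetics -> morphometry ->
    luminosity and write all artifacts plus ``report.json``/``report.txt``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = read_ped(cfg.ped_path) if cfg.ped_path is not None else FamilyCohort.default()
    panel = default_panel()

    stages = {}
    current = "genetics"
    try:
        stages["genetics"] = _genetics_stage(cfg, cohort, panel, outdir)
        current = "morphometry"
        icc_results, asym_records, morpho_table = _morphometry_stage(cfg, cohort, outdir)
        current = "luminosity"
        image = _luminosity_stage(cfg, cohort, outdir)
    except TwinscopeError as err:
        manifest = sorted(p.name for p in outdir.iterdir())
        raise TwinscopeError(
            f"pipeline stage {current!r} failed: {err}; partial artifacts: {manifest}"
        ) from err

    report = StudyReport(
        genetics=stages["genetics"],
        icc=icc_results,
        asymmetry=asym_records,
        image=image,
        provenance={
            "package_version": __version__,
            "seed": cfg.sim.seed,
            "config_hash": cfg.config_hash(),
            "icc_form": cfg.icc_form,
            "n_morphometry_rois": len(morpho_table.rois),
            "epsilon": cfg.epsilon,
            "n_quantiles": cfg.n_quantiles,
            "background_rule": cfg.background_rule,
        },
    )
    _verify_tallies(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    (outdir / "report.txt").write_text(render_summary(report))
    if cfg.make_plots:
        from . import plots

        plots.asymmetry_bars(asym_records, outdir / "asymmetry_plots")
    return report


def _verify_tallies(report: StudyReport) -> None:
    g = report.genetics
    n = g["n_matching"]
    if sum(g["per_gene_counts"].values()) != n or sum(g["per_class_counts"].values()) != n:
        raise TwinscopeError("tally conservation violated in genetics summary")


def render_summary(report: StudyReport) -> str:
    """Human-readable three-section summary of the primary results."""
    g = report.genetics
    lines = []
    lines.append("=" * 64)
    lines.append("Genetics Results")
    lines.append("=" * 64)
    lines.append(
        f"Variable SNPs in reading-gene panel: {g['n_panel_variable']}"
    )
    lines.append(f"Co-segregating SNPs (affected siblings match, twin differs): {g['n_matching']}")
    if g["panel_proportion"] is not None:
        lines.append(f"Panel proportion: {g['panel_proportion']:.4f}")
    if g.get("background_proportion") is not None:
        lines.append(f"Genome background proportion: {g['background_proportion']:.4f}")
    lines.append("Per-gene counts:")
    for gene, count in sorted(g["per_gene_counts"].items(), key=lambda kv: (-kv[1], kv[0])):
        lines.append(f"  {gene:10s} {count}")
    lines.append("Functional classes:")
    for fc, count in sorted(g["per_class_counts"].items(), key=lambda kv: (-kv[1], kv[0])):
        lines.append(f"  {fc:10s} {count}")

    lines.append("")
    lines.append("=" * 64)
    lines.append("Asymmetry Analyses")
    lines.append("=" * 64)
    form = report.provenance["icc_form"]
    lines.append(f"Pairwise ICCs ({form}); items are (ROI, hemisphere) averages:")
    for d in report.icc:
        lines.append(
            f"  {d['pair_label']:10s} {d['phenotype']:10s} {d['region_set']:14s} "
            f"ICC={d['icc']:+.3f} (n={d['n_items']})"
        )
    lines.append("Asymmetry directions (index = (L-R)/((L+R)/2)):")
    for rec in report.asymmetry:
        lines.append(
            f"  {rec['subject_id']:14s} {rec['phenotype']:10s} {rec['roi']:26s} "
            f"{rec['index']:+.3f} {rec['direction']}"
        )

    lines.append("")
    lines.append("=" * 64)
    lines.append("Image Analyses")
    lines.append("=" * 64)
    inter = report.image["inter_subject"]
    lines.append("Most similar sibling pair by luminosity Q-Q divergence:")
    for key in sorted(inter):
        e = inter[key]
        tie = " (tie)" if e["tie"] else ""
        lines.append(
            f"  {key:36s} -> {e['most_similar_pair']}{tie} "
            f"(divergence {e['divergence'][e['most_similar_pair']]:.4f})"
        )
    for name, pw in report.image["intra_subject"].items():
        lines.append(f"Pathway {name}: {pw['n_pairs']} ROI pairs compared within subjects")
    lines.append("")
    return "\n".join(lines)
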