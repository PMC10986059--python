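"""End-to-end orchestration: simulate → quantify → analyze.

Each stage is a plain function over a :class:`~chorioquant.config.RunConfig`
and a directory; one seed in the config drives every stochastic step, so
two runs with equal configs produce byte-identical outputs.  A JSON
manifest lists every file written by ``simulate`` with its derived seed;
``quantify`` fails fast, naming the file, when an image's boundary sidecar
is missing.
"""

from __future__ import annotations

import logging
import time as _time
from pathlib import Path

import pandas as pd

from . import io as cqio
from .choriocapillaris import EnFaceAngio, FdThresholdSpec, compensate_enface, compute_ccfd
from .config import RunConfig
from .geometry import ScanGeometry
from .stats import (
    NearWorkChangeModel,
    bonferroni,
    changes_table,
    paired_change_test,
    rm_anova_gg,
)
from .synth.angio import AngioParams, generate_cc_enface
from .synth.bscan import SceneParams, generate_bscan_scene
from .synth.cohort import METRICS, CohortSimParams, generate_cohort
from .vascularity import NiblackParams, average_meridians, quantify_bscan

logger = logging.getLogger("chorioquant")

STRUCT_COLUMNS = [
    "subject", "visit_min", "phase", "meridian",
    "SFCT_um", "LA_um2", "SA_um2", "TCA_um2", "CVI_pct",
]
CCFD_COLUMNS = ["subject", "visit_min", "phase", "ccfd_pct", "n_roi_px"]
COHORT_COLUMNS = ["subject", "group", "visit_min", "phase", "metric", "value", "al_mm"]

_MERIDIANS = ("vertical", "horizontal")


def _setup_run_logging(out_dir: Path, verbose: bool = False) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    have = {getattr(h, "_cq_tag", None) for h in logger.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler()
        h._cq_tag = "stderr"
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(h)
    for h in [h for h in logger.handlers if getattr(h, "_cq_tag", None) == "file"]:
        logger.removeHandler(h)
        h.close()
    fh = logging.FileHandler(out_dir / "run.log", mode="a")
    fh._cq_tag = "file"
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def _derived_seed(base: int, idx: int) -> int:
    return int((base * 1_000_003 + idx) % (2**31 - 1))


def run_simulate(config: RunConfig, out_dir: str | Path | None = None, verbose: bool = False) -> Path:
    """Generate the full synthetic dataset described by the config.

    Writes B-scan TIFFs with truth sidecars (two meridians per subject,
    visit and phase), en-face angiogram TIFFs with reference images and
    truth sidecars (one per subject, visit and phase), the statistical
    cohort CSV, and a manifest listing every file with its seed.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    _setup_run_logging(out, verbose)
    t0 = _time.perf_counter()
    (out / "scenes").mkdir(parents=True, exist_ok=True)
    (out / "angio").mkdir(parents=True, exist_ok=True)

    files: list[dict] = []
    idx = 0
    sc = config.scene
    for s in range(1, config.n_imaging_subjects + 1):
        subject = f"S{s:03d}"
        for visit in config.visits_min:
            for phase in ("pre", "post"):
                for meridian in _MERIDIANS:
                    seed = _derived_seed(config.seed, idx)
                    idx += 1
                    params = SceneParams(
                        image_width_px=sc.image_width_px,
                        image_height_px=sc.image_height_px,
                        lateral_um_per_px=sc.lateral_um_per_px,
                        axial_um_per_px=sc.axial_um_per_px,
                        choroid_thickness_um=sc.choroid_thickness_um,
                        target_lumen_fraction=sc.target_lumen_fraction,
                        vessel_radius_range_um=(sc.vessel_radius_min_um, sc.vessel_radius_max_um),
                        stroma_mean=sc.stroma_mean,
                        lumen_mean=sc.lumen_mean,
                        speckle_shape=sc.speckle_shape,
                        roi_width_mm=config.roi_width_mm,
                        seed=seed,
                    )
                    image, truth = generate_bscan_scene(params)
                    stem = f"{subject}_v{visit}_{phase}_{meridian}"
                    img_path = out / "scenes" / f"{stem}.tiff"
                    cqio.save_image(img_path, image)
                    sidecar = truth.to_json_dict()
                    sidecar.update({
                        "subject": subject, "visit_min": visit, "phase": phase,
                        "meridian": meridian, "al_mm": config.reference_al_mm,
                        "lateral_um_per_px": sc.lateral_um_per_px,
                        "axial_um_per_px": sc.axial_um_per_px, "seed": seed,
                    })
                    cqio.save_json(img_path.with_suffix(".json"), sidecar)
                    files.append({"path": str(img_path.relative_to(out)),
                                  "kind": "bscan", "seed": seed})
                ang_seed = _derived_seed(config.seed, idx)
                idx += 1
                an = config.angio
                aparams = AngioParams(
                    image_size_px=an.image_size_px,
                    lateral_um_per_px=an.lateral_um_per_px,
                    target_fd_fraction=an.target_fd_fraction,
                    perfused_mean=an.perfused_mean,
                    deficit_mean=an.deficit_mean,
                    noise_sd=an.noise_sd,
                    shadow_attenuation=an.shadow_attenuation,
                    projection_vessel_width_um=an.projection_vessel_width_um,
                    eval_circle_diameter_mm=config.circle_diameter_mm,
                    seed=ang_seed,
                )
                aimage, atruth = generate_cc_enface(aparams)
                stem = f"{subject}_v{visit}_{phase}_cc"
                apath = out / "angio" / f"{stem}.tiff"
                cqio.save_image(apath, aimage)
                cqio.save_image(out / "angio" / f"{stem}_ref.tiff", atruth.reference_image)
                asc = atruth.to_json_dict()
                asc.update({
                    "subject": subject, "visit_min": visit, "phase": phase,
                    "al_mm": config.reference_al_mm,
                    "lateral_um_per_px": an.lateral_um_per_px, "seed": ang_seed,
                })
                cqio.save_json(apath.with_suffix(".json"), asc)
                files.append({"path": str(apath.relative_to(out)),
                              "kind": "angio", "seed": ang_seed})

    cohort = generate_cohort(CohortSimParams(
        n_per_group=config.cohort.n_per_group, seed=_derived_seed(config.seed, 900_000)
    ))
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False, float_format="%.6f")
    files.append({"path": "cohort.csv", "kind": "cohort",
                  "seed": _derived_seed(config.seed, 900_000)})

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "files": files,
    }
    cqio.save_json(out / "manifest.json", manifest)
    logger.info("simulate: wrote %d files to %s in %.2fs (config %s)",
                len(files), out, _time.perf_counter() - t0, config.config_hash())
    return out


def run_quantify(config: RunConfig, dataset_dir: str | Path,
                 out_dir: str | Path | None = None, verbose: bool = False) -> Path:
    """Quantify every simulated image into per-visit metric CSVs."""
    dataset = Path(dataset_dir)
    out = Path(out_dir if out_dir is not None else dataset)
    _setup_run_logging(out, verbose)
    t0 = _time.perf_counter()
    manifest = cqio.load_json(dataset / "manifest.json")
    niblack = NiblackParams(window_px=config.niblack.window_px, k=config.niblack.k)
    fd_spec = FdThresholdSpec(
        sigma_ref=config.fd_threshold.sigma_ref, multiplier=config.fd_threshold.multiplier
    )

    struct_rows: list[dict] = []
    ccfd_rows: list[dict] = []
    per_scan: dict[tuple, dict[str, object]] = {}
    for entry in manifest["files"]:
        path = dataset / entry["path"]
        if entry["kind"] == "bscan":
            image = cqio.load_image(path)
            sidecar = cqio.load_json(path.with_suffix(".json"))
            boundaries = cqio.boundaries_from_sidecar(sidecar)
            geom = ScanGeometry(
                lateral_um_per_px=sidecar["lateral_um_per_px"],
                axial_um_per_px=sidecar["axial_um_per_px"],
                fovea_col=int(sidecar["fovea_col"]),
                al_mm=sidecar["al_mm"],
                reference_al_mm=config.reference_al_mm,
            )
            m = quantify_bscan(image, boundaries, geom, niblack=niblack,
                               roi_width_mm=config.roi_width_mm,
                               meridian=sidecar["meridian"])
            key = (sidecar["subject"], sidecar["visit_min"], sidecar["phase"])
            per_scan.setdefault(key, {})[sidecar["meridian"]] = m
        elif entry["kind"] == "angio":
            image = cqio.load_image(path)
            sidecar = cqio.load_json(path.with_suffix(".json"))
            enface = EnFaceAngio(image=image, lateral_um_per_px=sidecar["lateral_um_per_px"])
            ref_path = path.with_name(path.stem + "_ref.tiff")
            if ref_path.exists():
                reference = cqio.load_image(ref_path)
                enface = compensate_enface(enface, reference)
            res = compute_ccfd(enface, fd_spec, circle_diameter_mm=config.circle_diameter_mm,
                               al_mm=sidecar["al_mm"], reference_al_mm=config.reference_al_mm)
            ccfd_rows.append({
                "subject": sidecar["subject"], "visit_min": sidecar["visit_min"],
                "phase": sidecar["phase"], "ccfd_pct": res.ccfd_pct,
                "n_roi_px": res.n_roi_px,
            })

    for (subject, visit, phase), meridians in sorted(per_scan.items()):
        for name, m in sorted(meridians.items()):
            struct_rows.append({
                "subject": subject, "visit_min": visit, "phase": phase,
                "meridian": name, "SFCT_um": m.SFCT, "LA_um2": m.LA,
                "SA_um2": m.SA, "TCA_um2": m.TCA, "CVI_pct": m.CVI,
            })
        if set(meridians) >= set(_MERIDIANS):
            avg = average_meridians(meridians["vertical"], meridians["horizontal"])
            struct_rows.append({
                "subject": subject, "visit_min": visit, "phase": phase,
                "meridian": "averaged", "SFCT_um": avg.SFCT, "LA_um2": avg.LA,
                "SA_um2": avg.SA, "TCA_um2": avg.TCA, "CVI_pct": avg.CVI,
            })

    sdf = pd.DataFrame(struct_rows, columns=STRUCT_COLUMNS)
    cdf = pd.DataFrame(ccfd_rows, columns=CCFD_COLUMNS)
    sdf.to_csv(out / "structural_metrics.csv", index=False, float_format="%.6f")
    cdf.to_csv(out / "ccfd_metrics.csv", index=False, float_format="%.6f")
    logger.info("quantify: %d B-scans, %d angiograms in %.2fs",
                len(struct_rows), len(ccfd_rows), _time.perf_counter() - t0)
    return out


def analyze_cohort(cohort: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Cohort-level statistics from a long metrics table.

    Returns a dict with:

    * ``trend`` — per (group, metric, duration): mean/SD change, paired t,
      raw and Bonferroni-adjusted p (m = number of durations per
      group × metric family), direction arrow and significance stars, plus
      a non-gating Shapiro–Wilk normality p of the change scores.
    * ``time_effect`` — per metric: Greenhouse–Geisser-adjusted
      repeated-measures ANOVA of the percent changes across durations.
    * ``group_contrast`` — per metric: AL-adjusted between-group difference
      in percent change with cluster-robust SE and p.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    ch = changes_table(cohort)

    trend_rows = []
    for (group, metric), sub in ch.groupby(["group", "metric"]):
        durations = sorted(sub["visit_min"].unique())
        m = len(durations)
        raw = {}
        for dur in durations:
            deltas = sub.loc[sub["visit_min"] == dur, "delta"].to_numpy()
            t, p = paired_change_test(deltas)
            from scipy import stats as sps
            sw_p = float(sps.shapiro(deltas).pvalue) if len(deltas) >= 3 else float("nan")
            raw[dur] = (deltas, t, p, sw_p)
        p_adj = bonferroni([raw[d][2] for d in durations], m=m)
        for dur, padj in zip(durations, p_adj):
            deltas, t, p, sw_p = raw[dur]
            mean = float(deltas.mean())
            stars = "***" if padj < 0.001 else "**" if padj < 0.01 else "*" if padj < alpha else ""
            arrow = ("↑" if mean > 0 else "↓") if stars else ""
            trend_rows.append({
                "group": group, "metric": metric, "visit_min": dur,
                "mean_change": mean, "sd_change": float(deltas.std(ddof=1)),
                "t": t, "p_raw": p, "p_bonferroni": float(padj), "m_comparisons": m,
                "direction": arrow, "significance": stars, "shapiro_p": sw_p,
            })
    trend = pd.DataFrame(trend_rows)

    time_rows = []
    for metric, sub in ch.groupby("metric"):
        wide = sub.pivot_table(index="subject", columns="visit_min", values="pct_change")
        wide = wide.dropna()
        if wide.shape[1] >= 2 and wide.shape[0] > wide.shape[1]:
            r = rm_anova_gg(wide.to_numpy())
            time_rows.append({
                "metric": metric, "F": r.F, "df1": r.df1, "df2": r.df2,
                "epsilon_gg": r.epsilon_gg, "p": r.p,
            })
    time_effect = pd.DataFrame(time_rows)

    contrast_rows = []
    if cohort["group"].nunique() == 2:
        for metric in sorted(ch["metric"].unique()):
            res = NearWorkChangeModel.from_dataframe(
                cohort, metric, durations=sorted(ch["visit_min"].unique())
            ).fit()
            c = res.contrast
            contrast_rows.append({
                "metric": metric,
                "difference_pct": c.adjusted_mean_difference,
                "se": c.se, "p": c.p,
                "contrast": f"{c.groups[1]} - {c.groups[0]}",
            })
    group_contrast = pd.DataFrame(contrast_rows)
    return {"trend": trend, "time_effect": time_effect, "group_contrast": group_contrast}


def run_analyze(config: RunConfig, cohort_csv: str | Path,
                out_dir: str | Path | None = None, verbose: bool = False) -> Path:
    """Run the statistical layer on a cohort CSV and write tables + report."""
    cohort_csv = Path(cohort_csv)
    out = Path(out_dir if out_dir is not None else cohort_csv.parent)
    _setup_run_logging(out, verbose)
    t0 = _time.perf_counter()
    if not cohort_csv.exists():
        raise FileNotFoundError(f"cohort table missing: {cohort_csv}")
    cohort = pd.read_csv(cohort_csv)
    tables = analyze_cohort(cohort)
    tables["trend"].to_csv(out / "trend_table.csv", index=False, float_format="%.6g")
    tables["time_effect"].to_csv(out / "time_effect.csv", index=False, float_format="%.6g")
    tables["group_contrast"].to_csv(out / "group_contrast.csv", index=False, float_format="%.6g")
    report = _format_report(tables)
    (out / "report.txt").write_text(report)
    logger.info("analyze: wrote report to %s in %.2fs", out, _time.perf_counter() - t0)
    return out


def _format_report(tables: dict[str, pd.DataFrame]) -> str:
    lines = ["Near-work choroidal response — cohort report", "=" * 46, ""]
    trend = tables["trend"]
    for group in sorted(trend["group"].unique()):
        lines.append(f"[{group}]  change after near work (mean ± SD, Bonferroni-adjusted p)")
        g = trend[trend["group"] == group]
        for metric in METRICS:
            gm = g[g["metric"] == metric]
            if gm.empty:
                continue
            cells = []
            for _, row in gm.sort_values("visit_min").iterrows():
                cells.append(
                    f"{row.visit_min:>3.0f} min: {row.mean_change:+8.2f} ± {row.sd_change:6.2f}"
                    f" (p={row.p_bonferroni:.3g}){row.direction}{row.significance}"
                )
            lines.append(f"  {metric:<5} " + " | ".join(cells))
        lines.append("")
    te = tables["time_effect"]
    if not te.empty:
        lines.append("Duration effect on percent change (RM-ANOVA, Greenhouse–Geisser):")
        for _, row in te.iterrows():
            lines.append(
                f"  {row.metric:<5} F({row.df1:.2f}, {row.df2:.2f}) = {row.F:.3f},"
                f" eps = {row.epsilon_gg:.3f}, p = {row.p:.3g}"
            )
        lines.append("")
    gc = tables["group_contrast"]
    if not gc.empty:
        lines.append("AL-adjusted group difference in percent change:")
        for _, row in gc.iterrows():
            lines.append(
                f"  {row.metric:<5} {row.contrast}: {row.difference_pct:+.3f}%"
                f" (SE {row.se:.3f}, p = {row.p:.3g})"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def run_all(config: RunConfig, out_dir: str | Path | None = None, verbose: bool = False) -> Path:
    """simulate → quantify → analyze in one call; returns the run directory."""
    out = run_simulate(config, out_dir, verbose)
    run_quantify(config, out, out, verbose)
    run_analyze(config, out / "cohort.csv", out, verbose)
    return out
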