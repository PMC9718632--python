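"""End-to-end pipeline: simulate -> detect -> screen -> match -> fingerprint
-> multivariate screen -> dual-wavelength quantitation.

``run_pipeline`` reproduces the whole quality-evaluation workflow on a
synthetic study-shaped panel and additionally recomputes the published
method-comparison summary (relative errors between single-marker and
external-standard contents) from the packaged tables.  All outputs are
plain CSV/JSON and are byte-reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import BatchPanel, CommonPeakMatrix, PeakTable
from .datasets import (
    load_calibration_lines,
    load_content_pairs,
    load_standard_concentrations,
)
from .fingerprint import median_reference, panel_similarities
from .multivariate import nipals_plsda, pca, scree_table, screen_key_components, vip
from .peaks import (
    MatchConfig,
    detect_peaks,
    locate_by_relative_retention,
    locate_by_rt_difference,
    match_common_peaks,
    shear_solvent_region,
)
from .qams import (
    CalibrationCurve,
    ContentReport,
    RCFMeasurement,
    SamplePrep,
    aggregate_rcf,
    esm_content,
    fit_calibration,
    qams_content,
    rcf,
    relative_error,
    re_summary,
)
from .synth import default_panel_design, make_batch_panel, make_calibration_series

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "published_re_summary"]

INTERNAL_STANDARD = "forsythoside A"
#: analyte -> (quantitation wavelength, localization method)
ANALYTE_CHANNELS = {
    "phillyrin": (237.0, "rrv"),
    "arctiin": (237.0, "rrv"),
    "neochlorogenic acid": (327.0, "delta"),
    "chlorogenic acid": (327.0, "delta"),
    "isochlorogenic acid A": (327.0, "rrv"),
    "isochlorogenic acid C": (327.0, "rrv"),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_batches: int = 10
    area_cv: float = 0.08
    rt_jitter_sd_min: float = 0.1
    noise_sd: float = 0.01
    match: MatchConfig = field(default_factory=MatchConfig)
    prep: SamplePrep = field(default_factory=SamplePrep)
    fingerprint_wavelength: float = 237.0
    similarity_metric: str = "cosine"
    pca_mode: str = "correlation"
    detect_min_height: float = 0.1
    detect_min_prominence: float = 0.1
    plsda_classes: list | None = None  # default: first half vs second half
    plsda_components: int = 2
    rcf_noise_cv: float = 0.002


@dataclass
class PipelineResult:
    similarities: pd.Series
    reference_areas: np.ndarray
    matrix: CommonPeakMatrix
    scree: pd.DataFrame
    loadings: pd.DataFrame
    vip_table: pd.DataFrame
    key_components: list
    curves: dict
    rcf_table: pd.DataFrame
    content_reports: list
    re_min: float
    re_max: float
    re_by_analyte: pd.DataFrame
    published_re_min: float
    published_re_max: float
    log: dict


def published_re_summary() -> tuple[float, float, pd.DataFrame]:
    """Recompute relative errors from the packaged per-batch content pairs."""
    pairs = load_content_pairs(pairs_only=True)
    reports = [
        ContentReport(
            batch_id=str(r.batch),
            analyte=r.analyte,
            wavelength_nm=float(r.wavelength_nm),
            esm_content=float(r.esm_mg_g),
            qams_content=float(r.qams_mg_g),
            re_pct=relative_error(float(r.qams_mg_g), float(r.esm_mg_g)),
        )
        for r in pairs.itertuples()
    ]
    return re_summary(reports)


def _fit_reference_curves(seed: int) -> dict[tuple[str, float], CalibrationCurve]:
    """Refit the published calibration lines from noiseless synthetic series."""
    curves = {}
    for row in load_calibration_lines().itertuples():
        truth = CalibrationCurve(
            analyte=row.analyte,
            wavelength_nm=float(row.wavelength_nm),
            slope=float(row.slope),
            intercept=float(row.intercept),
            r=float(row.r),
            linear_range_ug=(float(row.linear_low_ug), float(row.linear_high_ug)),
        )
        series = make_calibration_series(
            truth, np.linspace(*truth.linear_range_ug, 6), noise_cv=0.0, seed=seed
        )
        curves[(row.analyte, float(row.wavelength_nm))] = fit_calibration(
            list(zip(series["amount_ug"], series["area"])),
            row.analyte,
            float(row.wavelength_nm),
        )
    return curves


def _simulate_rcfs(
    curves: dict, injection_uL: float, noise_cv: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[tuple[str, float], float]]:
    """Replicate correction-factor measurements on the mixed standard solution."""
    concs = load_standard_concentrations()
    w_is = concs[INTERNAL_STANDARD]
    rows, mean_f = [], {}
    for analyte, (wl, _) in ANALYTE_CHANNELS.items():
        curve_x = curves[(analyte, wl)]
        curve_is = curves[(INTERNAL_STANDARD, wl)]
        amount_x = concs[analyte] * injection_uL / 1000.0
        amount_is = w_is * injection_uL / 1000.0
        reps = []
        for _ in range(6):
            a_x = curve_x.predict_area(amount_x) * (1.0 + rng.normal(0.0, noise_cv))
            a_is = curve_is.predict_area(amount_is) * (1.0 + rng.normal(0.0, noise_cv))
            reps.append(
                rcf(
                    RCFMeasurement(
                        analyte=analyte,
                        wavelength_nm=wl,
                        W_is=w_is,
                        A_is=a_is,
                        W_x=concs[analyte],
                        A_x=a_x,
                    )
                )
            )
        agg = aggregate_rcf(reps, analyte, wl)
        mean_f[(analyte, wl)] = agg.mean_f
        rows.append(
            {
                "analyte": analyte,
                "wavelength_nm": wl,
                "mean_f": agg.mean_f,
                "rsd_pct": agg.rsd_pct,
            }
        )
    return pd.DataFrame(rows), mean_f


def _quantify(
    panel_truth: dict[float, BatchPanel],
    analyte_rts: dict[str, float],
    curves: dict,
    mean_f: dict,
    prep: SamplePrep,
) -> list[ContentReport]:
    """Locate analyte peaks per batch, then compute ESM and QAMS contents."""
    is_rt_design = analyte_rts[INTERNAL_STANDARD]
    reports = []
    for wl in (237.0, 327.0):
        for table in panel_truth[wl].batches:
            is_peak = locate_by_relative_retention(table, is_rt_design, 1.0, tol=0.05)
            is_esm = esm_content(is_peak.area, curves[(INTERNAL_STANDARD, wl)], prep)
            for analyte, (a_wl, method) in ANALYTE_CHANNELS.items():
                if a_wl != wl:
                    continue
                if method == "rrv":
                    peak = locate_by_relative_retention(
                        table, is_peak.rt_min, analyte_rts[analyte] / is_rt_design
                    )
                else:
                    peak = locate_by_rt_difference(
                        table, is_peak.rt_min, analyte_rts[analyte] - is_rt_design
                    )
                esm = esm_content(peak.area, curves[(analyte, wl)], prep)
                qams = qams_content(
                    peak.area, mean_f[(analyte, wl)], is_peak.area, is_esm
                )
                reports.append(
                    ContentReport(
                        batch_id=table.sample_id,
                        analyte=analyte,
                        wavelength_nm=wl,
                        esm_content=esm,
                        qams_content=qams,
                        re_pct=relative_error(qams, esm),
                    )
                )
    return reports


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full synthetic quality-evaluation workflow."""
    config = config or PipelineConfig()
    design = default_panel_design(
        seed=config.seed,
        n_batches=config.n_batches,
        area_cv=config.area_cv,
        rt_jitter_sd_min=config.rt_jitter_sd_min,
        noise_sd=config.noise_sd,
    )
    sim = make_batch_panel(design)
    log: dict = {"version": __version__, "seed": config.seed, "stages": []}

    # fingerprint channel: detect -> shear -> match (area screen inside)
    wl = config.fingerprint_wavelength
    detected = []
    for trace, table in zip(sim.traces[wl], sim.truth[wl].batches):
        d = detect_peaks(trace, config.detect_min_height, config.detect_min_prominence)
        d = shear_solvent_region(d, config.match.solvent_cut_min)
        detected.append(PeakTable(table.sample_id, wl, d.peaks))
        log["stages"].append(
            {"stage": "detect+shear", "batch": table.sample_id, "n_peaks": len(d)}
        )
    panel = BatchPanel(detected, metadata={"seed": config.seed})
    matrix = match_common_peaks(panel, config.match)
    log["stages"].append({"stage": "match", "n_common_peaks": matrix.n_peaks})

    fp = median_reference(matrix)
    sims = panel_similarities(matrix, fp, metric=config.similarity_metric)

    pca_res = pca(matrix.areas, mode=config.pca_mode)
    scree = scree_table(pca_res)
    loadings = pd.DataFrame(
        pca_res.loadings,
        index=[f"peak_{k}" for k in matrix.peak_ids],
        columns=[f"component_{j + 1}" for j in range(pca_res.loadings.shape[1])],
    )

    classes = config.plsda_classes
    if classes is None:
        half = matrix.n_batches // 2
        classes = ["group_A"] * half + ["group_B"] * (matrix.n_batches - half)
    model = nipals_plsda(matrix.areas, classes, n_components=config.plsda_components)
    vips = vip(model)
    vip_table = pd.DataFrame({"peak_id": matrix.peak_ids, "vip": vips})
    keys = screen_key_components(vips, peak_ids=matrix.peak_ids)

    # quantitation on both channels
    curves = _fit_reference_curves(config.seed)
    rng = np.random.default_rng(config.seed + 10_000)
    rcf_table, mean_f = _simulate_rcfs(
        curves, config.prep.injection_volume_uL, config.rcf_noise_cv, rng
    )
    analyte_rts = {
        s.analyte: s.rt_mean_min for s in design.common_peaks if s.analyte is not None
    }
    reports = _quantify(sim.truth, analyte_rts, curves, mean_f, config.prep)
    re_min, re_max, re_by_analyte = re_summary(reports)

    pub_min, pub_max, _ = published_re_summary()

    return PipelineResult(
        similarities=sims,
        reference_areas=fp.reference_areas,
        matrix=matrix,
        scree=scree,
        loadings=loadings,
        vip_table=vip_table,
        key_components=keys,
        curves=curves,
        rcf_table=rcf_table,
        content_reports=reports,
        re_min=re_min,
        re_max=re_max,
        re_by_analyte=re_by_analyte,
        published_re_min=pub_min,
        published_re_max=pub_max,
        log=log,
    )


def write_bundle(result: PipelineResult, outdir, config: PipelineConfig) -> None:
    """Write every pipeline output as CSV/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.matrix.to_dataframe().to_csv(out / "common_peak_matrix.csv", float_format="%.9g")
    result.matrix.consensus_dataframe().to_csv(
        out / "consensus_rt.csv", index=False, float_format="%.9g"
    )
    pd.DataFrame(
        {
            "peak_id": result.matrix.peak_ids,
            "reference_area": result.reference_areas,
        }
    ).to_csv(out / "reference_fingerprint.csv", index=False, float_format="%.9g")
    result.similarities.rename_axis("batch_id").to_csv(
        out / "similarities.csv", float_format="%.9g"
    )
    result.scree.to_csv(out / "scree.csv", index=False, float_format="%.9g")
    result.loadings.to_csv(out / "loadings.csv", float_format="%.9g")
    result.vip_table.to_csv(out / "vip.csv", index=False, float_format="%.9g")
    result.rcf_table.to_csv(out / "rcf.csv", index=False, float_format="%.9g")
    pd.DataFrame(
        {
            "batch_id": [r.batch_id for r in result.content_reports],
            "analyte": [r.analyte for r in result.content_reports],
            "wavelength_nm": [r.wavelength_nm for r in result.content_reports],
            "esm_mg_g": [r.esm_content for r in result.content_reports],
            "qams_mg_g": [r.qams_content for r in result.content_reports],
            "re_pct": [r.re_pct for r in result.content_reports],
        }
    ).to_csv(out / "content_report.csv", index=False, float_format="%.9g")
    summary = {
        "synthetic_re_min_pct": result.re_min,
        "synthetic_re_max_pct": result.re_max,
        "published_re_min_pct": result.published_re_min,
        "published_re_max_pct": result.published_re_max,
    }
    (out / "re_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "config": _config_dict(config),
        "log": result.log,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
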