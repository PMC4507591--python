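"""End-to-end orchestration: simulate -> extract -> split -> PLS -> iPLS.

One seeded, configured run produces a :class:`RunReport` holding the
full-spectrum PLS metrics for both feature types (absorption coefficient
and refractive index), an interval-PLS report per configured interval
width, and enough provenance to recompute every number from the persisted
intermediates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .containers import SampleGeometry, SpectraMatrix
from .extraction import build_matrix, extract_dataset
from .io import matrix_hash, save_model, write_dataset, write_matrix
from .ipls import IntervalReport, run_ipls
from .pls import assign_class, fit_pls, loo_cv, predict, rmse, split_dataset
from .simulate import (
    ClassProfile,
    InstrumentModel,
    default_wheat_profiles,
    generate_dataset,
    uniform_profiles,
)

__all__ = [
    "SimulationConfig",
    "ExtractionConfig",
    "ModellingConfig",
    "RunConfig",
    "RunReport",
    "load_config",
    "run",
    "render_report",
]

log = logging.getLogger("thzchem")

FEATURES = ("absorption", "refractive_index")


@dataclass(frozen=True)
class SimulationConfig:
    """Which classes to simulate and with what instrument/geometry."""

    profiles: str = "wheat"          # "wheat" | "uniform" | explicit list
    profile_list: Tuple[dict, ...] = ()
    n_per_class: int = 20
    seed: int = 0
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    geometry: SampleGeometry = field(default_factory=SampleGeometry)
    scans_per_sample: int = 3
    samples_per_reference: int = 3

    def resolve_profiles(self) -> List[ClassProfile]:
        if self.profiles == "wheat":
            return default_wheat_profiles()
        if self.profiles == "uniform":
            return uniform_profiles()
        if self.profiles == "explicit":
            out = []
            for p in self.profile_list:
                p = dict(p)
                if "signal_band" in p:
                    p["signal_band"] = tuple(p["signal_band"])
                out.append(ClassProfile(**p))
            return out
        raise ValueError(f"unknown profiles spec {self.profiles!r}")


@dataclass(frozen=True)
class ExtractionConfig:
    band: Tuple[float, float] = (0.2, 1.5)
    n_variables: int = 128


@dataclass(frozen=True)
class ModellingConfig:
    factors: int = 5
    calibration_fraction: float = 0.6
    interval_widths: Tuple[int, ...] = (4, 8, 16)
    split_seed: int = 1


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    modelling: ModellingConfig = field(default_factory=ModellingConfig)
    persist_traces: bool = False

    def to_dict(self) -> dict:
        # JSON round trip turns tuples into lists, keeping the dict
        # YAML/JSON-serialisable
        return json.loads(json.dumps(asdict(self)))

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        sim = dict(d.get("simulation", {}))
        if "instrument" in sim:
            sim["instrument"] = InstrumentModel(**sim["instrument"])
        if "geometry" in sim:
            sim["geometry"] = SampleGeometry(**sim["geometry"])
        if "profile_list" in sim:
            sim["profile_list"] = tuple(sim["profile_list"])
        ext = dict(d.get("extraction", {}))
        if "band" in ext:
            ext["band"] = tuple(ext["band"])
        mod = dict(d.get("modelling", {}))
        if "interval_widths" in mod:
            mod["interval_widths"] = tuple(mod["interval_widths"])
        return RunConfig(
            simulation=SimulationConfig(**sim),
            extraction=ExtractionConfig(**ext),
            modelling=ModellingConfig(**mod),
            persist_traces=bool(d.get("persist_traces", False)),
        )


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class FeatureResult:
    """Full-spectrum PLS metrics for one feature type (calibration set
    fitted and LOO-cross-validated; prediction set held out)."""

    feature: str
    factors: int
    r_calibration: float
    rmsec: float
    r_cv: float
    rmsecv: float
    rmsep: float
    loo_accuracy: float          # class assignment of LOO predictions
    prediction_accuracy: float   # class assignment on the prediction set


@dataclass(frozen=True)
class IntervalSummary:
    """Machine-readable digest of one interval-PLS run."""

    width: int
    n_intervals: int
    selected_interval: int
    selected_variables: Tuple[int, int]
    selected_band_THz: Tuple[float, float]
    selected_rmsecv: float
    selected_r: float
    full_spectrum_rmsecv: float
    rmsep: float                 # selected-interval model on prediction set
    prediction_accuracy: float
    table: Tuple[dict, ...]      # one row per interval


@dataclass(frozen=True)
class RunReport:
    config: dict
    n_samples: int
    n_calibration: int
    n_prediction: int
    feature_results: Tuple[FeatureResult, ...]
    interval_summaries: Tuple[IntervalSummary, ...]
    best_feature: str
    matrix_hashes: Dict[str, str]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "n_samples": self.n_samples,
            "n_calibration": self.n_calibration,
            "n_prediction": self.n_prediction,
            "feature_results": [asdict(f) for f in self.feature_results],
            "interval_summaries": [asdict(s) for s in self.interval_summaries],
            "best_feature": self.best_feature,
            "matrix_hashes": dict(self.matrix_hashes),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)


def _evaluate_feature(
    feature: str,
    cal: SpectraMatrix,
    pred: SpectraMatrix,
    factors: int,
) -> FeatureResult:
    from .pls import correlation  # local to keep the top import list short

    model = fit_pls(cal, factors)
    fitted = predict(model, cal.X)
    cv = loo_cv(cal, factors)
    loo_assign = assign_class(cv.predictions, cal.n_classes, cal.y)
    yhat_pred = predict(model, pred.X)
    pred_assign = assign_class(yhat_pred, cal.n_classes, pred.y)
    return FeatureResult(
        feature=feature,
        factors=factors,
        r_calibration=correlation(cal.y, fitted),
        rmsec=model.rmsec,
        r_cv=cv.r,
        rmsecv=cv.rmsecv,
        rmsep=rmse(pred.y, yhat_pred),
        loo_accuracy=loo_assign.accuracy,
        prediction_accuracy=pred_assign.accuracy,
    )


def _summarise_intervals(
    report: IntervalReport,
    cal: SpectraMatrix,
    pred: SpectraMatrix,
) -> IntervalSummary:
    sel = report.selected
    pred_sub = pred.select_variables(sel.start, sel.end)
    yhat = predict(report.selected_model, pred_sub.X)
    assign = assign_class(yhat, cal.n_classes, pred.y)
    return IntervalSummary(
        width=report.spec.interval_width,
        n_intervals=report.spec.n_intervals,
        selected_interval=report.selected_index,
        selected_variables=(sel.start, sel.end),
        selected_band_THz=(sel.f_lo, sel.f_hi),
        selected_rmsecv=sel.rmsecv,
        selected_r=sel.r,
        full_spectrum_rmsecv=report.full_spectrum_rmsecv,
        rmsep=rmse(pred.y, yhat),
        prediction_accuracy=assign.accuracy,
        table=tuple(report.to_frame().to_dict(orient="records")),
    )


def run(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the whole pipeline for one configuration.

    Deterministic given the configured seeds. If ``out_dir`` is given, the
    feature matrices, fitted full-spectrum models, interval reports and the
    run report are persisted there (traces too when ``persist_traces``).
    """
    sim, ext, mod = config.simulation, config.extraction, config.modelling
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log.info("simulate: %s profiles x %d", sim.profiles, sim.n_per_class)
    profiles = sim.resolve_profiles()
    dataset = generate_dataset(
        profiles,
        sim.n_per_class,
        sim.instrument,
        sim.geometry,
        sim.seed,
        scans_per_sample=sim.scans_per_sample,
        samples_per_reference=sim.samples_per_reference,
    )
    if out is not None and config.persist_traces:
        write_dataset(dataset, out / "dataset")

    log.info("extract: band %s, %d variables", ext.band, ext.n_variables)
    props = extract_dataset(dataset, band=ext.band)
    ids = dataset.sample_ids
    labels = [dataset.labels[s] for s in ids]
    matrices = {
        feat: build_matrix(
            [props[s] for s in ids],
            labels,
            band=ext.band,
            n_variables=ext.n_variables,
            feature=feat,
            sample_ids=ids,
        )
        for feat in FEATURES
    }
    hashes = {feat: matrix_hash(m) for feat, m in matrices.items()}
    if out is not None:
        for feat, m in matrices.items():
            write_matrix(
                m,
                out / f"matrix_{feat}.csv",
                sidecar={"feature": feat, "seed": sim.seed},
            )

    # one stratified split shared by both feature types
    cal_abs, pred_abs = split_dataset(
        matrices["absorption"], mod.calibration_fraction, mod.split_seed
    )
    cal_ids = set(cal_abs.sample_ids)
    cal_idx = [i for i, s in enumerate(ids) if s in cal_ids]
    pred_idx = [i for i, s in enumerate(ids) if s not in cal_ids]
    splits = {
        "absorption": (cal_abs, pred_abs),
        "refractive_index": (
            matrices["refractive_index"].select_samples(cal_idx),
            matrices["refractive_index"].select_samples(pred_idx),
        ),
    }

    log.info("full-spectrum PLS, %d factors", mod.factors)
    feature_results = tuple(
        _evaluate_feature(feat, *splits[feat], mod.factors) for feat in FEATURES
    )
    best_feature = min(feature_results, key=lambda r: r.rmsecv).feature
    if out is not None:
        for feat in FEATURES:
            model = fit_pls(splits[feat][0], mod.factors)
            save_model(
                model,
                out / f"model_full_{feat}.json",
                provenance={"matrix_hash": hashes[feat], "feature": feat},
            )

    # interval PLS on the best-practice feature: absorption spectra
    cal, pred = splits["absorption"]
    full_rmsecv = next(
        r for r in feature_results if r.feature == "absorption"
    ).rmsecv
    full_r = next(r for r in feature_results if r.feature == "absorption").r_cv
    summaries = []
    for width in mod.interval_widths:
        log.info("iPLS width %d", width)
        report = run_ipls(cal, width, mod.factors, full_cv=(full_rmsecv, full_r))
        summaries.append(_summarise_intervals(report, cal, pred))
        if out is not None:
            report.to_frame().to_csv(out / f"ipls_width{width}.csv", index=False)

    run_report = RunReport(
        config=config.to_dict(),
        n_samples=len(ids),
        n_calibration=cal.n_samples,
        n_prediction=pred.n_samples,
        feature_results=feature_results,
        interval_summaries=tuple(summaries),
        best_feature=best_feature,
        matrix_hashes=hashes,
    )
    if out is not None:
        (out / "report.json").write_text(run_report.to_json())
        (out / "report.txt").write_text(render_report(run_report))
    return run_report


def modelling_from_matrices(
    matrices: Dict[str, SpectraMatrix],
    mod: ModellingConfig,
) -> Tuple[Tuple[FeatureResult, ...], List[IntervalSummary]]:
    """Re-run only the modelling stages from persisted feature matrices.

    Produces exactly the numbers :func:`run` reports, enabling the
    intermediate-file integrity check.
    """
    cal_abs, pred_abs = split_dataset(
        matrices["absorption"], mod.calibration_fraction, mod.split_seed
    )
    ids = matrices["absorption"].sample_ids
    cal_ids = set(cal_abs.sample_ids)
    cal_idx = [i for i, s in enumerate(ids) if s in cal_ids]
    pred_idx = [i for i, s in enumerate(ids) if s not in cal_ids]
    splits = {
        "absorption": (cal_abs, pred_abs),
        "refractive_index": (
            matrices["refractive_index"].select_samples(cal_idx),
            matrices["refractive_index"].select_samples(pred_idx),
        ),
    }
    feature_results = tuple(
        _evaluate_feature(feat, *splits[feat], mod.factors) for feat in FEATURES
    )
    full_abs = next(r for r in feature_results if r.feature == "absorption")
    summaries = [
        _summarise_intervals(
            run_ipls(
                splits["absorption"][0],
                w,
                mod.factors,
                full_cv=(full_abs.rmsecv, full_abs.r_cv),
            ),
            *splits["absorption"],
        )
        for w in mod.interval_widths
    ]
    return feature_results, summaries


def render_report(report: RunReport) -> str:
    """Human-readable summary mirroring the JSON numbers exactly."""
    lines = []
    lines.append("THz chemometrics run report")
    lines.append("=" * 60)
    lines.append(
        f"samples: {report.n_samples} "
        f"(calibration {report.n_calibration} / prediction {report.n_prediction})"
    )
    lines.append("")
    lines.append("Full-spectrum PLS (per feature)")
    hdr = (
        f"{'feature':<18}{'factors':>8}{'R_cal':>9}{'RMSEC':>9}"
        f"{'R_cv':>9}{'RMSECV':>9}{'RMSEP':>9}{'acc':>7}"
    )
    lines.append(hdr)
    for fr in report.feature_results:
        lines.append(
            f"{fr.feature:<18}{fr.factors:>8d}{fr.r_calibration:>9.4f}"
            f"{fr.rmsec:>9.4f}{fr.r_cv:>9.4f}{fr.rmsecv:>9.4f}"
            f"{fr.rmsep:>9.4f}{fr.prediction_accuracy:>7.3f}"
        )
    lines.append(f"best feature by RMSECV: {report.best_feature}")
    for s in report.interval_summaries:
        lines.append("")
        lines.append(
            f"iPLS width {s.width}: {s.n_intervals} intervals; selected "
            f"interval {s.selected_interval} "
            f"(vars {s.selected_variables[0]}-{s.selected_variables[1]}, "
            f"{s.selected_band_THz[0]:.3f}-{s.selected_band_THz[1]:.3f} THz)"
        )
        lines.append(
            f"  selected RMSECV {s.selected_rmsecv:.4f} vs full-spectrum "
            f"{s.full_spectrum_rmsecv:.4f}; RMSEP {s.rmsep:.4f}; "
            f"accuracy {s.prediction_accuracy:.3f}"
        )
        lines.append(
            f"  {'interval':>8}{'vars':>12}{'RMSECV':>10}{'R':>8}"
        )
        for row in s.table:
            mark = " *" if row["selected"] else ""
            lines.append(
                f"  {row['interval']:>8d}{row['start']:>6d}-{row['end']:<5d}"
                f"{row['rmsecv']:>10.4f}{row['r']:>8.4f}{mark}"
            )
    return "\n".join(lines) + "\n"
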