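"""End-to-end study: simulate/load, smooth, transform, calibrate, select
effective wavelengths, refit, and report.

Sequence (mirroring how such chemometrics studies are run):

1. obtain a dataset (synthetic generator or CSV);
2. Savitzky-Golay smooth the raw reflectance;
3. split into calibration/validation;
4. for each spectral technique (raw / FDR / CR) fit each requested method
   on the calibration split and evaluate both splits;
5. pick the best (technique, method) pair by validation RPD (ties: higher
   validation r^2, then fewer latent variables);
6. compute VIP scores from the PLS fit of the best technique (PLS drives
   the selection even when another method wins) and select effective
   wavelengths at the configured threshold;
7. refit every method on the selected bands and evaluate;
8. write the study report (plain CSV + a JSON manifest, no timestamps, so
   repeated runs under one seed are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import CorrelationProfile, wavelength_correlations
from .dataset import SpectralDataset
from .evaluation import EvaluationReport, evaluate
from .exceptions import ConfigurationError, NspecError
from .preprocessing import SmoothingSpec, savgol_smooth
from .regression import (
    CVScheme,
    CVTrace,
    FittedModel,
    LOO,
    fit_mlr,
    fit_pcr,
    fit_pls,
    fit_svr_rbf,
)
from .selection import VIPProfile, vip_scores
from .synthetic import SimulationConfig, simulate_dataset, split_dataset
from .transforms import TRANSFORM_KINDS, apply_transform

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    simulation: SimulationConfig | None = None
    data_csv: str | None = None
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    transforms: tuple[str, ...] = ("raw", "fdr", "cr")
    methods: tuple[str, ...] = ("MLR", "PCR", "PLS", "SVM")
    cv: CVScheme = LOO
    svr_cv: CVScheme = field(default_factory=lambda: CVScheme("kfold", k=10, seed=0))
    vip_threshold: float = 2.0
    n_cal: int = 165
    n_val: int = 150
    max_order: int = 20
    svr_grid: dict | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and self.data_csv is None:
            self.simulation = SimulationConfig(seed=self.seed)
        self.transforms = tuple(self.transforms)
        self.methods = tuple(m.upper() for m in self.methods)
        if not self.transforms or not self.methods:
            raise ConfigurationError("need at least one transform and one method")
        for t in self.transforms:
            if t not in TRANSFORM_KINDS:
                raise ConfigurationError(f"unknown transform {t!r}")
        for m in self.methods:
            if m not in ("MLR", "PCR", "PLS", "SVM"):
                raise ConfigurationError(f"unknown method {m!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "simulation" in data and isinstance(data["simulation"], dict):
            data["simulation"] = SimulationConfig(**data["simulation"])
        if "smoothing" in data and isinstance(data["smoothing"], dict):
            data["smoothing"] = SmoothingSpec(**data["smoothing"])
        for key in ("cv", "svr_cv"):
            if key in data and isinstance(data[key], dict):
                data[key] = CVScheme(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_jsonable(self) -> dict:
        out = asdict(self)
        return out


@dataclass
class StudyRow:
    """One line of the results tables (Table-3/4 layout)."""

    method: str
    technique: str
    calibration: EvaluationReport
    validation: EvaluationReport
    selected_order: int | None
    hyperparameters: dict

    def flat(self) -> dict:
        return {
            "method": self.method,
            "technique": self.technique,
            "r2_cal": self.calibration.r2,
            "rmse_cal": self.calibration.rmse,
            "rpd_cal": self.calibration.rpd,
            "r2_val": self.validation.r2,
            "rmse_val": self.validation.rmse,
            "rpd_val": self.validation.rpd,
        }


@dataclass
class StudyReport:
    """Everything a study run produces."""

    config: StudyConfig
    full_rows: list[StudyRow]
    effective_rows: list[StudyRow]
    correlation_profiles: dict[str, CorrelationProfile]
    cv_traces: dict[str, CVTrace]
    vip_profile: VIPProfile
    selected_wavelengths: list[tuple[float, float]]
    best_key: tuple[str, str]
    variable_reduction_pct: float
    models: dict[str, FittedModel]
    provenance: dict

    def full_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.flat() for r in self.full_rows])

    def effective_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.flat() for r in self.effective_rows])

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.full_table().to_csv(out / "results_full_spectrum.csv", index=False)
        self.effective_table().to_csv(out / "results_effective_wavelengths.csv", index=False)
        for kind, profile in self.correlation_profiles.items():
            profile.to_csv(out / f"correlation_{kind}.csv")
        for key, trace in self.cv_traces.items():
            trace.to_csv(out / f"cvtrace_{key}.csv")
        self.vip_profile.to_csv(out / "vip_profile.csv")
        pd.DataFrame(
            self.selected_wavelengths, columns=["wavelength_nm", "vip"]
        ).to_csv(out / "effective_wavelengths.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True), encoding="utf-8"
        )


def report_variable_reduction(n_full: int, n_selected: int) -> float:
    """Percent of variables eliminated by selection, 2-decimal display value."""
    if not 0 < n_selected <= n_full:
        raise NspecError("require 0 < n_selected <= n_full")
    return round(100.0 * (n_full - n_selected) / n_full, 2)


def _fit_one(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    config: StudyConfig,
) -> tuple[FittedModel, CVTrace | None]:
    if method == "MLR":
        return fit_mlr(X, y), None
    if method == "PCR":
        return fit_pcr(X, y, max_components=config.max_order, cv_scheme=config.cv)
    if method == "PLS":
        return fit_pls(X, y, max_lv=config.max_order, cv_scheme=config.cv)
    if method == "SVM":
        return fit_svr_rbf(X, y, grid=config.svr_grid, cv_scheme=config.svr_cv)
    raise ConfigurationError(f"unknown method {method!r}")


def _evaluate_model(
    method: str,
    technique: str,
    model: FittedModel,
    cal: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
) -> StudyRow:
    rep_cal = evaluate(cal[1], model.predict(cal[0]), split="calibration")
    rep_val = evaluate(val[1], model.predict(val[0]), split="validation")
    return StudyRow(
        method=method,
        technique=technique,
        calibration=rep_cal,
        validation=rep_val,
        selected_order=model.selected_order,
        hyperparameters=dict(model.hyperparameters),
    )


def _load_dataset(config: StudyConfig) -> SpectralDataset:
    if config.data_csv is not None:
        return SpectralDataset.from_csv(config.data_csv)
    return simulate_dataset(config.simulation)


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full study; see the module docstring for the sequence."""
    t_start = time.perf_counter()
    dataset = _load_dataset(config)
    logger.info("stage=data n=%d bands=%d", dataset.n_samples, dataset.n_bands)

    smoothed = savgol_smooth(dataset, config.smoothing)
    cal_raw, val_raw = split_dataset(smoothed, config.n_cal, config.n_val, config.seed)
    logger.info("stage=split cal=%d val=%d", cal_raw.n_samples, val_raw.n_samples)

    transformed: dict[str, tuple[SpectralDataset, SpectralDataset]] = {}
    correlation_profiles: dict[str, CorrelationProfile] = {}
    for kind in config.transforms:
        t0 = time.perf_counter()
        cal_t = apply_transform(cal_raw, kind)
        val_t = apply_transform(val_raw, kind)
        transformed[kind] = (cal_t, val_t)
        correlation_profiles[kind] = wavelength_correlations(cal_t)
        logger.info("stage=transform kind=%s wall=%.2fs", kind, time.perf_counter() - t0)

    models: dict[str, FittedModel] = {}
    cv_traces: dict[str, CVTrace] = {}
    full_rows: list[StudyRow] = []
    for kind, (cal_t, val_t) in transformed.items():
        Xc, yc = cal_t.reflectance, cal_t.leaf_n
        Xv, yv = val_t.reflectance, val_t.leaf_n
        for method in config.methods:
            t0 = time.perf_counter()
            model, trace = _fit_one(method, Xc, yc, config)
            key = f"{kind}_{method}"
            models[key] = model
            if trace is not None:
                cv_traces[key] = trace
            full_rows.append(_evaluate_model(method, kind, model, (Xc, yc), (Xv, yv)))
            logger.info("stage=fit model=%s wall=%.2fs", key, time.perf_counter() - t0)

    best_row = max(
        full_rows,
        key=lambda r: (r.validation.rpd, r.validation.r2, -(r.selected_order or 0)),
    )
    best_key = (best_row.technique, best_row.method)
    best_kind = best_row.technique
    logger.info("stage=select best=%s-%s", *best_key)

    # effective-wavelength selection is always driven by the PLS fit of the
    # winning spectral technique
    pls_key = f"{best_kind}_PLS"
    if pls_key not in models:
        cal_t, _ = transformed[best_kind]
        model, trace = fit_pls(
            cal_t.reflectance, cal_t.leaf_n, max_lv=config.max_order, cv_scheme=config.cv
        )
        models[pls_key] = model
        cv_traces[pls_key] = trace
    vip = vip_scores(
        models[pls_key],
        transformed[best_kind][0].wavelengths,
        threshold=config.vip_threshold,
    )
    selected = vip.selected
    if not selected:
        logger.warning("no band reached VIP threshold %.2f", config.vip_threshold)
    sel_idx = np.searchsorted(
        transformed[best_kind][0].wavelengths, [w for w, _ in selected]
    )

    effective_rows: list[StudyRow] = []
    if selected:
        cal_t, val_t = transformed[best_kind]
        Xc, yc = cal_t.reflectance[:, sel_idx], cal_t.leaf_n
        Xv, yv = val_t.reflectance[:, sel_idx], val_t.leaf_n
        for method in config.methods:
            t0 = time.perf_counter()
            model, trace = _fit_one(method, Xc, yc, config)
            key = f"effective_{method}"
            models[key] = model
            if trace is not None:
                cv_traces[key] = trace
            effective_rows.append(
                _evaluate_model(method, best_kind, model, (Xc, yc), (Xv, yv))
            )
            logger.info("stage=refit model=%s wall=%.2fs", key, time.perf_counter() - t0)

    reduction = (
        report_variable_reduction(smoothed.n_bands, len(selected)) if selected else 0.0
    )
    config_json = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    provenance = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "best_model": "-".join(best_key),
        "selected_wavelengths_nm": [w for w, _ in selected],
        "variable_reduction_pct": reduction,
        "n_calibration": int(cal_raw.n_samples),
        "n_validation": int(val_raw.n_samples),
    }
    report = StudyReport(
        config=config,
        full_rows=full_rows,
        effective_rows=effective_rows,
        correlation_profiles=correlation_profiles,
        cv_traces=cv_traces,
        vip_profile=vip,
        selected_wavelengths=selected,
        best_key=best_key,
        variable_reduction_pct=reduction,
        models=models,
        provenance=provenance,
    )
    if out_dir is None:
        out_dir = config.output_dir
    if out_dir is not None:
        report.write(out_dir)
    logger.info("stage=done wall=%.2fs", time.perf_counter() - t_start)
    return report
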