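"""Configuration-driven orchestration of the full fusion experiment.

simulate -> calibrate -> preprocess -> select wavelengths -> extract visual
features -> fuse -> train -> evaluate, with one shared 7:3 split, training-
only fitting of every stateful stage, and a self-describing run directory
(config copy, manifest, per-stage tables, per-sample predictions, summary).
Fully reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .preprocess import calibrate_reflectance, make_chain
from .regression import (
    CVPLSRegression,
    FusedPLSRegressor,
    EvalReport,
    eval_report,
    train_test_split_ids,
    zscore_fit,
)
from .selection import SELECTOR_REGISTRY, SelectionResult
from .spectra import read_reference, read_spectra
from .vision import FEATURE_NAMES, extract_features_table

__all__ = ["PipelineConfig", "run_pipeline", "save_model", "load_model"]

MODEL_FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """All knobs of one experiment; defaults follow the modelling protocol
    (7:3 split, 5-fold CV with seed 42, at most 25 latent variables,
    SG+SNV preprocessing with CARS selection)."""

    seed: int = 0
    simulate: bool = True
    n_samples: int = 120
    data_dir: str | None = None  # used when simulate=False
    preprocess_chain: str = "SG+SNV"
    sg_window: int = 11
    sg_order: int = 2
    selection_method: str = "CARS"
    selection_params: dict = field(default_factory=dict)
    fusion_mode: str = "per_block"
    split_ratio: float = 0.7
    cv_folds: int = 5
    max_latent: int = 25
    cv_seed: int = 42

    def validate(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if self.selection_method.upper() not in SELECTOR_REGISTRY:
            raise ValueError(f"unknown selection method {self.selection_method!r}")
        if not self.simulate and self.data_dir is None:
            raise ValueError("data_dir is required when simulate is false")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def stage(self, name: str, t0: float, **info) -> None:
        kv = " ".join(f"{k}={v}" for k, v in info.items())
        self.lines.append(f"{name} duration_s={time.perf_counter() - t0:.3f} {kv}")
        self.path.write_text("\n".join(self.lines) + "\n")


def _fit_selector(method: str, params: dict, X, y, seed: int):
    cls = SELECTOR_REGISTRY[method.upper()]
    return cls(seed=seed, **params).fit(X, y)


def run_pipeline(config: PipelineConfig, out_dir) -> dict[str, EvalReport]:
    """Run the whole experiment; returns the three evaluation reports
    (``spectral``, ``visual``, ``fused``) and writes all artifacts under
    ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "log.txt")
    config.to_yaml(out / "config.yaml")

    # ---- data: simulate or load -------------------------------------------
    t0 = time.perf_counter()
    if config.simulate:
        ds_cfg = synthetic.DatasetConfig(seed=config.seed)
        ds_cfg.ssc.n_samples = config.n_samples
        paths = synthetic.generate_dataset(ds_cfg, out / "data")
        data_dir = out / "data"
    else:
        data_dir = Path(config.data_dir)
        paths = {
            "spectra": data_dir / "spectra.csv",
            "dark": data_dir / "dark.csv",
            "white": data_dir / "white.csv",
            "ssc": data_dir / "ssc.csv",
            "images": data_dir / "images",
        }
        for key, p in paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"stage=data missing input {key}: {p}")
    ssc = pd.read_csv(paths["ssc"], dtype={"sample_id": str})
    if "ssc_brix" not in ssc.columns:
        raise ValueError("stage=data: ssc table is missing the 'ssc_brix' column")
    raw = read_spectra(paths["spectra"])
    _, dark = read_reference(paths["dark"])
    _, white = read_reference(paths["white"])
    log.stage("data", t0, n=raw.n_samples, spectra_hash=_hash_array(raw.intensities))

    # ---- calibration -------------------------------------------------------
    t0 = time.perf_counter()
    refl = calibrate_reflectance(raw, dark, white)
    log.stage("calibrate", t0, hash=_hash_array(refl.intensities))

    # ---- shared split ------------------------------------------------------
    train_ids, test_ids = train_test_split_ids(
        refl.sample_ids, config.split_ratio, config.seed
    )
    y = ssc.set_index("sample_id")["ssc_brix"]
    y_tr = y.loc[train_ids].to_numpy()
    y_te = y.loc[test_ids].to_numpy()

    # ---- preprocessing (fit on train only) ---------------------------------
    t0 = time.perf_counter()
    chain = make_chain(config.preprocess_chain, config.sg_window, config.sg_order)
    spec_tr = refl.subset(train_ids)
    spec_te = refl.subset(test_ids)
    Xs_tr = chain.fit_transform(spec_tr.intensities)
    Xs_te = chain.transform(spec_te.intensities)
    log.stage("preprocess", t0, chain=config.preprocess_chain, hash=_hash_array(Xs_tr))

    # ---- wavelength selection (train only) ---------------------------------
    t0 = time.perf_counter()
    selector = _fit_selector(
        config.selection_method, config.selection_params, Xs_tr, y_tr, config.seed
    )
    support = selector.get_support()
    sel_idx = np.nonzero(support)[0]
    result = SelectionResult(
        method=config.selection_method.upper(),
        selected_indices=sel_idx,
        rmsecv_trace=getattr(selector, "rmsecv_trace_", np.array([])),
        retained_counts=getattr(selector, "retained_counts_", np.array([sel_idx.size])),
        threshold=getattr(selector, "threshold_", None),
        seed=config.seed,
    )
    result.save(
        refl.wavelengths,
        getattr(selector, "reliability_", np.ones(refl.n_wavelengths))[sel_idx]
        if hasattr(selector, "reliability_")
        else np.ones(sel_idx.size),
        out / "selected_wavelengths.csv",
        out / "selection_diagnostics.txt",
    )
    Xsel_tr, Xsel_te = Xs_tr[:, support], Xs_te[:, support]
    log.stage("select", t0, method=result.method, n_selected=sel_idx.size)

    # ---- visual features ----------------------------------------------------
    t0 = time.perf_counter()
    feats = extract_features_table(paths["images"], list(ssc["sample_id"]))
    feats.to_csv(out / "visual_features.csv", index=False)
    fmat = feats.set_index("sample_id")[list(FEATURE_NAMES)]
    Xv_tr = fmat.loc[train_ids].to_numpy()
    Xv_te = fmat.loc[test_ids].to_numpy()
    log.stage("features", t0, hash=_hash_array(Xv_tr))

    # ---- three models -------------------------------------------------------
    t0 = time.perf_counter()
    reports: dict[str, EvalReport] = {}
    preds = []

    spectral = CVPLSRegression(config.max_latent, config.cv_folds, config.cv_seed)
    spectral.fit(Xsel_tr, y_tr)
    reports["spectral"] = eval_report(
        y_tr, spectral.predict(Xsel_tr), y_te, spectral.predict(Xsel_te)
    )

    vis_std = zscore_fit(Xv_tr)
    visual = CVPLSRegression(
        min(config.max_latent, len(FEATURE_NAMES)), config.cv_folds, config.cv_seed
    )
    visual.fit(vis_std.transform(Xv_tr), y_tr)
    reports["visual"] = eval_report(
        y_tr,
        visual.predict(vis_std.transform(Xv_tr)),
        y_te,
        visual.predict(vis_std.transform(Xv_te)),
    )

    fused = FusedPLSRegressor(
        n_spectral=Xsel_tr.shape[1],
        fusion_mode=config.fusion_mode,
        max_latent=config.max_latent,
        cv_folds=config.cv_folds,
        cv_seed=config.cv_seed,
    )
    X_tr = np.hstack([Xsel_tr, Xv_tr])
    X_te = np.hstack([Xsel_te, Xv_te])
    fused.fit(X_tr, y_tr)
    reports["fused"] = eval_report(y_tr, fused.predict(X_tr), y_te, fused.predict(X_te))

    models = {"spectral": spectral, "visual": visual, "fused": fused}
    inputs = {
        "spectral": (Xsel_tr, Xsel_te),
        "visual": (vis_std.transform(Xv_tr), vis_std.transform(Xv_te)),
        "fused": (X_tr, X_te),
    }
    for name, model in models.items():
        a, b = inputs[name]
        for ids, ytrue, mat, part in ((train_ids, y_tr, a, "train"), (test_ids, y_te, b, "test")):
            pred = model.predict(mat)
            preds.append(
                pd.DataFrame(
                    {"sample_id": ids, "model": name, "partition": part,
                     "y_true": ytrue, "y_pred": pred}
                )
            )
    pd.concat(preds, ignore_index=True).to_csv(out / "predictions.csv", index=False)
    save_model(fused, sel_idx, out / "fused_model.json")
    log.stage("train", t0, fused_lv=fused.n_components_)

    # ---- summary ------------------------------------------------------------
    rows = []
    for name in ("spectral", "visual", "fused"):
        r = reports[name].as_dict()
        r["model"] = name
        r["n_latent"] = models[name].n_components_
        rows.append(r)
    summary = pd.DataFrame(rows)[["model", "R2c", "RMSEC", "R2v", "RMSEV", "RPD", "n_latent"]]
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6f")
    text = [
        f"{'model':<10} {'R2c':>8} {'RMSEC':>8} {'R2v':>8} {'RMSEV':>8} {'RPD':>6} {'LV':>4}"
    ]
    for _, r in summary.iterrows():
        text.append(
            f"{r['model']:<10} {r['R2c']:>8.4f} {r['RMSEC']:>8.4f} "
            f"{r['R2v']:>8.4f} {r['RMSEV']:>8.4f} {r['RPD']:>6.2f} {int(r['n_latent']):>4}"
        )
    (out / "summary.txt").write_text("\n".join(text) + "\n")
    (out / "split.json").write_text(
        json.dumps({"train": train_ids, "test": test_ids}, indent=1)
    )
    return reports


def save_model(model: FusedPLSRegressor, selected_indices: np.ndarray, path) -> None:
    """JSON serialization of the fused model (format_version 1)."""
    pls = model.pls_.pls_
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_spectral": int(model.n_spectral),
        "fusion_mode": model.fusion_spec_.mode,
        "selected_indices": np.asarray(selected_indices, int).tolist(),
        "spectral_standardizer": {
            "mean": model.spec_standardizer_.mean_.tolist(),
            "sd": model.spec_standardizer_.sd_.tolist(),
        },
        "visual_standardizer": {
            "mean": model.vis_standardizer_.mean_.tolist(),
            "sd": model.vis_standardizer_.sd_.tolist(),
        },
        "fusion_weights": {
            "spectral": model.fusion_spec_.spectral_weights.tolist(),
            "visual": model.fusion_spec_.visual_weights.tolist(),
        },
        "pls": {
            "n_components": int(model.n_components_),
            "coef": pls.coef_.ravel().tolist(),
            "intercept": float(np.ravel(pls.intercept_)[0]),
            "x_weights": pls.x_weights_.tolist(),
            "x_loadings": pls.x_loadings_.tolist(),
            "y_loadings": pls.y_loadings_.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return payload


def predict_from_saved(payload: dict, X_spec: np.ndarray, X_vis: np.ndarray) -> np.ndarray:
    """Apply a saved fused model to new raw feature blocks."""
    zs = (X_spec - np.array(payload["spectral_standardizer"]["mean"])) / np.array(
        payload["spectral_standardizer"]["sd"]
    )
    zv = (X_vis - np.array(payload["visual_standardizer"]["mean"])) / np.array(
        payload["visual_standardizer"]["sd"]
    )
    fusedX = np.hstack(
        [zs * np.array(payload["fusion_weights"]["spectral"]),
         zv * np.array(payload["fusion_weights"]["visual"])]
    )
    return fusedX @ np.array(payload["pls"]["coef"]) + payload["pls"]["intercept"]
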