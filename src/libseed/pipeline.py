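"""One-command orchestration: simulate -> preprocess -> PCA -> iPLS ->
train 4 classifiers on full and selected regions -> evaluate.

Every stage writes its artifact to the run directory so stages can be
re-run and audited independently.  Region selection and all hyperparameter
searches see calibration data only; prediction-set labels are first read at
the evaluation stage.

The default profile is desk-scale: the CNN trains for 100 epochs, and on
the "full" region its input is the full wavelength range decimated to at
most `cnn.max_input_length` channels (every n-th channel).  The flag
``cnn.full_profile: true`` restores the 1000-epoch, undecimated recipe.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import synth
from .dataset import SpectralDataset, write_dataset
from .preprocess import PreprocessConfig, preprocess_pipeline
from .chemometrics import ipls_select, pca
from .classifiers import (ELMClassifier, RBFKernelSVM, RBFNetworkClassifier,
                          split_cal_pred)
from .cnn import SpectralCNNClassifier
from .evaluate import build_report

__all__ = ["RunConfig", "load_config", "run_all", "DEFAULT_CONFIG"]

log = logging.getLogger("libseed")

DEFAULT_CONFIG: dict = {
    "seed": 20200215,
    "out_dir": "runs/default",
    "regions": ["full", "selected"],
    "sim": {
        "n_cultivars": 3,
        "n_samples_per_cultivar": 59,
        "n_craters": 16,
        "n_accumulations": 5,
        "noise_sd": 30.0,
        "heteroscedastic": False,
        "shot_jitter_sigma": 0.15,
        "sample_jitter_sigma": 0.10,
        "sample_scale_sigma": 0.05,
        "baseline_coeffs": [25.0, -70.0, 50.0],
        "peak_shape": "lorentzian",
        "lambda_min": 230.0,
        "lambda_max": 880.0,
        "resolving_power": None,
    },
    "preprocess": {
        "trim_lo": 380.01,
        "trim_hi": 860.04,
        "wavelet_name": "db6",
        "decomposition_level": 3,
        "normalization_scope": "per-spectrum",
    },
    "ipls": {
        "k_min": 10,
        "k_max": 30,
        "max_latent": 15,
        "n_folds": 10,
        "cv_scheme": "contiguous",
    },
    "svm": {"exp_min": -8, "exp_max": 8},
    "rbfnn": {"spread_min": 1, "spread_max": 100},
    "elm": {},
    "cnn": {
        "epochs": 100,
        "batch_size": 20,
        "learning_rate": 1e-5,
        "weight_decay": 1e-4,
        "final_relu": True,
        "max_input_length": 2048,
        "full_profile": False,
    },
}


class RunConfig:
    """Resolved configuration: defaults overlaid with user overrides."""

    def __init__(self, data: dict):
        self.data = data

    def __getitem__(self, key):
        return self.data[key]

    def to_dict(self) -> dict:
        return copy.deepcopy(self.data)


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Read YAML config (empty file -> all defaults), reject unknown keys,
    validate the cheap-to-check fields before any computation."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: top level must be a mapping")
    if overrides:
        data = _merge_shallow(data, overrides)
    resolved = _merge(DEFAULT_CONFIG, data)
    PreprocessConfig(**resolved["preprocess"])   # validates wavelet name etc.
    cfg = RunConfig(resolved)
    _sim_config(cfg)                             # validates simulator counts
    return cfg


def _merge_shallow(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_shallow(out[k], v)
        else:
            out[k] = v
    return out


def _sim_config(cfg: RunConfig) -> synth.SimConfig:
    sim = dict(cfg["sim"])
    sim["baseline_coeffs"] = tuple(sim["baseline_coeffs"])
    return synth.SimConfig(**sim, seed=int(cfg["seed"]))


def _subseed(seed: int, offset: int) -> int:
    return (int(seed) + offset) % (2**31 - 1)


def _decimate(X: np.ndarray, max_len: int) -> tuple[np.ndarray, int]:
    step = max(1, int(np.ceil(X.shape[1] / max_len)))
    return X[:, ::step], step


def run_all(config: RunConfig | None = None,
            out_dir: str | Path | None = None) -> Path:
    """Execute the full study; returns the run directory.

    Persists: dataset.csv (+manifest), preprocessed.csv, pca.json,
    ipls.json + rmsecv_intervals.tsv, one JSON per model x region, and the
    evaluation report (report.json + TSV tables) plus manifest.json.
    """
    cfg = config or RunConfig(copy.deepcopy(DEFAULT_CONFIG))
    run_dir = Path(out_dir if out_dir is not None else cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    timings: dict[str, float] = {}
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}
    current = {"stage": "init"}

    def stage(name):
        log.info("stage %s", name)
        current["stage"] = name
        timings[name] = time.time()

    def done(name, **info):
        timings[name] = round(time.time() - timings[name], 2)
        manifest["stages"][name] = info

    try:
        stage("simulate")
        dataset = synth.generate_dataset(_sim_config(cfg))
        write_dataset(dataset, run_dir / "dataset.csv")
        done("simulate", n_samples=dataset.n_samples,
             n_variables=dataset.n_variables)

        stage("preprocess")
        pre = preprocess_pipeline(dataset, PreprocessConfig(**cfg["preprocess"]))
        write_dataset(pre, run_dir / "preprocessed.csv")
        done("preprocess", n_variables=pre.n_variables)

        stage("pca")
        _, evr = pca(pre)
        (run_dir / "pca.json").write_text(json.dumps({
            "explained_variance_pct": [round(100 * v, 2) for v in evr[:10]],
            "first3_total_pct": round(100 * float(evr[:3].sum()), 2),
        }, indent=2))
        done("pca", first3_total_pct=round(100 * float(evr[:3].sum()), 2))

        stage("split")
        split = split_cal_pred(int(cfg["sim"]["n_samples_per_cultivar"]),
                               int(cfg["sim"]["n_cultivars"]))
        cal, prd = split.calibration, split.prediction
        X, y = pre.intensities, pre.labels
        done("split", n_calibration=len(cal), n_prediction=len(prd))

        stage("ipls")
        ip = cfg["ipls"]
        result = ipls_select(X[cal], y[cal], wavelengths=pre.wavelengths,
                             k_range=range(ip["k_min"], ip["k_max"] + 1),
                             max_latent=ip["max_latent"],
                             n_folds=ip["n_folds"], cv_scheme=ip["cv_scheme"])
        best = result.best
        (run_dir / "ipls.json").write_text(json.dumps({
            "best": best.to_dict(),
            "global_rmsecv": result.global_rmsecv,
            "global_n_latent": result.global_n_latent,
            "cv_scheme": result.cv_scheme,
            "n_folds": result.n_folds,
        }, indent=2))
        lines = ["k\tinterval\tvar_start\tvar_stop\twl_lo\twl_hi\tbest_lv\trmsecv"]
        for m in result.table:
            lines.append(f"{m.k}\t{m.interval_index}\t{m.var_start}"
                         f"\t{m.var_stop}\t{m.wavelength_lo:.2f}"
                         f"\t{m.wavelength_hi:.2f}\t{m.best_n_latent}"
                         f"\t{m.rmsecv:.6f}")
        (run_dir / "rmsecv_intervals.tsv").write_text("\n".join(lines) + "\n")
        done("ipls", selected=best.to_dict(),
             global_rmsecv=result.global_rmsecv)

        sel = slice(best.var_start - 1, best.var_stop)
        cnn_cfg = cfg["cnn"]
        full_profile = bool(cnn_cfg["full_profile"])
        results: dict = {}
        for region in cfg["regions"]:
            Xr = X if region == "full" else X[:, sel]
            results[region] = {}
            for name in ("svm", "rbfnn", "elm", "cnn"):
                stage(f"train:{name}:{region}")
                Xtr = Xr
                params: dict = {}
                if name == "svm":
                    model = RBFKernelSVM(**cfg["svm"])
                elif name == "rbfnn":
                    model = RBFNetworkClassifier(**cfg["rbfnn"])
                elif name == "elm":
                    model = ELMClassifier(
                        random_state=_subseed(seed, 1), **cfg["elm"])
                else:
                    epochs = 1000 if full_profile else int(cnn_cfg["epochs"])
                    if region == "full" and not full_profile:
                        Xtr, step = _decimate(Xr, int(cnn_cfg["max_input_length"]))
                        params["decimation_step"] = step
                    model = SpectralCNNClassifier(
                        epochs=epochs,
                        batch_size=int(cnn_cfg["batch_size"]),
                        learning_rate=float(cnn_cfg["learning_rate"]),
                        weight_decay=float(cnn_cfg["weight_decay"]),
                        final_relu=bool(cnn_cfg["final_relu"]),
                        random_state=_subseed(seed, 2))
                model.fit(Xtr[cal], y[cal])
                params.update(_fitted_params(model))
                r = {
                    "y_true_cal": y[cal], "y_pred_cal": model.predict(Xtr[cal]),
                    "y_true_pred": y[prd], "y_pred_pred": model.predict(Xtr[prd]),
                    "params": params,
                }
                results[region][name] = r
                (run_dir / f"model_{name}_{region}.json").write_text(
                    json.dumps({
                        "params": params,
                        "cal_correct": int(np.sum(r["y_pred_cal"] == y[cal])),
                        "pred_correct": int(np.sum(r["y_pred_pred"] == y[prd])),
                        "n_cal": len(cal), "n_pred": len(prd),
                    }, indent=2, default=float))
                done(f"train:{name}:{region}", **params)

        stage("evaluate")
        report = build_report(results, out_dir=run_dir,
                              manifest={"seed": seed})
        done("evaluate", n_regions=len(report["regions"]))
    except Exception as exc:
        manifest["failed_stage"] = current["stage"]
        (run_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(
            f"pipeline failed in stage {current['stage']}: {exc}") from exc
    manifest["timings_s"] = timings
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return run_dir


def _fitted_params(model) -> dict:
    if isinstance(model, RBFKernelSVM):
        return {"C": model.C_, "gamma": model.gamma_,
                "cv_accuracy": model.cv_accuracy_}
    if isinstance(model, RBFNetworkClassifier):
        return {"spread": model.spread_, "cv_accuracy": model.cv_accuracy_}
    if isinstance(model, ELMClassifier):
        return {"n_hidden": model.n_hidden_, "cv_accuracy": model.cv_accuracy_,
                "condition_number": model.condition_number_}
    if isinstance(model, SpectralCNNClassifier):
        return {"epochs": model.epochs, "final_loss": model.loss_curve_[-1]}
    return {}
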