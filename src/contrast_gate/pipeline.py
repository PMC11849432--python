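"""End-to-end orchestration: profile → (augment) → evaluate → threshold → validate.

A single config document (YAML/JSON) drives the run; every stochastic step
derives its seed from the config seed, and the emitted ``report.json`` is a
pure function of the config (byte-identical across reruns).  Per-stage
timings go to the run log only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import augmentation, contrast, io_manifest, seg_metrics, synthetic_data
from . import threshold_analysis as ta
from .errors import ConfigError, ContrastGateError, UnreadableFileError
from .io_manifest import DatasetManifest

log = logging.getLogger("contrast_gate")

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "contrast": {"low_hu": 15.0, "high_hu": 80.0, "bins": 20},
    "augment": {
        "enabled": False,
        "rounds": 3,
        "step_hu": 2.0,
        "delta_hu": 2.0,
        "floor_quantile": 0.5,
    },
    "predictions": {"source": "surrogate"},
    "threshold": {
        "grid_min": 0.005,
        "grid_max": 0.30,
        "grid_step": 0.005,
        "purity_threshold": 0.05,
        "restarts": 10,
        "include_detection": True,
        "performance_bins": 8,
        "crop_fpr_max": None,
        "crop_tpr_min": None,
    },
    "validate": {
        "enabled": True,
        "threshold": None,  # None -> use the selected threshold
        "seeds": [0, 1, 2],
        "test_fraction": 0.25,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    path = Path(path)
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return doc


def normalize_config(config: dict) -> dict:
    cfg = _merge(_DEFAULTS, config)
    if "simulate" not in cfg and "input" not in cfg:
        raise ConfigError("config must contain a 'simulate' or an 'input' block")
    if "input" in cfg and not cfg["input"].get("manifest"):
        raise ConfigError("input block must name a 'manifest'")
    return cfg


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name: str):
    """Re-raise data errors with the failing stage name attached."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %-10s ok (%.2fs)", name, dt)
                return False
            if isinstance(exc, ContrastGateError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def recover_planted_threshold(
    critical_contrast: float,
    seed: int,
    n_slices: int = 400,
    n_patients: int = 40,
    grid: Sequence[float] | None = None,
) -> dict[str, float]:
    """Plant a performance cliff and re-estimate it from scratch.

    Generates a contrast-balanced phantom study (uniform Fisher-ratio
    targets, mirroring a test set deliberately balanced across contrast
    ranges), runs the surrogate segmenter with the cliff at
    ``critical_contrast``, and returns both estimates of the critical
    contrast: the ROC elbow and the clustering R²-sweep selection.
    """
    phantom = synthetic_data.PhantomConfig(
        seed=seed, f_distribution="uniform", f_max=0.35
    )
    samples, truth = synthetic_data.generate_synthetic_dataset(
        phantom, n_slices, n_patients, seed=seed
    )
    true_f = dict(zip(truth["slice_id"], truth["target_f"]))
    surrogate = synthetic_data.SurrogateConfig(
        critical_contrast=critical_contrast, seed=seed + 100
    )
    preds = synthetic_data.surrogate_evaluate_dataset(samples, true_f, surrogate)
    records, _, _ = contrast.contrast_profile(samples)
    fisher = {r.slice_id: r.fisher for r in records}
    scored = [s for s in samples if s.slice_id in fisher]
    evals = [
        seg_metrics.evaluate_slice(preds[s.slice_id], s.lesion_mask, s.slice_id)
        for s in scored
    ]
    confusions = {
        s.slice_id: seg_metrics.confusion_counts(preds[s.slice_id], s.lesion_mask)
        for s in scored
    }
    grid = ta.default_threshold_grid() if grid is None else np.asarray(list(grid))
    sweep = ta.roc_sweep(confusions, fisher, grid)
    elbow = ta.elbow_threshold(sweep)
    X, ids = ta.build_feature_matrix(evals, fisher)
    battery = ta.run_cluster_battery(X, seed=seed)
    f_vec = np.array([fisher[i] for i in ids])
    r2_curve, selected = ta.r2_threshold_sweep(battery, f_vec, grid)
    best = battery[int(np.argmax([b.silhouette for b in battery]))]
    purity, sil = ta.cluster_quality(best, f_vec, critical_contrast)
    return {
        "planted": float(critical_contrast),
        "elbow": float(elbow),
        "r2_selected": float(selected),
        "best_silhouette": float(sil),
        "best_purity_at_planted": float(purity),
        "n_slices": len(scored),
    }


def run_full_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the whole analysis and write report.json plus CSV tables.

    Returns the report dict (what report.json contains).
    """
    cfg = normalize_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    report: dict[str, Any] = {"config_hash": config_hash(cfg), "seed": seed}

    # ---- acquire slices -------------------------------------------------
    with _stage("acquire"):
        if "simulate" in cfg:
            sim = dict(cfg["simulate"])
            n_slices = int(sim.pop("n_slices", 400))
            n_patients = int(sim.pop("n_patients", 40))
            surrogate_over = sim.pop("surrogate", {})
            cstar = sim.pop("critical_contrast", None)
            phantom = synthetic_data.PhantomConfig(**sim.pop("phantom", {}), seed=seed)
            samples, truth = synthetic_data.generate_synthetic_dataset(
                phantom, n_slices, n_patients, seed=seed
            )
            true_f = dict(zip(truth["slice_id"], truth["target_f"]))
            if cstar is not None:
                surrogate_over.setdefault("critical_contrast", float(cstar))
            surrogate_cfg = synthetic_data.SurrogateConfig(
                **surrogate_over, seed=int(rng.integers(synthetic_data.MAX_SEED))
            )
        else:
            samples, _manifest = io_manifest.load_dataset(cfg["input"]["manifest"])
            true_f = None
            surrogate_cfg = None
        report["n_slices"] = len(samples)

    # ---- contrast profile ----------------------------------------------
    ccfg = cfg["contrast"]
    with _stage("profile"):
        records, degenerates, (edges, counts) = contrast.contrast_profile(
            samples, ccfg["low_hu"], ccfg["high_hu"], bins=int(ccfg["bins"])
        )
        fisher = {r.slice_id: r.fisher for r in records}
        scored = [s for s in samples if s.slice_id in fisher]
        report["contrast"] = {
            "n_scored": len(records),
            "n_degenerate": len(degenerates),
            "histogram_edges": [_round(e) for e in edges],
            "histogram_counts": [int(c) for c in counts],
            "imbalance_share": _round(
                augmentation.imbalance_share(fisher.values(), bins=int(ccfg["bins"]))
            ),
        }
        pd.DataFrame(
            {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
        ).to_csv(out / "contrast_histogram.csv", index=False)

    # ---- optional augmentation (report-level) ---------------------------
    acfg = cfg["augment"]
    if acfg["enabled"]:
        with _stage("augment"):
            augmented, aug_report = augmentation.augment_dataset(
                scored,
                records,
                rounds=int(acfg["rounds"]),
                step_hu=float(acfg["step_hu"]),
                delta_hu=float(acfg["delta_hu"]),
                floor_quantile=float(acfg["floor_quantile"]),
                low_hu=ccfg["low_hu"],
                high_hu=ccfg["high_hu"],
            )
            aug_fisher = [
                contrast.score_slice(s, ccfg["low_hu"], ccfg["high_hu"]).fisher
                for s in augmented
            ]
            report["augment"] = {
                "n_original": len(scored),
                "n_augmented_total": len(augmented),
                "accept_min_f": _round(aug_report.accept_min_f),
                "accept_max_f": _round(aug_report.accept_max_f),
                "imbalance_share_after": _round(
                    augmentation.imbalance_share(aug_fisher, bins=int(ccfg["bins"]))
                ),
            }
            aug_report.table.to_csv(out / "augmentation_report.csv", index=False)

    # ---- predictions + per-slice evaluation -----------------------------
    pcfg = cfg["predictions"]
    with _stage("evaluate"):
        if pcfg["source"] == "surrogate":
            if true_f is None:
                true_f = dict(fisher)  # measured F stands in for the truth
            preds = synthetic_data.surrogate_evaluate_dataset(
                scored, true_f, surrogate_cfg or synthetic_data.SurrogateConfig(
                    seed=int(rng.integers(synthetic_data.MAX_SEED))
                ),
            )
        elif pcfg["source"] == "dir":
            pred_dir = Path(pcfg.get("dir", ""))
            if not pred_dir.is_dir():
                raise ConfigError(f"predictions dir not found: {pred_dir}")
            preds = {}
            for s in scored:
                f = pred_dir / f"{s.slice_id}.npz"
                try:
                    with np.load(f) as z:
                        preds[s.slice_id] = (z[z.files[0]] > 0.5).astype(np.uint8)
                except (FileNotFoundError, OSError) as exc:
                    raise UnreadableFileError(f"missing prediction {f}: {exc}") from exc
        else:
            raise ConfigError(f"unknown predictions source {pcfg['source']!r}")
        evals = [
            seg_metrics.evaluate_slice(preds[s.slice_id], s.lesion_mask, s.slice_id)
            for s in scored
        ]
        confusions = {
            s.slice_id: seg_metrics.confusion_counts(preds[s.slice_id], s.lesion_mask)
            for s in scored
        }
        seg_metrics.evaluations_frame(evals).to_csv(out / "evaluations.csv", index=False)

    # ---- threshold analysis ---------------------------------------------
    tcfg = cfg["threshold"]
    grid = ta.default_threshold_grid(
        float(tcfg["grid_min"]), float(tcfg["grid_max"]), float(tcfg["grid_step"])
    )
    with _stage("threshold"):
        fmax = max(fisher.values())
        perf_edges = np.linspace(0.0, fmax, int(tcfg["performance_bins"]) + 1)
        perf = ta.bin_performance(evals, fisher, perf_edges)
        perf.to_csv(out / "per_bin_performance.csv", index=False)

        sweep = ta.roc_sweep(confusions, fisher, grid)
        cropped = ta.crop_sweep(sweep, tcfg["crop_fpr_max"], tcfg["crop_tpr_min"])
        elbow = ta.elbow_threshold(cropped if cropped else sweep)
        pd.DataFrame(
            [
                {
                    "threshold": p.contrast_threshold,
                    "tpr": p.tpr,
                    "fpr": p.fpr,
                    "n_slices": p.n_slices,
                }
                for p in sweep
            ]
        ).to_csv(out / "roc_sweep.csv", index=False)

        X, ids = ta.build_feature_matrix(
            evals, fisher, include_detection=bool(tcfg["include_detection"])
        )
        battery = ta.run_cluster_battery(
            X, seed=seed, restarts=int(tcfg["restarts"]), slice_ids=ids
        )
        f_vec = np.array([fisher[i] for i in ids])
        ptable = ta.purity_table(battery, f_vec, float(tcfg["purity_threshold"]))
        ptable.to_csv(out / "purity_table.csv", index=False)
        r2_curve, selected = ta.r2_threshold_sweep(battery, f_vec, grid)
        r2_curve.to_csv(out / "r2_curve.csv", index=False)

        best = battery[int(np.nanargmax([b.silhouette for b in battery]))]
        scatter = pd.DataFrame(
            {
                "slice_id": ids,
                "fisher": f_vec,
                "cluster": best.labels,
                "dsc": [e.dsc for e in evals],
                "hd": [e.hd for e in evals],
                "raad": [e.raad for e in evals],
            }
        )
        scatter.to_csv(out / "cluster_scatter.csv", index=False)
        lowc = int(np.argmin(best.centroids[:, -1]))
        cluster_f_means = [
            _round(float(f_vec[best.labels == k].mean())) for k in (lowc, 1 - lowc)
        ]

        report["threshold"] = {
            "grid": [_round(g) for g in (grid[0], grid[-1], grid[1] - grid[0])],
            "elbow_threshold": _round(elbow),
            "selected_threshold": _round(selected),
            "best_combo": {
                "algorithm": best.algorithm,
                "distance": best.distance,
                "silhouette": _round(best.silhouette),
                "purity": _round(
                    ta.cluster_quality(best, f_vec, float(tcfg["purity_threshold"]))[0]
                ),
            },
            "r2_at_selected": _round(
                float(r2_curve.set_index("threshold").loc[selected, "r2"])
            ),
            "cluster_fisher_means": cluster_f_means,
            "failure_fraction_below_selected": {
                k: (None if np.isnan(v) else _round(v))
                for k, v in ta.failure_fraction_below(evals, fisher, selected).items()
            },
        }

    # ---- validation by retraining ---------------------------------------
    vcfg = cfg["validate"]
    if vcfg["enabled"]:
        with _stage("validate"):
            rows = [
                {
                    "slice_id": s.slice_id,
                    "file": "",
                    "patient_id": s.patient_id,
                    "slice_index": s.slice_index,
                    "lesion_area_cm2": s.lesion_area_cm2,
                    "fisher": fisher[s.slice_id],
                    "split": "",
                }
                for s in scored
            ]
            manifest = DatasetManifest(
                pd.DataFrame(rows, columns=io_manifest.MANIFEST_COLUMNS)
            )
            manifest = io_manifest.contrast_balanced_split(
                manifest, test_fraction=float(vcfg["test_fraction"]), seed=seed
            )
            split = dict(zip(manifest.table["slice_id"], manifest.table["split"]))
            train = [s for s in scored if split[s.slice_id] == "train"]
            test = [s for s in scored if split[s.slice_id] == "test"]
            v_threshold = (
                float(vcfg["threshold"]) if vcfg["threshold"] is not None else selected
            )
            vreport = ta.validate_threshold(
                train, test, fisher, fisher, v_threshold,
                seeds=[int(s) for s in vcfg["seeds"]],
            )
            vreport.table.to_csv(out / "validation.csv", index=False)
            vt = vreport.table.set_index(["training", "test"])
            report["validation"] = {
                "threshold": _round(v_threshold),
                "n_train_full": vreport.n_train_full,
                "n_train_filtered": vreport.n_train_filtered,
                "reduction_fraction": _round(vreport.reduction_fraction),
                "dsc_full_training": _round(vt.loc[("all", "all"), "dsc_mean"]),
                "dsc_filtered_training": _round(
                    vt.loc[("f_ge_threshold", "all"), "dsc_mean"]
                ),
            }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report
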