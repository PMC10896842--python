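"""End-to-end orchestration: sleep data processing → protocol simulation.

The pipeline mirrors the two-procedure design of the method: (A) process
sleep EEG — detect SOs, type them by co-detection clustering, represent
them as CD matrices, average the global ones into the stimulation
target, compute ANOVA-F feature weights, train the global/non-global
classifier; (B) simulate stimulation — optimize every (montage,
waveform, Δt) grid cell against the target with the GA, score the
optimized paradigms, and select the protocol with the highest "global"
posterior probability.

Because source estimation is external to this package, stage (A) takes
its per-SO CD matrices either from an imported store or from the
synthetic generator; the detection/clustering stages run on (synthetic
or real) EEG and establish the global/non-global labelling context.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify
from .cd import average_cd, estimate_paradigm_cd, flatten_cd
from .clustering import build_codetection, kmeans_hamming, label_clusters
from .detection import SODetectionParams, detect_sos
from .montage import Montage, Paradigm, enumerate_montages
from .optimize import GAConfig, optimize_grid, select_protocol
from .synthetic import (DEFAULT_QUARTILE_CANDIDATES, SyntheticCDSpec,
                        SyntheticEEGSpec, cds_from_dataset, detection_scores,
                        frontal_posterior_partition, gen_cd_dataset, gen_eeg,
                        gen_transfer)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a fully synthetic end-to-end run."""

    seed: int = 0
    stage: str = "SWS"
    dt: int = 200
    eeg_spec: SyntheticEEGSpec | None = None
    cd_spec: SyntheticCDSpec | None = None
    #: ground-truth paradigm whose CD becomes the global-class mean; when
    #: None, the generator's default trough-bump pattern is used
    true_paradigm: Paradigm | None = None
    montages: list[Montage] | None = None
    waveform_kinds: list[str] = field(default_factory=lambda: ["W1"])
    ga: GAConfig | None = None
    n_trees: int = 100
    tune_classifier: bool = False
    run_detection: bool = True
    out_dir: str | None = None


def _default_montages(seed: int, n: int = 3) -> list[Montage]:
    rng = np.random.default_rng(seed)
    lists = [DEFAULT_QUARTILE_CANDIDATES[q]
             for q in ("left-anterior", "right-anterior",
                       "left-posterior", "right-posterior")]
    all_m = enumerate_montages(lists)
    idx = rng.choice(len(all_m), size=min(n, len(all_m)), replace=False)
    return [all_m[i] for i in sorted(idx)]


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Run the full pipeline; returns a report dict (JSON-serialisable
    except for the ``selected_result`` entry, a :class:`ProtocolResult`)."""
    cfg = cfg or PipelineConfig()
    t0 = time.time()
    report: dict = {"seed": cfg.seed, "stage": cfg.stage, "dt_ms": cfg.dt}

    # --- stage A1: detection + clustering on (synthetic) EEG ------------
    if cfg.run_detection:
        eeg_spec = cfg.eeg_spec or SyntheticEEGSpec(seed=cfg.seed)
        rec, truth = gen_eeg(eeg_spec)
        events = detect_sos(rec, SODetectionParams(), stage=cfg.stage)
        recall, precision = detection_scores(truth, events)
        report["detection"] = {
            "n_planted": int(len(truth)), "n_detected": len(events),
            "recall": recall, "precision": precision,
        }
        if len({e.channel for e in events}) >= 3 and len(events) >= 10:
            codet = build_codetection(events, rec.channel_names)
            model = kmeans_hamming(codet, seed=cfg.seed, replicates=50)
            frontal, posterior_chs = frontal_posterior_partition(rec.channel_names)
            model = label_clusters(model, frontal, posterior_chs)
            types = model.types()
            report["clustering"] = {
                "inertia": model.inertia,
                "counts": {t: int((types == t).sum()) for t in set(types)},
            }
        else:
            logger.warning("too few events for clustering; skipping stage")
            report["clustering"] = None

    # --- stage A2: CD dataset, target, weights, classifier ---------------
    tm = gen_transfer(seed=cfg.seed)
    cd_spec = cfg.cd_spec or SyntheticCDSpec(dt=cfg.dt, seed=cfg.seed)
    global_mean = None
    if cfg.true_paradigm is not None:
        target_cd = estimate_paradigm_cd(cfg.true_paradigm, tm)
        rms = float(np.sqrt(np.mean(flatten_cd(target_cd) ** 2)))
        noise_sd = max(rms / max(cd_spec.effect, 1e-9), 1e-9)
        cd_spec = SyntheticCDSpec(**{**cd_spec.__dict__, "dt": cfg.dt,
                                     "noise_sd": noise_sd})
        global_mean = target_cd
    X, y = gen_cd_dataset(cd_spec, global_mean=global_mean)
    target = average_cd(cds_from_dataset(X[y == 1], cd_spec.dt))
    weights = classify.anova_f_weights(X, y)
    cv_mcc = classify.crossval_mcc(X, y, folds=5, seed=cfg.seed,
                                   n_trees=cfg.n_trees)
    clf = classify.train(X, y, seed=cfg.seed, n_trees=cfg.n_trees,
                         tune=cfg.tune_classifier)
    report["classifier"] = {"crossval_mcc": cv_mcc,
                            "n_global": int((y == 1).sum()),
                            "n_nonglobal": int((y == 0).sum())}

    # --- stage B: grid optimisation and protocol selection ---------------
    montages = cfg.montages or _default_montages(cfg.seed)
    if cfg.true_paradigm is not None and cfg.true_paradigm.montage not in montages:
        montages = [cfg.true_paradigm.montage] + list(montages)
    ga_cfg = cfg.ga or GAConfig(seed=cfg.seed)
    results = optimize_grid(montages, cfg.waveform_kinds, [cfg.dt],
                            target, tm, weights, cfg=ga_cfg)
    best, any_global = select_protocol(results, model=clf, target=target,
                                       weights=weights)
    report["grid"] = {
        "n_cells": len(results),
        "n_failed": sum(r.failed for r in results),
        "cells": [r.to_record() for r in results],
    }
    report["protocol"] = {
        "paradigm": best.paradigm.key,
        "posterior": best.posterior,
        "predicted_global": bool(best.predicted_global),
        "any_global": bool(any_global),
        "wcc": best.wcc,
        "wmse": best.wmse,
        "fitness": best.fitness,
    }
    if cfg.true_paradigm is not None:
        report["protocol"]["true_paradigm"] = cfg.true_paradigm.montage.key
        report["protocol"]["matched_true_montage"] = (
            best.paradigm.montage.key == cfg.true_paradigm.montage.key)
    report["manifest"] = {
        "seed": cfg.seed,
        "target_hash": _hash_array(target.values),
        "weights_hash": _hash_array(weights.w),
        "runtime_s": round(time.time() - t0, 2),
    }
    report["selected_result"] = best
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        serialisable = {k: v for k, v in report.items() if k != "selected_result"}
        (out / "report.json").write_text(json.dumps(serialisable, indent=2))
    return report
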