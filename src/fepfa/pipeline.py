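"""End-to-end orchestration: simulate -> select -> refine -> classify.

Runs the full desk-scale analogue of the staged-dementia pipeline on
synthetic planted-signal data: generate a labeled feature matrix, select
features with the pathfinder wrapper, refine the subset with fuzzy-entropy
ranking, classify the held-out half, and write every artifact (masks,
scores, history, metrics, run manifest) to an output directory.
"""

from __future__ import annotations

import json
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import fuzzy_entropy, metrics, pfa, synthetic


@dataclass
class PipelineConfig:
    """All stage parameters with desk-scale defaults."""

    seed: int = 0
    # synthetic data (stands in for the four-class MRI feature table)
    n_per_class: int = 50
    n_classes: int = 4
    d: int = 200
    d_informative: int = 20
    effect_size: float = 3.0
    # pathfinder search
    swarm_size: int = 20
    max_iter: int = 30
    knn_k: int = 5
    eval_scheme: str = "holdout_50_50"
    # fuzzy-entropy refinement
    retain_fraction: float = fuzzy_entropy.DEFAULT_RETAIN_FRACTION
    fuzziness: float = 2.0
    # final classification
    classifier: str = "knn"
    classifier_params: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(**raw)


@dataclass
class PipelineResult:
    pfa_mask: pfa.SelectionMask
    refined_mask: pfa.SelectionMask
    pfa_record: pfa.FitnessRecord
    history: list[float]
    metrics_pfa: metrics.MetricsReport
    metrics_refined: metrics.MetricsReport
    timings: dict[str, float]
    truth: synthetic.PlantedTruth


def _split(data: synthetic.LabeledFeatureMatrix, seed: int):
    xtr, xte, ytr, yte = train_test_split(
        data.values, data.labels, test_size=0.5, stratify=data.labels, random_state=seed
    )
    train = synthetic.LabeledFeatureMatrix(xtr, ytr, list(data.feature_ids))
    test = synthetic.LabeledFeatureMatrix(xte, yte, list(data.feature_ids))
    return train, test


def run_pipeline(
    config: PipelineConfig | str | Path, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute every stage; optionally write artifacts under ``out_dir``."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_toml(config)
    timings: dict[str, float] = {}

    def staged(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        return result

    data, truth = staged(
        "simulate",
        lambda: synthetic.make_gaussian_feature_data(
            cfg.n_per_class, cfg.n_classes, cfg.d, cfg.d_informative, cfg.effect_size, cfg.seed
        ),
    )
    pfa_cfg = pfa.PfaConfig(
        swarm_size=cfg.swarm_size,
        max_iter=cfg.max_iter,
        knn_k=cfg.knn_k,
        eval_scheme=cfg.eval_scheme,
        seed=cfg.seed,
    )
    mask, record, history = staged("pfa_select", lambda: pfa.run_pfa(data, pfa_cfg))
    refined = staged(
        "fuzzy_refine",
        lambda: fuzzy_entropy.refine_selection(
            data, mask, retain_fraction=cfg.retain_fraction, e=cfg.fuzziness, seed=cfg.seed
        ),
    )
    train, test = _split(data, cfg.seed)
    report_pfa = staged(
        "classify_pfa",
        lambda: metrics.classify_selected(
            train, test, mask, cfg.classifier, cfg.classifier_params, seed=cfg.seed
        ),
    )
    report_ref = staged(
        "classify_refined",
        lambda: metrics.classify_selected(
            train, test, refined, cfg.classifier, cfg.classifier_params, seed=cfg.seed
        ),
    )

    result = PipelineResult(
        pfa_mask=mask,
        refined_mask=refined,
        pfa_record=record,
        history=history,
        metrics_pfa=report_pfa,
        metrics_refined=report_ref,
        timings=timings,
        truth=truth,
    )
    if out_dir is not None:
        _write_artifacts(Path(out_dir), cfg, result)
    return result


def _write_artifacts(out: Path, cfg: PipelineConfig, res: PipelineResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    synthetic.save_mask(res.pfa_mask.selected, out / "pfa_mask.csv")
    synthetic.save_mask(res.refined_mask.selected, out / "refined_mask.csv")
    pd.DataFrame({"iteration": range(len(res.history)), "best_cost": res.history}).to_csv(
        out / "history.csv", index=False
    )
    metrics_rows = {
        "pfa": asdict(res.metrics_pfa),
        "refined": asdict(res.metrics_refined),
    }
    pd.DataFrame(metrics_rows).T.to_csv(out / "metrics.csv")
    manifest = {
        "config": asdict(cfg),
        "timings_s": res.timings,
        "pfa_fitness": asdict(res.pfa_record),
        "n_selected_pfa": res.pfa_mask.n_selected,
        "n_selected_refined": res.refined_mask.n_selected,
        "informative_recall_pfa": planted_recall(res.pfa_mask, res.truth),
        "informative_recall_refined": planted_recall(res.refined_mask, res.truth),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def planted_recall(mask: pfa.SelectionMask, truth: synthetic.PlantedTruth) -> float:
    """Fraction of planted informative features present in a mask."""
    informative = truth.informative_mask
    if not informative.any():
        return float("nan")
    return float((mask.selected & informative).sum() / informative.sum())
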