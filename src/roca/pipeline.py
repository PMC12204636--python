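"""End-to-end orchestration: synthesize -> train -> score patients -> evaluate.

The pipeline mirrors the deployed flow of the screening tool: labeled
drawings are synthesized and a classifier is trained on them; a patient
cohort is simulated; each simulated patient "draws" a battery consistent
with their per-task correctness; the classifier judges each drawing; the
rubric turns judgments into a score; and the screening statistics are
computed against true status.  Every stage draws its seed deterministically
from one master seed, so reruns of the same configuration reproduce the
report exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, simulate_cohort
from .drawing import TASKS
from .scoring import ScreenPolicy, score_battery
from .screen_eval import (ChanceModel, chance_confusion, confusion_from_predictions,
                          metrics_from_confusion, p_vs_chance, roc_curve,
                          threshold_sweep, youden_threshold)
from .sketchnet import (NetConfig, TrainSpec, TrainedClassifier, build_model,
                        drawings_to_arrays, train)
from .synth import generate_labeled, generate_labeled_dataset


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    seed: int
    n_per_cell: int = 200
    correct_fraction: float = 0.5
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainSpec = field(default_factory=TrainSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    threshold: int = 7
    n_boot: int = 1000
    level: float = 0.95

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "RunConfig":
        if "seed" not in raw:
            raise ValueError("configuration must provide an explicit 'seed'")
        kw = dict(raw)
        if "net" in kw:
            kw["net"] = NetConfig(**kw["net"])
        if "train" in kw:
            kw["train"] = TrainSpec(**kw["train"])
        if "cohort" in kw:
            cspec = dict(kw["cohort"])
            if "task_fail" in cspec:
                cspec["task_fail"] = {k: tuple(v) for k, v in cspec["task_fail"].items()}
            kw["cohort"] = CohortSpec(**cspec)
        return cls(**kw)


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return decorate


def derive_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def simulate_patient_batteries(cohort: pd.DataFrame, classifier: TrainedClassifier,
                               seed: int) -> pd.DataFrame:
    """Give each simulated patient a drawn battery and re-score it via the classifier.

    For each patient and task, a synthetic drawing matching the patient's
    true per-task correctness is generated, classified, and condensed; the
    rubric is applied to the classifier's judgments.  Returns a copy of the
    cohort with ``pred_<task>`` columns and a ``roca_score`` column.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    preds: dict[str, list[bool]] = {t: [] for t in TASKS}
    for _, row in cohort.iterrows():
        for task in TASKS:
            drawing, _ = generate_labeled(task, bool(row[task]), int(rng.integers(2 ** 31)))
            preds[task].append(classifier.classify_drawing(drawing).condensed_correct)
    for task in TASKS:
        out[f"pred_{task}"] = preds[task]
    out["roca_score"] = [score_battery({t: bool(out[f"pred_{t}"][i]) for t in TASKS})
                         for i in out.index]
    return out


def evaluate_cohort(scores: np.ndarray, impaired: np.ndarray, threshold: int = 7,
                    n_boot: int = 1000, seed: int = 0, level: float = 0.95) -> dict:
    """The full screening evaluation on one cohort of (score, status) pairs."""
    policy = ScreenPolicy(threshold=threshold)
    pred = ["positive" if s <= threshold else "negative" for s in scores]
    true = ["positive" if i else "negative" for i in impaired]
    cm = confusion_from_predictions(pred, true)
    metrics = metrics_from_confusion(cm)

    roc = roc_curve(scores, impaired, positive_low=True)
    youden_t, youden_j = youden_threshold(roc)
    records = list(zip(scores.tolist(), impaired.tolist()))

    def auc_stat(recs):
        s = np.array([r[0] for r in recs])
        y = np.array([r[1] for r in recs], dtype=bool)
        return roc_curve(s, y).auc

    auc_cmp, auc_boot = p_vs_chance(records, auc_stat, 0.5, n_boot=n_boot, seed=seed)

    prior_pos = float(np.mean(impaired))
    chance = ChanceModel.uniform_binary(prior_pos)
    chance_cm, chance_metrics = chance_confusion(chance)

    metric_results = {}
    for name in ("accuracy", "sensitivity", "npv", "specificity", "ppv"):
        def stat(recs, _name=name):
            s = np.array([r[0] for r in recs])
            y = np.array([r[1] for r in recs], dtype=bool)
            p = ["positive" if v <= threshold else "negative" for v in s]
            t = ["positive" if i else "negative" for i in y]
            return getattr(metrics_from_confusion(confusion_from_predictions(p, t)), _name)
        chance_value = getattr(chance_metrics, name)
        point_value = getattr(metrics, name)
        if np.isnan(point_value):
            # zero denominator at this cut (e.g. nobody screened negative):
            # flagged, not bootstrapped
            metric_results[name] = {"value": point_value, "ci": [float("nan")] * 2,
                                    "chance": chance_value, "p_vs_chance": "undefined"}
            continue
        cmp_, boot = p_vs_chance(records, stat, chance_value, n_boot=n_boot, seed=seed + 1)
        metric_results[name] = {
            "value": point_value,
            "ci": [boot.ci_low, boot.ci_high],
            "chance": chance_value,
            "p_vs_chance": cmp_.display(),
        }

    sweep = threshold_sweep(scores, impaired, n_boot=n_boot, seed=seed + 2, level=level)
    return {
        "n": int(len(scores)),
        "threshold": threshold,
        "policy": policy.rule,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "metrics": metric_results,
        "auc": {"point": roc.auc, "boot_mean": auc_boot.boot_mean,
                "ci": [auc_boot.ci_low, auc_boot.ci_high],
                "p_vs_chance": auc_cmp.display(), "chance": 0.5},
        "roc_points": [{"threshold": p.threshold, "sensitivity": p.sensitivity,
                        "fpr": p.fpr} for p in roc.points],
        "youden": {"threshold": youden_t, "j": youden_j},
        "chance_baseline": {"confusion": {"tp": chance_cm.tp, "fp": chance_cm.fp,
                                          "fn": chance_cm.fn, "tn": chance_cm.tn},
                            "metrics": chance_metrics.as_dict()},
        "threshold_sweep": {str(t): {"metrics": e["metrics"], "ci": e["ci"]}
                            for t, e in sweep["sweep"].items()},
        "best_screen_threshold": sweep["best_screen_threshold"],
        "n_boot": n_boot, "seed": seed, "level": level,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full flow and return (and optionally write) the report."""
    seeds = derive_seeds(config.seed, 5)

    @_stage("synth")
    def do_synth():
        pairs = generate_labeled_dataset(config.n_per_cell, config.correct_fraction,
                                         seed=seeds[0])
        return drawings_to_arrays(pairs)

    @_stage("train")
    def do_train(x, labels):
        from dataclasses import replace
        model = build_model(config.net)
        # the master seed governs every stage; per-stage seeds are derived
        return train(model, x, labels, replace(config.train, seed=seeds[1]))

    @_stage("cohort")
    def do_cohort():
        from dataclasses import replace
        return simulate_cohort(replace(config.cohort, seed=seeds[2]))

    @_stage("score")
    def do_score(cohort, classifier):
        return simulate_patient_batteries(cohort, classifier, seed=seeds[3])

    @_stage("evaluate")
    def do_eval(scored):
        return evaluate_cohort(scored["roca_score"].to_numpy(),
                               (scored["status"] == "impaired").to_numpy(),
                               threshold=config.threshold, n_boot=config.n_boot,
                               seed=seeds[4], level=config.level)

    x, labels = do_synth()
    classifier, train_report = do_train(x, labels)
    cohort = do_cohort()
    scored = do_score(cohort, classifier)
    evaluation = do_eval(scored)

    drawing_agreement = float(np.mean(
        [scored[f"pred_{t}"].to_numpy() == scored[t].to_numpy() for t in TASKS]))
    report = {
        "version": __version__,
        "seeds": {"master": config.seed, "synth": seeds[0], "train": seeds[1],
                  "cohort": seeds[2], "batteries": seeds[3], "evaluate": seeds[4]},
        "training": {"final_val_acc": train_report["final_val_acc"],
                     "n_train": train_report["n_train"],
                     "n_val": train_report["n_val"]},
        "drawing_agreement": drawing_agreement,
        "evaluation": evaluation,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        classifier.save(out / "model.npz")
        scored.to_csv(out / "cohort.csv", index=False)
        (out / "training_report.json").write_text(json.dumps(train_report, indent=2))
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
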