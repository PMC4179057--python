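"""End-to-end pipeline: simulate -> calibrate -> detect -> mine -> train.

Ties the services together the way the deployed system wires them: the
load-cell stream drives the bed-presence detector, the detector's Bin /
Bout events are merged with the ambient sensors into the transition
miner and the early-night classifier, and all artifacts (event logs,
DOT graphs, tree dumps, metrics JSON) are written to an output
directory.  A config dict plus a seed fully determine every artifact.

Reported metrics:

* detector — event-level precision/recall/F1 of Bin/Bout against the
  simulator's ground truth (greedy time matching), and the fraction of
  half-second windows whose presence decision disagrees with the true
  bed state;
* transitions — the largest absolute difference between transition
  probabilities mined from detected bed events and those mined from the
  ground-truth bed events (the error introduced by the detection layer);
* classifier — stratified 10-fold cross-validation accuracy of the
  C4.5 model against the majority-class baseline.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import io as nio
from .bed_presence import calibrate, detect_stream, window_decisions
from .features import build_dataset
from .signal_stats import DEFAULT_WINDOW, rolling_window_stats, WindowStats
from .simulator import LoadcellConfig, NightRecord, ScenarioConfig, simulate
from .transitions import TransitionModel
from .tree import cross_validate, train_c45

REQUIRED_KEYS = ("scenario", "seed")

_SCENARIO_SCALARS = {
    "n_nights", "night_hours", "early_hours", "start_date",
    "emfit_miss_rate", "emfit_spurious_per_night", "inactivity_timeout_min",
}
_LOADCELL_FIELDS = {f.name for f in dataclasses.fields(LoadcellConfig)}


def scenario_from_dict(d: dict, seed: int) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a config mapping.

    Only scalar scenario knobs and the load-cell emission block are
    exposed through files; planted matrices and dwell tables keep their
    defaults (they are the study conditions).  Unknown keys are an error.
    """
    d = dict(d or {})
    lc = d.pop("loadcell", {})
    unknown = (set(d) - _SCENARIO_SCALARS) | (set(lc) - _LOADCELL_FIELDS)
    if unknown:
        raise nio.ConfigKeyError(f"unknown scenario keys: {sorted(unknown)}")
    kwargs = dict(d)
    if lc:
        kwargs["loadcell"] = LoadcellConfig(**lc)
    return ScenarioConfig(seed=seed, **kwargs)


def match_events(detected, truth, tol_s: float = 10.0) -> int:
    """Greedy chronological matching of same-symbol events within tol_s."""
    matched = 0
    used: set[int] = set()
    for d in detected:
        for i, t in enumerate(truth):
            if i in used or t.symbol != d.symbol:
                continue
            if abs((d.ts - t.ts).total_seconds()) <= tol_s:
                used.add(i)
                matched += 1
                break
    return matched


def event_level_scores(detected, truth, tol_s: float = 10.0) -> dict:
    tp = match_events(detected, truth, tol_s)
    precision = tp / len(detected) if detected else 1.0
    recall = tp / len(truth) if truth else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"tp": tp, "n_detected": len(detected), "n_true": len(truth),
            "precision": precision, "recall": recall, "f1": f1}


def window_truth(record: NightRecord, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Ground-truth occupancy at each window's end time."""
    n_windows = (record.adc.size // window)
    ends = (np.arange(1, n_windows + 1) * window) / record.sampling_hz
    truth = np.zeros(n_windows, dtype=bool)
    for a, b in record.bed_intervals:
        truth |= (ends > a) & (ends <= b)
    return truth


def calibration_windows(record: NightRecord, window: int = DEFAULT_WINDOW):
    m_w, mean_w, sigma_w = rolling_window_stats(record.weights, n=window)
    dt = window / record.sampling_hz
    return [
        WindowStats(m_w=float(m_w[i]), mean_w=float(mean_w[i]),
                    sigma_w=float(sigma_w[i]), window_end_ts=(i + 1) * dt, n=window)
        for i in range(m_w.size)
    ]


def run_pipeline(config: dict, seed: int | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns the metrics dict.

    ``config`` needs at least the keys ``scenario`` and ``seed`` (the
    ``seed`` argument overrides the file value).  With ``out_dir`` set,
    writes events.jsonl, thresholds.json, detected_events.jsonl,
    transitions.dot / transitions.csv, dataset.csv, tree.txt / tree.dot
    and metrics.json.
    """
    missing = [k for k in REQUIRED_KEYS if k not in config and
               not (k == "seed" and seed is not None)]
    if missing:
        raise nio.ConfigKeyError(f"missing config keys: {missing}")
    seed = int(config["seed"] if seed is None else seed)
    cfg = scenario_from_dict(config.get("scenario", {}), seed=seed)
    clf_cfg = dict(config.get("classifier", {}))
    mining_cfg = dict(config.get("mining", {}))
    detector_cfg = dict(config.get("detector", {}))

    nights = simulate(cfg, include_loadcell=True)

    # calibration on the first night, applied to all nights
    thresholds = calibrate(calibration_windows(nights[0]))

    confirm = int(detector_cfg.get("confirm", 2))
    detected_by_night: dict[str, list] = {}
    true_by_night: dict[str, list] = {}
    mis_windows = 0
    total_windows = 0
    for rec in nights:
        det = detect_stream(
            rec.weights, thresholds, sampling_hz=rec.sampling_hz,
            confirm=confirm, night_id=rec.night_id, night_start=rec.night_start,
        )
        detected_by_night[rec.night_id] = det
        true_by_night[rec.night_id] = rec.true_bed_events
        dec = window_decisions(rec.weights, thresholds)
        truth = window_truth(rec)
        mis_windows += int((dec != truth).sum())
        total_windows += dec.size

    all_detected = [e for rec in nights for e in detected_by_night[rec.night_id]]
    all_true = [e for rec in nights for e in true_by_night[rec.night_id]]
    det_scores = event_level_scores(all_detected, all_true)

    # transition mining from detected vs ground-truth bed events
    debounce = float(mining_cfg.get("debounce_gap_s", 30.0))
    conf_thr = float(mining_cfg.get("confidence_threshold", 0.2))
    model_det = TransitionModel(debounce_gap_s=debounce)
    model_truth = TransitionModel(debounce_gap_s=debounce)
    events_by_night: dict[str, list] = {}
    night_starts = {}
    for rec in nights:
        merged = sorted(rec.ambient_events + detected_by_night[rec.night_id],
                        key=lambda e: e.ts)
        events_by_night[rec.night_id] = merged
        night_starts[rec.night_id] = rec.night_start
        model_det.observe_all(merged)
        model_truth.observe_all(rec.events_with_true_bed())
    p_det = model_det.probability_matrix()
    p_truth = model_truth.probability_matrix()
    both = ~(np.isnan(p_det).any(axis=1) | np.isnan(p_truth).any(axis=1))
    trans_err = (float(np.nanmax(np.abs(p_det[both] - p_truth[both])))
                 if both.any() else float("nan"))

    # early-night classifier
    dataset = build_dataset(
        events_by_night, night_starts,
        width_min=float(clf_cfg.get("width_min", 20.0)),
        night_hours=cfg.night_hours, early_hours=cfg.early_hours,
    )
    k = int(clf_cfg.get("cv_folds", 10))
    cv = cross_validate(dataset, k=k, seed=seed,
                        min_leaf=int(clf_cfg.get("min_leaf", 5)),
                        max_depth=int(clf_cfg.get("max_depth", 10)))
    tree = train_c45(dataset, min_leaf=int(clf_cfg.get("min_leaf", 5)),
                     max_depth=int(clf_cfg.get("max_depth", 10)))

    metrics = {
        "seed": seed,
        "n_nights": cfg.n_nights,
        "thresholds": {"O_m_w": thresholds.O_m_w,
                       "O_sigma_w": thresholds.O_sigma_w},
        "detector": {
            "f1": det_scores["f1"], "precision": det_scores["precision"],
            "recall": det_scores["recall"],
            "n_detected": det_scores["n_detected"],
            "n_true": det_scores["n_true"],
            "window_misclassification_rate": mis_windows / total_windows,
        },
        "transitions": {
            "recovery_max_abs_error": trans_err,
            "n_transitions": int(model_det.counts.sum()),
        },
        "classifier": {
            "cv_mean_accuracy": cv["mean_accuracy"],
            "cv_std_accuracy": cv["std_accuracy"],
            "majority_baseline": cv["majority_baseline"],
            "n_observations": int(len(dataset)),
            "tree_depth": tree.depth,
            "tree_leaves": tree.n_leaves(),
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nio.write_event_log(
            [e for nid in sorted(events_by_night) for e in events_by_night[nid]],
            out / "events.jsonl")
        nio.write_event_log(all_detected, out / "detected_events.jsonl")
        nio.write_json(metrics["thresholds"], out / "thresholds.json")
        (out / "transitions.dot").write_text(model_det.export_graph(conf_thr))
        model_det.to_frame().to_csv(out / "transitions.csv", index=False)
        dataset.to_csv(out / "dataset.csv", index=False)
        (out / "tree.txt").write_text(tree.to_text())
        (out / "tree.dot").write_text(tree.to_dot())
        nio.write_json(metrics, out / "metrics.json")
    return metrics
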