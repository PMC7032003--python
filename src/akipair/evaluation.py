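"""End-to-end experiments and performance metrics.

``run_experiment`` drives the whole pipeline over a grid of prediction
horizons d and window lengths w: label and filter the cohort, under-sample to
balanced datasets, and for each dataset split into selection/prediction
parts, fit the symbol bins, select channels (SFS or SBS) on the selection
part, classify the prediction part with the selection part as the reference
set, and score the predictions.  Metrics are averaged across the balanced
datasets (macro by default; micro pools the confusion counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import cohort_builder as cb
from .classifier import ABSTAIN, POSITIVE, KnnConfig, PairId
from .io_config import PipelineConfig, read_tables
from .representation import build_payloads, fit_pair_symbolizers
from .selection import (SelectionResult, evaluate_pair_set, pair_vote_table,
                        pair_vote_table_against, sbs, sfs)
from .synthetic_ehr import generate_cohort

__all__ = ["ConfusionMetrics", "MetricsReport", "confusion_metrics", "roc_auc",
           "run_experiment", "write_reports"]


@dataclass(frozen=True)
class ConfusionMetrics:
    precision: float
    recall: float
    f1: float
    accuracy: float
    no_positive_predictions: bool = False


@dataclass(frozen=True)
class MetricsReport:
    """Averaged performance at one (horizon, window) grid point."""

    horizon_days: int
    window_days: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float
    n_datasets: int
    per_dataset: Tuple[Dict, ...]


def confusion_metrics(labels: Sequence[bool], predictions: Sequence[bool]) -> ConfusionMetrics:
    """Precision/recall/F1/accuracy with AKI as the positive class.

    With zero predicted positives the precision is undefined; it is reported
    as 0 with ``no_positive_predictions`` set, which keeps result tables
    total without hiding the degenerate case.
    """
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    if y.size == 0 or y.size != p.size:
        raise ValueError("labels and predictions must be equal-length and non-empty")
    tp = int((y & p).sum())
    fp = int((~y & p).sum())
    fn = int((y & ~p).sum())
    flag = (tp + fp) == 0
    precision = 0.0 if flag else tp / (tp + fp)
    recall = tp / (y.sum()) if y.any() else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    accuracy = float((y == p).mean())
    return ConfusionMetrics(precision, recall, f1, accuracy, flag)


def roc_auc(labels: Sequence[bool], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def _candidate_pairs(payloads: Dict[str, Dict[PairId, object]],
                     restrict: Optional[str]) -> List[PairId]:
    pairs = sorted({p for pl in payloads.values() for p in pl})
    if restrict is not None:
        pairs = [p for p in pairs if p.lab_code == restrict]
    return pairs


def _classify_part(
    selected: Sequence[PairId],
    target_payloads: Dict[str, Dict[PairId, object]],
    ref_payloads: Dict[str, Dict[PairId, object]],
    ref_labels: Dict[str, bool],
    knn: KnnConfig,
) -> Tuple[Dict[str, bool], Dict[str, float]]:
    """OR-fused label and risk score for every target encounter."""
    target_ids = sorted(target_payloads)
    fused = {e: False for e in target_ids}
    risk = {e: 0.0 for e in target_ids}
    if selected:
        votes = pair_vote_table_against(selected, target_payloads,
                                        ref_payloads, ref_labels, knn)
        for e in target_ids:
            for pair in selected:
                v = votes[pair][e]
                if v.vote == POSITIVE:
                    fused[e] = True
                if v.vote != ABSTAIN and v.positive_fraction is not None:
                    risk[e] = max(risk[e], v.positive_fraction)
    return fused, risk


def _run_one_dataset(
    dataset: Sequence[cb.EncounterRecord],
    spec: cb.WindowSpec,
    cfg: PipelineConfig,
    split_seed: int,
) -> Dict:
    windowed = [cb.extract_window(r, spec) for r in dataset]
    sel_part, pred_part = cb.split_selection_prediction(
        windowed, cfg.prediction_fraction, split_seed)

    fit_pop = windowed if cfg.all_inpatients_sigma else sel_part
    params = fit_pair_symbolizers(fit_pop)
    sel_payloads = build_payloads(sel_part, params)
    pred_payloads = build_payloads(pred_part, params)
    sel_labels = {r.encounter_id: r.label == cb.AKI for r in sel_part}
    pred_labels = {r.encounter_id: r.label == cb.AKI for r in pred_part}

    knn = KnnConfig(k=cfg.k, tie_vote=cfg.tie_vote)
    candidates = _candidate_pairs(sel_payloads, cfg.pairs_restrict)
    votes = pair_vote_table(candidates, sel_payloads, sel_labels, knn,
                            leave_one_out=not cfg.resubstitution_selection)
    select = sfs if cfg.selection_method == "sfs" else sbs
    result: SelectionResult = select(candidates, votes, sel_labels)

    fused, risk = _classify_part(result.selected, pred_payloads,
                                 sel_payloads, sel_labels, knn)
    ids = sorted(pred_labels)
    y = [pred_labels[e] for e in ids]
    p = [fused[e] for e in ids]
    s = [risk[e] for e in ids]
    m = confusion_metrics(y, p)
    auc = roc_auc(y, s) if (any(y) and not all(y)) else float("nan")
    return {
        "selected_pairs": [list(pr) for pr in result.selected],
        "selection_accuracy": result.accuracy,
        "precision": m.precision, "recall": m.recall, "f1": m.f1,
        "accuracy": m.accuracy, "auc": auc,
        "no_positive_predictions": m.no_positive_predictions,
        "labels": y, "predictions": p, "scores": s,
    }


def run_experiment(
    cfg: PipelineConfig,
    encounters: Optional[pd.DataFrame] = None,
    labs: Optional[pd.DataFrame] = None,
) -> List[MetricsReport]:
    """Run the full pipeline over the configured (horizon, window) grid.

    Inputs come from the provided tables, from ``cfg.data_dir`` CSVs, or from
    the synthetic generator when ``cfg.generator`` is set.  Deterministic
    given the configuration and its seeds.
    """
    if encounters is None or labs is None:
        if cfg.generator is not None:
            cohort = generate_cohort(cfg.generator)
            encounters, labs = cohort.encounters, cohort.labs
            encounters = encounters.assign(
                admission_datetime=pd.to_datetime(encounters["admission_datetime"]),
                discharge_datetime=pd.to_datetime(encounters["discharge_datetime"]),
            )
            labs = labs.assign(lab_datetime=pd.to_datetime(labs["lab_datetime"]))
        else:
            d = Path(cfg.data_dir)
            encounters, labs, _ = read_tables(d / "encounters.csv", d / "labs.csv")

    records, _audit = cb.build_cohort(
        encounters, labs, cfg.creatinine_code,
        delta=cfg.aki_delta, ratio=cfg.aki_ratio,
        pair_window_hours=cfg.pair_window_hours, ratio_cap=cfg.ratio_cap)
    records = cb.filter_cohort(records, cfg.min_age, cfg.min_stay_days)

    if cfg.balanced:
        datasets = cb.balance_by_undersampling(records, cfg.seed)
    else:
        datasets = [list(records)]
    split_seeds = (np.random.SeedSequence(cfg.seed).generate_state(len(datasets))
                   % np.uint32(2 ** 31))

    reports: List[MetricsReport] = []
    for w in cfg.window_days:
        for d in cfg.horizon_days:
            spec = cb.WindowSpec(prediction_days=d, window_length_days=w)
            per_ds = [_run_one_dataset(ds, spec, cfg, int(split_seeds[i]))
                      for i, ds in enumerate(datasets)]
            if cfg.micro_average:
                y = sum((r["labels"] for r in per_ds), [])
                p = sum((r["predictions"] for r in per_ds), [])
                s = sum((r["scores"] for r in per_ds), [])
                m = confusion_metrics(y, p)
                auc = roc_auc(y, s) if (any(y) and not all(y)) else float("nan")
                agg = (m.precision, m.recall, m.f1, m.accuracy, auc)
            else:
                agg = tuple(
                    float(np.nanmean([r[k] for r in per_ds]))
                    for k in ("precision", "recall", "f1", "accuracy", "auc"))
            for r in per_ds:  # trim bulky vectors from the per-dataset record
                for k in ("labels", "predictions", "scores"):
                    r.pop(k)
            reports.append(MetricsReport(
                horizon_days=d, window_days=w,
                precision=agg[0], recall=agg[1], f1=agg[2],
                accuracy=agg[3], auc=agg[4],
                n_datasets=len(per_ds), per_dataset=tuple(per_ds)))
    return reports


def write_reports(reports: Sequence[MetricsReport], outdir) -> None:
    """metrics.json plus one CSV table per window length (rows = horizons)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    payload = [
        {k: getattr(r, k) for k in ("horizon_days", "window_days", "precision",
                                    "recall", "f1", "accuracy", "auc",
                                    "n_datasets")} | {"per_dataset": list(r.per_dataset)}
        for r in reports
    ]
    (out / "metrics.json").write_text(json.dumps(payload, indent=2))
    df = pd.DataFrame([{k: getattr(r, k) for k in (
        "window_days", "horizon_days", "precision", "recall", "f1",
        "accuracy", "auc", "n_datasets")} for r in reports])
    for w, grp in df.groupby("window_days"):
        grp.drop(columns="window_days").sort_values("horizon_days").to_csv(
            out / f"metrics_window_{w}d.csv", index=False)
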