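"""Evaluation metrics: variance accounted for, RMSE, and the
sensitivity/specificity accounting for submovement-event prediction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedVAFError(ValueError):
    pass


def vaf(observed, predicted) -> float:
    """Variance accounted for, percent: 100 * (1 - SSE / SST).

    SST is taken about the mean of the observed series; a prediction equal
    to that mean scores 0% and VAF may be negative for worse predictions.
    """
    y = np.asarray(observed, float).ravel()
    yhat = np.asarray(predicted, float).ravel()
    if y.shape != yhat.shape or len(y) < 2:
        raise ValueError("series must have equal length >= 2")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise UndefinedVAFError("VAF undefined for a constant observed series")
    return float(100.0 * (1.0 - np.sum((y - yhat) ** 2) / sst))


def rmse(observed, predicted) -> float:
    """Root-mean-squared error in the input units.

    For (n, 3) trajectories the per-sample residual is the Euclidean
    distance between observed and predicted points.
    """
    y = np.asarray(observed, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape:
        raise ValueError("series must have equal shapes")
    if y.ndim == 2:
        d2 = np.sum((y - yhat) ** 2, axis=1)
    else:
        d2 = (y - yhat) ** 2
    return float(np.sqrt(np.mean(d2)))


@dataclass
class EventMatchConfig:
    """Matching rule linking a predicted trigger to a decomposed onset.

    tolerance : float
        Maximum |t_pred - t_true| in seconds for a True Positive
        (default 0.10 s, one minimum submovement duration).
    """

    tolerance: float = 0.10

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class EventCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def sensitivity(self) -> float:
        """TP / (TP + FN), percent: corrective submovements correctly predicted."""
        denom = self.tp + self.fn
        return float("nan") if denom == 0 else 100.0 * self.tp / denom

    @property
    def specificity(self) -> float:
        """TN / (TN + FP), percent: absent corrections correctly not predicted."""
        denom = self.tn + self.fp
        return float("nan") if denom == 0 else 100.0 * self.tn / denom


def _match_reach(true_ev, pred_ev, tol) -> tuple[int, int, int]:
    """Greedy one-to-one in-order matching; returns (tp, fp, fn)."""
    true_ev = sorted(true_ev)
    pred_ev = sorted(pred_ev)
    used = [False] * len(pred_ev)
    tp = 0
    for t in true_ev:
        best, best_d = None, tol
        for i, p in enumerate(pred_ev):
            if not used[i] and abs(p - t) <= best_d:
                best, best_d = i, abs(p - t)
        if best is not None:
            used[best] = True
            tp += 1
    fp = used.count(False)
    fn = len(true_ev) - tp
    return tp, fp, fn


def sensitivity_specificity(
    true_events: list[list[float]],
    predicted_events: list[list[float]],
    cfg: EventMatchConfig | None = None,
    n_slots: list[int] | None = None,
) -> EventCounts:
    """Event-level confusion counts over per-reach onset/trigger time lists.

    Predicted triggers within ``cfg.tolerance`` of a decomposed corrective
    onset are True Positives (greedy one-to-one matching); unmatched
    predictions are False Positives and unmatched onsets False Negatives.
    True Negatives are counted per (reach, submovement slot) with neither a
    decomposed nor a predicted correction; ``n_slots`` gives the number of
    slots per reach (default: one more than the larger event count, the
    final submovement of a reach needing no further correction).
    """
    cfg = cfg or EventMatchConfig()
    if len(true_events) != len(predicted_events):
        raise ValueError("need one event list per reach in both arguments")
    counts = EventCounts()
    for r, (te, pe) in enumerate(zip(true_events, predicted_events)):
        tp, fp, fn = _match_reach(te, pe, cfg.tolerance)
        slots = n_slots[r] if n_slots is not None else max(len(te), len(pe)) + 1
        counts.tp += tp
        counts.fp += fp
        counts.fn += fn
        counts.tn += max(slots - tp - fp - fn, 0)
    return counts
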