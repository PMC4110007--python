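"""Causal kinematic features and training labels for the three predictors.

At any instant of a reach the available information is: the start and
target positions, the set of submovements already initiated, and the
current fingertip kinematics. From these, three fixed-order feature
vectors are built:

* initiation (21 values): all 15 pairwise Euclidean distances among
  {start, target, fingertip, current-submovement start, current-submovement
  end, endpoint of all initiated submovements}; two binary in-target flags
  (fingertip now / planned endpoint); remaining time in the current
  submovement, the same normalized by its duration; time since the current
  submovement's onset and its exponential transform e^(-20 t), which
  emphasizes the early part of each submovement.
* amplitude (24 values): the 6 pairwise 3D differences among {start,
  target, current-submovement start, endpoint of all initiated
  submovements}, each normalized by DTTAPS (below), plus the
  sign-preserving 4th root of the 3 velocity and 3 acceleration components.
* duration (12 values): the 10 pairwise distances among {start, target,
  current-submovement start/end, endpoint of all initiated submovements},
  plus the 4th root of speed and acceleration magnitudes.

DTTAPS, the Distance To Target accounted for by All Prior Submovements, is
the distance from the planned endpoint of the prior submovements to the
target (for the first submovement, simply the start-target distance). It
normalizes amplitude features and targets so large- and small-amplitude
submovements train on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .minjerk import Submovement

#: virtual spherical target radius, cm
TARGET_RADIUS = 1.27
#: floor applied to DTTAPS before use as a divisor, cm
DTTAPS_FLOOR = 0.1
#: rate constant of the time-since-onset transform, 1/s
DECAY_RATE = 20.0


class ContextError(ValueError):
    pass


@dataclass
class SubmovementContext:
    """Causal state of a reach at time ``t_now``.

    ``initiated`` holds every submovement begun at or before ``t_now``
    (for first-submovement prediction it is empty and all planned
    positions coincide with the start).
    """

    start: np.ndarray
    target: np.ndarray
    initiated: list[Submovement]
    t_now: float
    fingertip_p: np.ndarray
    fingertip_v: np.ndarray
    fingertip_a: np.ndarray

    @property
    def current(self) -> Submovement | None:
        return self.initiated[-1] if self.initiated else None


def _displacement_at(sub: Submovement, t: float) -> np.ndarray:
    tau = np.clip((t - sub.t0) / sub.D, 0.0, 1.0)
    return sub.A * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def planned_position(start: np.ndarray, subs: list[Submovement], t: float) -> np.ndarray:
    """Position of the noise-free planned trajectory (start + all pulses) at t."""
    pos = np.asarray(start, float).copy()
    for sub in subs:
        pos += _displacement_at(sub, t)
    return pos


def dttaps(ctx: SubmovementContext, k: int) -> float:
    """Distance To Target accounted for by All Prior Submovements, cm.

    For submovement ``k`` (1-based) this is the distance from the endpoint
    implied by submovements 1..k-1 to the target; for k=1 it is the
    start-target distance. Floored at 0.1 cm so it is safe as a divisor.
    """
    if k < 1:
        raise ValueError("submovement index k is 1-based")
    prior = ctx.initiated[: k - 1]
    endpoint = np.asarray(ctx.start, float) + sum((s.A for s in prior), np.zeros(3))
    return max(float(np.linalg.norm(np.asarray(ctx.target, float) - endpoint)), DTTAPS_FLOOR)


def signed_fourth_root(x) -> np.ndarray | float:
    """sign(x) * |x|^(1/4): compresses the dynamic range of v and a while
    preserving direction."""
    x = np.asarray(x, float)
    out = np.sign(x) * np.abs(x) ** 0.25
    return float(out) if out.ndim == 0 else out


def time_decay(t_since_start: float) -> float:
    """e^(-20 t): close to 1 just after a submovement starts, ~0 after 0.3 s."""
    if t_since_start < 0:
        raise ValueError("time since submovement start must be >= 0")
    return float(np.exp(-DECAY_RATE * t_since_start))


# ---------------------------------------------------------------------------
# fixed feature orders

_INIT_POSITIONS = ("start", "target", "fingertip", "cur_start", "cur_end", "end_all")
_AMP_POSITIONS = ("start", "target", "cur_start", "end_all")
_DUR_POSITIONS = ("start", "target", "cur_start", "cur_end", "end_all")

INITIATION_FEATURES = tuple(
    [f"d_{a}_{b}" for a, b in combinations(_INIT_POSITIONS, 2)]
    + [
        "in_target_now",
        "in_target_planned",
        "t_remaining",
        "t_remaining_norm",
        "t_since_onset",
        "t_since_decay",
    ]
)
AMPLITUDE_FEATURES = tuple(
    [f"d{ax}_{a}_{b}" for a, b in combinations(_AMP_POSITIONS, 2) for ax in "xyz"]
    + [f"v4{ax}" for ax in "xyz"]
    + [f"a4{ax}" for ax in "xyz"]
)
DURATION_FEATURES = tuple(
    [f"d_{a}_{b}" for a, b in combinations(_DUR_POSITIONS, 2)] + ["v4mag", "a4mag"]
)


def _positions(ctx: SubmovementContext) -> dict[str, np.ndarray]:
    cur = ctx.current
    if cur is None:
        cur_start = cur_end = np.asarray(ctx.start, float)
    else:
        cur_start = planned_position(ctx.start, ctx.initiated, cur.t0)
        cur_end = planned_position(ctx.start, ctx.initiated, cur.t_end)
    end_all = np.asarray(ctx.start, float) + sum((s.A for s in ctx.initiated), np.zeros(3))
    return {
        "start": np.asarray(ctx.start, float),
        "target": np.asarray(ctx.target, float),
        "fingertip": np.asarray(ctx.fingertip_p, float),
        "cur_start": cur_start,
        "cur_end": cur_end,
        "end_all": end_all,
    }


def build_initiation_features(ctx: SubmovementContext) -> np.ndarray:
    """21-vector of causal features for the initiation-time predictor."""
    if not ctx.initiated:
        raise ContextError("initiation features need at least one initiated submovement")
    pos = _positions(ctx)
    cur = ctx.current
    feats = [np.linalg.norm(pos[b] - pos[a]) for a, b in combinations(_INIT_POSITIONS, 2)]
    t_since = max(ctx.t_now - cur.t0, 0.0)
    remaining = max(cur.t_end - ctx.t_now, 0.0)
    feats += [
        float(np.linalg.norm(pos["fingertip"] - pos["target"]) <= TARGET_RADIUS),
        float(np.linalg.norm(pos["end_all"] - pos["target"]) <= TARGET_RADIUS),
        remaining,
        remaining / cur.D,
        t_since,
        time_decay(t_since),
    ]
    out = np.asarray(feats, float)
    if not np.isfinite(out).all():
        raise ContextError("non-finite initiation features")
    return out


def build_amplitude_features(ctx: SubmovementContext, k: int) -> tuple[np.ndarray, float]:
    """24-vector for the amplitude predictor, plus the DTTAPS normalizer (cm).

    The context holds the submovements initiated *before* the k-th one; its
    amplitude target must be divided by the returned normalizer.
    """
    norm = dttaps(ctx, k)
    pos = _positions(ctx)
    feats = []
    for a, b in combinations(_AMP_POSITIONS, 2):
        feats.extend((pos[b] - pos[a]) / norm)
    feats.extend(signed_fourth_root(ctx.fingertip_v))
    feats.extend(signed_fourth_root(ctx.fingertip_a))
    out = np.asarray(feats, float)
    if not np.isfinite(out).all():
        raise ContextError("non-finite amplitude features")
    return out, norm


def build_duration_features(ctx: SubmovementContext, k: int) -> np.ndarray:
    """12-vector for the duration predictor."""
    pos = _positions(ctx)
    feats = [np.linalg.norm(pos[b] - pos[a]) for a, b in combinations(_DUR_POSITIONS, 2)]
    feats.append(signed_fourth_root(np.linalg.norm(ctx.fingertip_v)))
    feats.append(signed_fourth_root(np.linalg.norm(ctx.fingertip_a)))
    out = np.asarray(feats, float)
    if not np.isfinite(out).all():
        raise ContextError("non-finite duration features")
    return out


# ---------------------------------------------------------------------------
# training tables


def _ctx_at(trial, subs: list[Submovement], t: float) -> SubmovementContext:
    i = int(np.clip(round((t - trial.t.samples[0]) / trial.t.dt), 0, len(trial.t) - 1))
    return SubmovementContext(
        start=trial.start,
        target=trial.target,
        initiated=subs,
        t_now=t,
        fingertip_p=trial.p[i],
        fingertip_v=trial.v[i],
        fingertip_a=trial.a[i],
    )


def build_training_tables(
    dataset,
    decompositions: dict,
    label_mode: str = "step",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-reach feature tables for the three predictors.

    Initiation rows are generated per decomposed submovement window: for
    submovement k the predictor is queried at every 0.01 s timestep from its
    onset to the later of its end and the next onset; the label is 1 at and
    after the next submovement's onset ("step" mode) or only at the onset
    timestep ("impulse" mode), 0 otherwise. Amplitude and duration tables
    gain one row per decomposed submovement, evaluated causally at its
    onset. Metadata columns are prefixed ``meta_``; labels are suffixed
    ``__label``.
    """
    if label_mode not in ("step", "impulse"):
        raise ValueError("label_mode must be 'step' or 'impulse'")
    init_rows, amp_rows, dur_rows = [], [], []
    for trial in dataset.retained:
        dec = decompositions.get(trial.trial_id)
        if dec is None:
            continue
        subs = sorted(dec.submovements, key=lambda s: s.t0)
        K = len(subs)
        t_axis = trial.t.samples
        dt = trial.t.dt
        for k, sub in enumerate(subs):
            t_next = subs[k + 1].t0 if k + 1 < K else None
            # the last window runs through the recorded dwell tail so the
            # quiet at-target state is part of the training distribution;
            # other windows extend at least 0.1 s past the next onset so
            # every correction contributes a full step of positive labels
            if t_next is None:
                w_end = t_axis[-1]
            else:
                w_end = max(sub.t_end, t_next + 0.1)
            m = (t_axis >= sub.t0 - 1e-9) & (t_axis <= w_end + 1e-9)
            onset_seen = False
            for t in t_axis[m]:
                ctx = _ctx_at(trial, subs[: k + 1], t)
                if t_next is None or t < t_next - 1e-9:
                    label = 0.0
                elif label_mode == "step":
                    label = 1.0
                else:
                    label = 0.0 if onset_seen else 1.0
                    onset_seen = True
                init_rows.append(
                    {
                        "meta_trial": trial.trial_id,
                        "meta_k": k + 1,
                        "meta_t": t,
                        "meta_t_next": np.nan if t_next is None else t_next,
                        **dict(zip(INITIATION_FEATURES, build_initiation_features(ctx))),
                        "initiate__label": label,
                    }
                )
        for k, sub in enumerate(subs, start=1):
            ctx = _ctx_at(trial, subs[: k - 1], sub.t0)
            if k == 1:
                # the reach begins at rest; measured kinematics at t0 = 0
                # carry the zero-phase filter's anti-causal smear of the
                # upcoming pulse, which no causal predictor should see
                ctx.fingertip_p = np.asarray(trial.start, float)
                ctx.fingertip_v = np.zeros(3)
                ctx.fingertip_a = np.zeros(3)
            amp_feats, norm = build_amplitude_features(ctx, k)
            amp_rows.append(
                {
                    "meta_trial": trial.trial_id,
                    "meta_k": k,
                    "meta_dttaps": norm,
                    **dict(zip(AMPLITUDE_FEATURES, amp_feats)),
                    "ax__label": sub.A[0] / norm,
                    "ay__label": sub.A[1] / norm,
                    "az__label": sub.A[2] / norm,
                }
            )
            dur_rows.append(
                {
                    "meta_trial": trial.trial_id,
                    "meta_k": k,
                    **dict(zip(DURATION_FEATURES, build_duration_features(ctx, k))),
                    "duration__label": sub.D,
                }
            )
    return (
        pd.DataFrame(init_rows),
        pd.DataFrame(amp_rows),
        pd.DataFrame(dur_rows),
    )


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a training table (neither metadata nor labels)."""
    return [c for c in table.columns if not c.startswith("meta_") and not c.endswith("__label")]


def label_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.endswith("__label")]
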