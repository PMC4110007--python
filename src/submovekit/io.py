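"""Reach-kinematics datasets: CSV loading and preprocessing.

Datasets are long-format CSVs, one row per 100 Hz sample, with a trial
identifier, time, fingertip x/y/z and target x/y/z (cm). Occluded samples
carry NaN fingertip coordinates. Preprocessing resamples each trial to a
uniform grid, interpolates occlusions of at most five samples, excludes
trials occluded for longer (> 50 ms), low-pass filters positions at 10 Hz
with a zero-phase 4th-order Butterworth, and differentiates to velocity
and acceleration with central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .minjerk import TimeGrid

DEFAULT_SCHEMA = {
    "trial": "trial",
    "time": "t",
    "fingertip": ["px", "py", "pz"],
    "target": ["tx", "ty", "tz"],
    "unit_scale": 1.0,  # multiply positions by this to get cm
}


class SchemaError(ValueError):
    pass


class TooShortError(ValueError):
    pass


@dataclass
class ReachTrial:
    """One reach: uniform time grid, fingertip positions and target, cm."""

    trial_id: str
    t: TimeGrid
    p: np.ndarray                      # (n, 3) fingertip position, cm
    start: np.ndarray                  # (3,) cm
    target: np.ndarray                 # (3,) cm
    v: np.ndarray | None = None        # (n, 3) cm/s
    a: np.ndarray | None = None        # (n, 3) cm/s^2
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def duration(self) -> float:
        return self.t.samples[-1] - self.t.samples[0]

    @property
    def distance(self) -> float:
        """Start-to-target Euclidean distance, cm."""
        return float(np.linalg.norm(self.target - self.start))


@dataclass
class Dataset:
    participant_id: str
    trials: list[ReachTrial]
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self):
        return len(self.trials)

    @property
    def retained(self) -> list[ReachTrial]:
        return [tr for tr in self.trials if not tr.excluded]


def load_dataset(path, schema: dict | None = None, participant_id: str | None = None) -> Dataset:
    """Read a long-format kinematics CSV into a raw (unpreprocessed) Dataset.

    Occluded samples are rows whose fingertip coordinates are NaN; they are
    kept in the raw trial and handled by :func:`preprocess`.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty dataset")
    needed = [schema["trial"], schema["time"], *schema["fingertip"], *schema["target"]]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    scale = float(schema["unit_scale"])

    trials = []
    for tid, g in df.groupby(schema["trial"], sort=False):
        t = g[schema["time"]].to_numpy(float)
        p = g[schema["fingertip"]].to_numpy(float) * scale
        tgt = g[schema["target"]].to_numpy(float) * scale
        dt = float(np.median(np.diff(t)))
        grid = TimeGrid(t[0] + dt * np.arange(len(t)), dt)
        target = np.nanmean(tgt, axis=0)
        valid = ~np.isnan(p).any(axis=1)
        start = p[valid][:3].mean(axis=0) if valid.any() else np.full(3, np.nan)
        trials.append(ReachTrial(str(tid), grid, p, start, target))
    return Dataset(participant_id or str(path), trials, {"source": str(path)})


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of runs of True in a boolean mask."""
    runs, i, n = [], 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def preprocess(
    trial: ReachTrial,
    fs: float = 100.0,
    gap_max: int = 5,
    cutoff: float = 10.0,
    filter_order: int = 4,
) -> ReachTrial:
    """Resample, gap-interpolate, filter. Returns the trial (possibly excluded).

    Trials with an occlusion run longer than ``gap_max`` samples (> 50 ms at
    100 Hz) are flagged excluded rather than raising; shorter gaps are filled
    by cubic-spline interpolation before zero-phase Butterworth filtering.
    """
    if trial.duration < 0.5:
        return replace(trial, excluded=True, exclusion_reason="too_short")
    occluded = np.isnan(trial.p).any(axis=1)
    for _, length in _nan_runs(occluded):
        if length > gap_max:
            return replace(trial, excluded=True, exclusion_reason="occlusion>50ms")

    dt = 1.0 / fs
    t_old = trial.t.samples
    grid = TimeGrid.regular(t_old[-1], dt, t_start=t_old[0])
    good = ~occluded
    spline = CubicSpline(t_old[good], trial.p[good])
    p = spline(np.clip(grid.samples, t_old[good][0], t_old[good][-1]))

    sos = signal.butter(filter_order, cutoff, fs=fs, output="sos")
    p = signal.sosfiltfilt(sos, p, axis=0)

    start = p[:3].mean(axis=0)
    return replace(trial, t=grid, p=p, start=start, excluded=False, exclusion_reason=None)


def differentiate(trial: ReachTrial) -> ReachTrial:
    """Populate velocity and acceleration by central differences."""
    if len(trial.t) < 3:
        raise TooShortError(f"trial {trial.trial_id}: need >= 3 samples to differentiate")
    v = np.gradient(trial.p, trial.t.dt, axis=0)
    a = np.gradient(v, trial.t.dt, axis=0)
    return replace(trial, v=v, a=a)


def preprocess_dataset(ds: Dataset, **kwargs) -> Dataset:
    """Preprocess and differentiate every trial; excluded trials stay flagged."""
    out = []
    for tr in ds.trials:
        tr = preprocess(tr, **kwargs)
        if not tr.excluded:
            tr = differentiate(tr)
        out.append(tr)
    log = {
        "n_trials": len(out),
        "n_excluded": sum(t.excluded for t in out),
        "exclusions": {t.trial_id: t.exclusion_reason for t in out if t.excluded},
    }
    return Dataset(ds.participant_id, out, {**ds.provenance, "preprocessing": log})


def export_dataset(ds: Dataset, path, schema: dict | None = None) -> None:
    """Write a Dataset back to the long-format CSV dialect."""
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    frames = []
    for tr in ds.trials:
        frames.append(
            pd.DataFrame(
                {
                    schema["trial"]: tr.trial_id,
                    schema["time"]: tr.t.samples,
                    **dict(zip(schema["fingertip"], tr.p.T)),
                    **dict(zip(schema["target"], np.tile(tr.target, (len(tr.t), 1)).T)),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
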