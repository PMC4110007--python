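"""Closed-loop reach generation from the trained predictors.

The simulator reproduces the prediction loop of the model: the first
submovement is triggered automatically at t = 0 with network-predicted
amplitude and duration; at every subsequent 0.01 s timestep the
initiation network is queried on features derived from the *simulated*
trajectory (so prediction errors propagate, as they would in real
reaching), and each 0.5-crossing adds a corrective submovement with
network-predicted parameters. A reach succeeds on one second of
continuous dwell inside the 1.27 cm target sphere and fails on three
seconds of simulated time or thirty triggered submovements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .features import (
    SubmovementContext,
    TARGET_RADIUS,
    build_amplitude_features,
    build_duration_features,
    build_initiation_features,
)
from .metrics import rmse, vaf
from .minjerk import (
    Submovement,
    TimeGrid,
    position_trajectory,
    superpose,
    superpose_acceleration,
)


@dataclass
class SimulationConfig:
    dt: float = 0.01
    target_radius: float = TARGET_RADIUS
    dwell: float = 1.0
    timeout: float = 3.0
    max_submovements: int = 30
    #: minimum steps after a trigger before the next initiation query
    refractory: int = 1

    def __post_init__(self):
        if min(self.dt, self.target_radius, self.dwell, self.timeout) <= 0:
            raise ValueError("all simulation parameters must be positive")
        if self.max_submovements < 1 or self.refractory < 0:
            raise ValueError("invalid submovement cap or refractory")


@dataclass
class SimResult:
    times: np.ndarray
    trajectory: np.ndarray             # (n, 3) cm
    submovements: list[Submovement]
    success: bool
    end_distance: float                # cm to target center at trajectory end
    failure_reason: str | None = None  # "timeout" or "submovement_cap"

    @property
    def n_submovements(self) -> int:
        return len(self.submovements)


class Policy(Protocol):
    """What the simulator needs: per-state trigger probability and
    parameters of a newly triggered submovement."""

    def trigger_prob(self, ctx: SubmovementContext) -> float: ...
    def amplitude(self, ctx: SubmovementContext, k: int) -> np.ndarray: ...
    def duration(self, ctx: SubmovementContext, k: int) -> float: ...


class AnnPolicy:
    """Adapts a TrainedNets triple to the simulator's Policy protocol."""

    def __init__(self, nets):
        self.nets = nets

    def trigger_prob(self, ctx):
        return self.nets.initiation_prob(build_initiation_features(ctx))

    def amplitude(self, ctx, k):
        row, norm = build_amplitude_features(ctx, k)
        return self.nets.predict_amplitude(row, norm)

    def duration(self, ctx, k):
        return self.nets.predict_duration(build_duration_features(ctx, k))


def _state(subs, start, t, dt):
    grid = TimeGrid(np.array([t, t + dt]), dt)
    p = position_trajectory(subs, start, grid)[0]
    v = superpose(subs, grid)[0]
    a = superpose_acceleration(subs, grid)[0]
    return p, v, a


def simulate_reach(policy, start, target, cfg: SimulationConfig | None = None) -> SimResult:
    """Generate one closed-loop reach from start to target.

    ``policy`` is a Policy (e.g. :class:`AnnPolicy` around trained
    networks). Deterministic: fixed policy and endpoints give an identical
    result.
    """
    cfg = cfg or SimulationConfig()
    start = np.asarray(start, float)
    target = np.asarray(target, float)
    n_steps = int(round(cfg.timeout / cfg.dt))
    dwell_steps = int(round(cfg.dwell / cfg.dt))

    subs: list[Submovement] = []
    ctx0 = SubmovementContext(start, target, [], 0.0, start, np.zeros(3), np.zeros(3))
    subs.append(
        Submovement(t0=0.0, D=policy.duration(ctx0, 1), A=np.asarray(policy.amplitude(ctx0, 1), float))
    )

    times = [0.0]
    traj = [start.copy()]
    in_radius = 1 if np.linalg.norm(start - target) <= cfg.target_radius else 0
    success, reason = False, None
    steps_since_trigger = 0

    for i in range(1, n_steps + 1):
        t = i * cfg.dt
        p, v, a = _state(subs, start, t, cfg.dt)
        times.append(t)
        traj.append(p)
        if np.linalg.norm(p - target) <= cfg.target_radius:
            in_radius += 1
            if in_radius >= dwell_steps:
                success = True
                break
        else:
            in_radius = 0
        steps_since_trigger += 1
        if steps_since_trigger >= cfg.refractory:
            ctx = SubmovementContext(start, target, subs, t, p, v, a)
            if policy.trigger_prob(ctx) > 0.5:
                k = len(subs) + 1
                sub = Submovement(
                    t0=t,
                    D=policy.duration(ctx, k),
                    A=np.asarray(policy.amplitude(ctx, k), float),
                )
                subs.append(sub)
                steps_since_trigger = 0
                if len(subs) >= cfg.max_submovements:
                    reason = "submovement_cap"
                    break
    else:
        reason = "timeout"

    traj = np.asarray(traj)
    return SimResult(
        times=np.asarray(times),
        trajectory=traj,
        submovements=subs,
        success=success,
        end_distance=float(np.linalg.norm(traj[-1] - target)),
        failure_reason=reason,
    )


def evaluate_closed_loop(policy, dataset, cfg: SimulationConfig | None = None) -> dict:
    """Simulate every retained trial's reach and compare to the recording.

    Trajectories are compared on the shared 100 Hz grid over the overlap of
    the two time bases; VAF is pooled over the three dimensions and all
    trials (the observed mean taken over the pooled samples), RMSE is the
    per-sample Euclidean distance pooled the same way.
    """
    cfg = cfg or SimulationConfig()
    results, obs_chunks, sim_chunks = [], [], []
    for trial in dataset.retained:
        sim = simulate_reach(policy, trial.start, trial.target, cfg)
        n = min(len(sim.trajectory), len(trial.p))
        obs_chunks.append(trial.p[:n])
        sim_chunks.append(sim.trajectory[:n])
        results.append(sim)
    obs = np.vstack(obs_chunks)
    pred = np.vstack(sim_chunks)
    end_d = np.array([r.end_distance for r in results])
    failed = np.array([not r.success for r in results])
    report = {
        "n_trials": len(results),
        "target_acquisition_rate": 100.0 * float(np.mean(~failed)),
        "end_distance_mean": float(end_d.mean()),
        "end_distance_sd": float(end_d.std()),
        "end_distance_failed_mean": float(end_d[failed].mean()) if failed.any() else float("nan"),
        "end_distance_failed_sd": float(end_d[failed].std()) if failed.any() else float("nan"),
        "trajectory_vaf": vaf(obs.ravel(), pred.ravel()),
        "trajectory_rmse": rmse(obs, pred),
        "mean_n_submovements": float(np.mean([r.n_submovements for r in results])),
    }
    return {"summary": report, "per_trial": results}
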