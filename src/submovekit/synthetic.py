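"""Synthetic reach corpora with known ground-truth submovements.

The generator emulates the structure of rapid 3D target-directed arm
reaches sampled at 100 Hz: radial reaches of 20-70 cm whose first
submovement deliberately undershoots the target (covering a random
fraction of the start-target distance), followed by 1-4 overlapping
corrective submovements that each cover most of the remaining vector, the
last closing onto the target. Durations follow an amplitude-dependent
rule (larger corrections take longer), onsets are spaced a few hundred
milliseconds apart with overlap, and trajectories carry band-limited
velocity noise plus optional short occlusion gaps. Every reach comes with
its generating submovements, so decomposition, feature building, network
training and the closed loop are all testable against ground truth.

The undershoot-then-correct policy is a deterministic-plus-noise stand-in
for a human corrective policy: it is the mapping the networks must
recover in end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
from scipy import signal

from .features import TARGET_RADIUS
from .io import Dataset, ReachTrial, export_dataset
from .minjerk import Submovement, TimeGrid, position_trajectory, superpose


@dataclass
class GeneratorConfig:
    n_reaches: int = 50
    distance_range: tuple[float, float] = (20.0, 70.0)   # cm
    n_submovements_range: tuple[int, int] = (2, 5)
    #: fraction of the start-target distance covered by the 1st submovement
    undershoot_frac: tuple[float, float] = (0.6, 0.9)
    #: correction policy. "aimed" (default): every correction aims at the
    #: target and misses by a random fraction of the remaining distance —
    #: the stochastic-correction account of human reaching, in which error
    #: is proportional to movement extent. "fractional": each correction
    #: deliberately covers correction_frac of the remaining vector, giving
    #: chains of comparably sized submovements.
    correction_mode: str = "aimed"
    #: relative miss of an aimed correction, fraction of remaining distance
    correction_miss: tuple[float, float] = (0.1, 0.25)
    #: fraction of the remaining vector covered by a "fractional"-mode
    #: correction; near one half, successive corrections carry comparable
    #: velocity power
    correction_frac: tuple[float, float] = (0.4, 0.6)
    #: in aimed mode, corrections stop and the reach closes once the
    #: remaining error is below this, cm
    aimed_close_threshold: float = 1.0
    direction_jitter_deg: float = 3.0
    #: a correction is initiated at this phase of the ongoing submovement's
    #: duration, making correction timing causally learnable from the
    #: current movement state; phases below 1 overlap the predecessor,
    #: phases above 1 are corrections launched after a short pause
    onset_phase: tuple[float, float] = (0.8, 1.3)
    #: absolute bounds on the inter-onset gap, seconds
    inter_onset_gap: tuple[float, float] = (0.2, 1.0)
    #: duration rule D = d0 + d_slope * |A| + N(0, d_noise), clipped to
    #: limits; a 34 cm primary submovement lasts ~0.54 s, matching rapid
    #: human point-to-point reaches
    d0: float = 0.2
    d_slope: float = 0.01             # s/cm
    d_noise: float = 0.04             # s
    duration_limits: tuple[float, float] = (0.1, 1.5)
    #: if set (cm), corrections continue while the remaining error exceeds
    #: it and the submovement count emerges from the reach geometry; None
    #: (default) draws the count uniformly from the range, with the final
    #: submovement closing from whatever remains — which spreads the
    #: closing-correction distances over a wide range
    close_threshold: float | None = None
    #: relative error of the penultimate "close attempt" in reaches of 3+
    #: submovements, as a fraction of the remaining distance; the residual
    #: it leaves behind is closed by a final micro-correction, as in real
    #: reaching where decomposed amplitudes run down to half a centimeter.
    #: None disables the attempt/micro structure (ordinary fractional
    #: corrections all the way to the final exact close).
    close_attempt_err: tuple[float, float] | None = (0.08, 0.2)
    #: sd of the closing error of the final submovement, cm (within target radius)
    closure_noise: float = 0.15
    velocity_noise_sigma: float = 0.5  # cm/s RMS, band-limited below 10 Hz
    noise_cutoff_hz: float = 6.0
    gap_rate: float = 0.05            # fraction of trials given an occlusion gap
    gap_length: tuple[int, int] = (1, 3)  # samples
    fs: float = 100.0
    tail: float = 0.3                 # s of hold at the endpoint
    seed: int = 0

    @classmethod
    def well_separated(cls, **overrides) -> "GeneratorConfig":
        """Corpus of 2-4 temporally well-separated submovements of
        comparable salience, for parameter-recovery studies.

        Corrections cover a smaller fraction of the remaining vector and
        onsets are spaced further apart than the default corpus, so each
        submovement contributes a resolvable share of the velocity signal.
        """
        base = dict(
            n_submovements_range=(2, 4),
            undershoot_frac=(0.6, 0.8),
            # deliberate fractional corrections with f ~ 0.5 make successive
            # submovements comparable in magnitude, so every true submovement
            # carries a resolvable share of the velocity signal; fixed counts
            # (not convergence-driven) so recovery is scored against a known
            # count, and no attempt/micro pair, whose centimeter-scale final
            # correction is below the knee criterion's resolution
            correction_mode="fractional",
            correction_frac=(0.4, 0.6),
            close_threshold=None,
            close_attempt_err=None,
            # corrections late in the ongoing submovement, with a 0.3 s
            # floor on the gap, keep onsets temporally separated
            onset_phase=(0.7, 1.0),
            inter_onset_gap=(0.3, 1.0),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    start: np.ndarray
    target: np.ndarray
    submovements: list[Submovement]

    @property
    def endpoint(self) -> np.ndarray:
        return self.start + sum((s.A for s in self.submovements), np.zeros(3))

    @property
    def on_target(self) -> bool:
        return bool(np.linalg.norm(self.endpoint - self.target) <= TARGET_RADIUS)


def _jitter_direction(vec: np.ndarray, deg: float, rng) -> np.ndarray:
    """Rotate vec by a random small angle about a random perpendicular axis."""
    norm = np.linalg.norm(vec)
    if norm == 0 or deg <= 0:
        return vec
    axis = rng.normal(size=3)
    axis -= axis @ vec / norm**2 * vec
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.normal(0.0, deg))
    # Rodrigues rotation
    return (
        vec * np.cos(ang)
        + np.cross(axis, vec) * np.sin(ang)
        + axis * (axis @ vec) * (1 - np.cos(ang))
    )


def _duration(cfg: GeneratorConfig, amp: float, rng) -> float:
    d = cfg.d0 + cfg.d_slope * amp + rng.normal(0.0, cfg.d_noise)
    return float(np.clip(d, *cfg.duration_limits))


def sample_reach(cfg: GeneratorConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw one reach: start, target, and its true submovement sequence."""
    start = np.zeros(3)
    direction = rng.normal(size=3)
    direction[0] = abs(direction[0]) + 0.5  # radial, roughly forward
    direction /= np.linalg.norm(direction)
    dist = rng.uniform(*cfg.distance_range)
    target = start + dist * direction

    n_max = cfg.n_submovements_range[1]
    if cfg.correction_mode == "aimed" or cfg.close_threshold is not None:
        n_sub = None  # count emerges from convergence
    else:
        n_sub = int(rng.integers(cfg.n_submovements_range[0], n_max + 1))
    subs: list[Submovement] = []
    pos = start.copy()
    t0 = 0.0
    while True:
        remaining = target - pos
        k = len(subs)
        if n_sub is not None:
            closing = k == n_sub - 1
        elif cfg.correction_mode == "aimed":
            closing = k >= 1 and (
                k == n_max - 1 or np.linalg.norm(remaining) <= cfg.aimed_close_threshold
            )
        else:
            closing = k == n_max - 1 or (
                k >= 1 and np.linalg.norm(remaining) <= cfg.close_threshold
            )
        attempt = (
            cfg.close_attempt_err is not None
            and n_sub is not None
            and n_sub >= 3
            and k == n_sub - 2
        )
        if closing:
            A = remaining + rng.normal(0.0, cfg.closure_noise, size=3)
            err = np.linalg.norm(A - remaining)
            if err > 0.8 * TARGET_RADIUS:  # keep the closing error inside the target
                A = remaining + (A - remaining) * 0.8 * TARGET_RADIUS / err
        elif k == 0:
            frac = rng.uniform(*cfg.undershoot_frac)
            A = _jitter_direction(frac * remaining, cfg.direction_jitter_deg, rng)
        elif cfg.correction_mode == "aimed" or attempt:
            # aimed correction: covers the remaining vector up to a miss
            # proportional to the remaining distance
            band = cfg.close_attempt_err if attempt else cfg.correction_miss
            miss = rng.normal(size=3)
            miss *= rng.uniform(*band) * np.linalg.norm(remaining) / np.linalg.norm(miss)
            A = remaining + miss
        else:
            frac = rng.uniform(*cfg.correction_frac)
            A = _jitter_direction(frac * remaining, cfg.direction_jitter_deg, rng)
        sub = Submovement(t0=t0, D=_duration(cfg, float(np.linalg.norm(A)), rng), A=A)
        subs.append(sub)
        pos = pos + A
        if closing:
            break
        gap = rng.uniform(*cfg.onset_phase) * sub.D
        t0 += float(np.clip(gap, *cfg.inter_onset_gap))
    return GroundTruth(start, target, subs)


def _bandlimited_noise(n: int, sigma: float, cfg: GeneratorConfig, rng) -> np.ndarray:
    """(n, 3) velocity noise, cm/s, low-passed below the preprocessing cutoff."""
    if sigma <= 0:
        return np.zeros((n, 3))
    white = rng.normal(size=(max(n, 64), 3))
    sos = signal.butter(4, cfg.noise_cutoff_hz, fs=cfg.fs, output="sos")
    filt = signal.sosfiltfilt(sos, white, axis=0)[:n]
    return filt / np.sqrt(np.mean(filt**2)) * sigma


def render_trial(
    truth: GroundTruth, cfg: GeneratorConfig, rng: np.random.Generator, trial_id: str = "0"
) -> ReachTrial:
    """Render a reach at 100 Hz: closed-form positions plus integrated
    velocity noise, with an occlusion gap injected at the configured rate."""
    dt = 1.0 / cfg.fs
    t_end = max(s.t_end for s in truth.submovements) + cfg.tail
    grid = TimeGrid.regular(round(t_end / dt) * dt, dt)
    p = position_trajectory(truth.submovements, truth.start, grid)
    v = superpose(truth.submovements, grid)
    noise_v = _bandlimited_noise(len(grid), cfg.velocity_noise_sigma, cfg, rng)
    p = p + np.cumsum(noise_v, axis=0) * dt
    v = v + noise_v
    if rng.uniform() < cfg.gap_rate:
        length = int(rng.integers(cfg.gap_length[0], cfg.gap_length[1] + 1))
        i0 = int(rng.integers(3, max(len(grid) - length - 3, 4)))
        p[i0 : i0 + length] = np.nan
    trial = ReachTrial(
        trial_id=trial_id,
        t=grid,
        p=p,
        start=truth.start.copy(),
        target=truth.target.copy(),
        v=v,
    )
    return trial


def generate_corpus(cfg: GeneratorConfig | None = None) -> tuple[Dataset, list[GroundTruth]]:
    """A seeded corpus of rendered reaches with their ground truth."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    trials, truths = [], []
    for i in range(cfg.n_reaches):
        truth = sample_reach(cfg, rng)
        trials.append(render_trial(truth, cfg, rng, trial_id=f"r{i:04d}"))
        truths.append(truth)
    ds = Dataset("synthetic", trials, {"generator_seed": cfg.seed, "n_reaches": cfg.n_reaches})
    return ds, truths


def export_corpus(ds: Dataset, truths: list[GroundTruth], path, truth_path=None) -> None:
    """Write the corpus CSV plus a ground-truth JSON sidecar."""
    export_dataset(ds, path)
    if truth_path is not None:
        doc = [
            {
                "trial_id": tr.trial_id,
                "start": truth.start.tolist(),
                "target": truth.target.tolist(),
                "submovements": [list(s.as_tuple()) for s in truth.submovements],
                "on_target": truth.on_target,
            }
            for tr, truth in zip(ds.trials, truths)
        ]
        with open(truth_path, "w") as fh:
            json.dump(doc, fh, indent=1)


def load_truth(truth_path) -> list[GroundTruth]:
    with open(truth_path) as fh:
        doc = json.load(fh)
    return [
        GroundTruth(
            np.asarray(d["start"]),
            np.asarray(d["target"]),
            [Submovement(t0, D, np.array([ax, ay, az])) for t0, D, ax, ay, az in d["submovements"]],
        )
        for d in doc
    ]
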