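"""Decompose a measured reach into overlapping minimum-jerk submovements.

For each candidate submovement count N the 5N parameters (t0, D, Ax, Ay, Az
per submovement) are fitted by bounded nonlinear least squares so that the
superposed minimum-jerk velocities match the measured 3D velocity. The cost
is the integrated squared velocity error plus a penalty on simultaneous
opposing submovements,

    J = sum_d int (v_rec,d - v_meas,d)^2 dt
        + lam * sum_d int ( sum_j |v_j,d| - |sum_j v_j,d| ) dt,

whose penalty integrand is zero wherever overlapping submovements agree in
sign and positive where they oppose. Because the number of submovements is
unknown a priori, the fit is repeated over a range of N (warm-starting N+1
from the N-submovement fit) and the optimal N is the knee of the cost curve:
after min-max normalizing both axes, the point furthest below the descending
(0,1)-(1,0) diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io import ReachTrial
from .metrics import vaf
from .minjerk import D_MIN, Submovement, TimeGrid, superpose


class FitFailureError(RuntimeError):
    pass


@dataclass
class DecompositionConfig:
    n_range: tuple[int, ...] = tuple(range(1, 11))
    d_min: float = D_MIN
    d_max: float = 2.0
    #: overlap-penalty weight, relative to the trial's RMS speed (see
    #: reconstruction_cost); >= 0.
    lambda_overlap: float = 0.01
    n_restarts: int = 5
    seed: int = 0
    tol: float = 1e-6
    #: initial duration guess for newly introduced submovements, seconds
    d_init: float = 0.3

    def __post_init__(self):
        self.n_range = tuple(sorted(self.n_range))
        if not self.n_range or self.n_range[0] < 1:
            raise ValueError("n_range must be non-empty with counts >= 1")
        if self.lambda_overlap < 0:
            raise ValueError("lambda_overlap must be >= 0")


@dataclass
class DecompositionResult:
    trial_id: str
    n_range: tuple[int, ...]
    cost_curve: np.ndarray                 # J(N) per candidate
    fits: dict                             # N -> list[Submovement]
    n_star: int
    recon_vaf: float                       # % VAF of the selected reconstruction

    @property
    def submovements(self) -> list[Submovement]:
        return self.fits[self.n_star]


# ---------------------------------------------------------------------------
# cost


def _velocities(params: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Per-submovement velocities, shape (N, n, 3), from a flat 5N vector."""
    p = params.reshape(-1, 5)
    t = grid.samples
    out = np.zeros((len(p), len(t), 3))
    for j, (t0, D, *A) in enumerate(p):
        tau = np.clip((t - t0) / D, 0.0, 1.0)
        mask = ((t - t0) >= 0.0) & ((t - t0) <= D)
        shape = 30.0 * tau**2 * (1.0 - tau) ** 2 * mask / D
        out[j] = np.outer(shape, A)
    return out


def _velocities_with_grads(params: np.ndarray, grid: TimeGrid):
    """Velocities plus their partials w.r.t. (t0, D, A) per submovement.

    Returns vj (N,n,3), dv_dt0 (N,n,3), dv_dD (N,n,3), shape (N,n) where
    shape is the common scalar profile g(tau)/D so that dv/dA_d = shape.
    """
    p = params.reshape(-1, 5)
    t = grid.samples
    N, n = len(p), len(t)
    vj = np.zeros((N, n, 3))
    dt0 = np.zeros((N, n, 3))
    dD = np.zeros((N, n, 3))
    shp = np.zeros((N, n))
    for j, (t0, D, *A) in enumerate(p):
        A = np.asarray(A)
        tau = np.clip((t - t0) / D, 0.0, 1.0)
        mask = ((t - t0) >= 0.0) & ((t - t0) <= D)
        g = 30.0 * tau**2 * (1.0 - tau) ** 2 * mask
        gp = 60.0 * tau * (1.0 - tau) * (1.0 - 2.0 * tau) * mask
        shp[j] = g / D
        vj[j] = np.outer(shp[j], A)
        dt0[j] = np.outer(-gp / D**2, A)
        dD[j] = np.outer(-(g + tau * gp) / D**2, A)
    return vj, dt0, dD, shp


def _penalty_integrand(vj: np.ndarray) -> np.ndarray:
    """(n, 3) opposing-overlap integrand: sum_j |v_j,d| - |sum_j v_j,d| >= 0."""
    return np.abs(vj).sum(axis=0) - np.abs(vj.sum(axis=0))


def _lambda_effective(trial: ReachTrial, cfg: DecompositionConfig) -> float:
    # scaled by RMS speed so both cost terms carry (cm/s)^2 units
    return cfg.lambda_overlap * float(np.sqrt(np.mean(trial.v**2) * 3))


def reconstruction_cost(
    subs: list[Submovement], trial: ReachTrial, cfg: DecompositionConfig
) -> float:
    """The scalar cost J of a candidate submovement set against a trial."""
    params = np.concatenate([s.as_tuple() for s in subs]) if subs else np.empty(0)
    return _cost_from_params(params, trial, cfg)


def _cost_from_params(params, trial, cfg) -> float:
    dt = trial.t.dt
    if params.size == 0:
        return float(np.sum(trial.v**2) * dt)
    vj = _velocities(params, trial.t)
    err = vj.sum(axis=0) - trial.v
    lam = _lambda_effective(trial, cfg)
    return float(np.sum(err**2) * dt + lam * np.sum(_penalty_integrand(vj)) * dt)


def _residuals(params: np.ndarray, trial: ReachTrial, lam: float) -> np.ndarray:
    dt = trial.t.dt
    vj = _velocities(params, trial.t)
    err = (vj.sum(axis=0) - trial.v) * np.sqrt(dt)
    pen = np.sqrt(lam * dt * np.maximum(_penalty_integrand(vj), 0.0) + 1e-15)
    return np.concatenate([err.ravel(), pen.ravel()])


def _jacobian(params: np.ndarray, trial: ReachTrial, lam: float) -> np.ndarray:
    """Analytic Jacobian of _residuals, shape (2*n*3, 5N)."""
    dt = trial.t.dt
    vj, dt0, dD, shp = _velocities_with_grads(params, trial.t)
    N, n, _ = vj.shape
    vsum = vj.sum(axis=0)
    pen_val = np.sqrt(lam * dt * np.maximum(_penalty_integrand(vj), 0.0) + 1e-15)
    # d pen / d v_j,d = lam*dt*(sign(v_j,d) - sign(vsum_d)) / (2 pen)
    sgn_sum = np.sign(vsum)
    J = np.zeros((2 * n * 3, 5 * N))
    sq = np.sqrt(dt)
    for j in range(N):
        pen_fac = lam * dt * (np.sign(vj[j]) - sgn_sum) / (2.0 * pen_val)  # (n,3)
        for col, dv in ((5 * j, dt0[j]), (5 * j + 1, dD[j])):
            J[: n * 3, col] = (dv * sq).ravel()
            J[n * 3 :, col] = (pen_fac * dv).ravel()
        for d in range(3):
            dv = np.zeros((n, 3))
            dv[:, d] = shp[j]
            J[: n * 3, 5 * j + 2 + d] = (dv * sq).ravel()
            J[n * 3 :, 5 * j + 2 + d] = (pen_fac * dv).ravel()
    return J


# ---------------------------------------------------------------------------
# fitting


def _projected_amplitude(v: np.ndarray, grid: TimeGrid, t0: float, D: float) -> np.ndarray:
    """Least-squares amplitude of a (t0, D) pulse against a velocity field."""
    t = grid.samples
    tau = np.clip((t - t0) / D, 0.0, 1.0)
    mask = ((t - t0) >= 0.0) & ((t - t0) <= D)
    shape = 30.0 * tau**2 * (1.0 - tau) ** 2 * mask / D
    denom = float(shape @ shape)
    if denom == 0:
        return np.zeros(3)
    return v.T @ shape / denom


def _fit_single_pulse(residual: np.ndarray, trial: ReachTrial, cfg: DecompositionConfig) -> np.ndarray:
    """Best single (t0, D, A) pulse against a residual velocity field."""
    t = trial.t.samples
    t_peak = t[int(np.argmax(np.linalg.norm(residual, axis=1)))]
    best, best_sse = None, np.inf
    # coarse search over duration; amplitude is linear-optimal per (t0, D)
    for D in (0.15, 0.3, 0.5, 0.8):
        t0 = float(np.clip(t_peak - D / 2, 0.0, t[-1] - cfg.d_min))
        A = _projected_amplitude(residual, trial.t, t0, D)
        sse = float(np.sum((_velocities(np.array([t0, D, *A]), trial.t)[0] - residual) ** 2))
        if sse < best_sse:
            best, best_sse = np.array([t0, D, *A]), sse
    return best


def _greedy_init(trial: ReachTrial, n: int, cfg: DecompositionConfig) -> np.ndarray:
    """Matching-pursuit initialization: repeatedly fit the best single
    pulse to the residual velocity and deflate."""
    residual = trial.v.copy()
    params = []
    for _ in range(n):
        pulse = _fit_single_pulse(residual, trial, cfg)
        params.extend(pulse)
        residual = residual - _velocities(pulse, trial.t)[0]
    return np.array(params)


def _bounds(trial: ReachTrial, n: int, cfg: DecompositionConfig):
    t_end = trial.t.samples[-1]
    a_max = max(2.0 * trial.distance, 20.0)
    lo = np.tile([0.0, cfg.d_min, -a_max, -a_max, -a_max], n)
    hi = np.tile([max(t_end - cfg.d_min, 1e-3), cfg.d_max, a_max, a_max, a_max], n)
    return lo, hi


def _fit_once(x0, trial, cfg) -> tuple[np.ndarray, float]:
    n = len(x0) // 5
    lo, hi = _bounds(trial, n, cfg)
    x0 = np.clip(x0, lo, hi)
    lam = _lambda_effective(trial, cfg)
    res = least_squares(
        _residuals,
        x0,
        jac=_jacobian,
        bounds=(lo, hi),
        args=(trial, lam),
        method="trf",
        ftol=cfg.tol,
        xtol=cfg.tol,
    )
    if not np.isfinite(res.x).all():
        raise FitFailureError(f"trial {trial.trial_id}: optimizer returned non-finite parameters")
    return res.x, _cost_from_params(res.x, trial, cfg)


def _params_to_subs(params: np.ndarray) -> list[Submovement]:
    subs = [
        Submovement(t0=max(p[0], 0.0), D=max(p[1], D_MIN), A=p[2:5])
        for p in params.reshape(-1, 5)
    ]
    return sorted(subs, key=lambda s: s.t0)


def decompose_fixed_n(
    trial: ReachTrial,
    N: int,
    cfg: DecompositionConfig | None = None,
    x0: np.ndarray | None = None,
) -> tuple[list[Submovement], float]:
    """Fit exactly N submovements; best of ``n_restarts`` multi-starts.

    ``x0`` adds one extra warm-start candidate (used by decompose_reach for
    nested initialization from the N-1 fit).
    """
    cfg = cfg or DecompositionConfig()
    if trial.v is None:
        raise ValueError("trial must be differentiated before decomposition")
    rng = np.random.default_rng([cfg.seed, N, len(trial.t)])
    t_end = trial.t.samples[-1]

    candidates = [_greedy_init(trial, N, cfg)]
    if x0 is not None:
        candidates.append(np.asarray(x0, float))
    a_scale = 0.05 * max(trial.distance, 1.0)
    for _ in range(max(cfg.n_restarts - 1, 0)):
        jitter = candidates[0].copy().reshape(-1, 5)
        jitter[:, 0] += rng.normal(0, 0.1 * t_end, size=N)
        jitter[:, 1] *= rng.uniform(0.7, 1.8, size=N)
        # additive component lets zero-amplitude inits escape the saddle
        jitter[:, 2:] = jitter[:, 2:] * rng.uniform(0.7, 1.3, size=(N, 3)) + rng.normal(
            0, a_scale, size=(N, 3)
        )
        candidates.append(jitter.ravel())

    best_x, best_cost, last_err = None, np.inf, None
    for x0_i in candidates:
        try:
            x, cost = _fit_once(x0_i, trial, cfg)
        except FitFailureError as err:  # pragma: no cover - rare
            last_err = err
            continue
        if cost < best_cost:
            best_x, best_cost = x, cost
    if best_x is None:  # pragma: no cover
        raise FitFailureError(f"trial {trial.trial_id}: all {len(candidates)} starts failed") from last_err
    return _params_to_subs(best_x), best_cost


def select_optimal_n(cost_curve: np.ndarray, n_range: tuple[int, ...]) -> int:
    """Knee of the cost-per-N curve: furthest point below the normalized diagonal.

    Both axes are min-max normalized to [0, 1]; the distance of each point
    below the descending diagonal from (0, 1) to (1, 0) is proportional to
    1 - x - y. Ties (including a degenerate straight-line curve) break toward
    the smallest N.
    """
    J = np.asarray(cost_curve, float)
    if len(J) != len(n_range) or len(J) < 1:
        raise ValueError("cost_curve and n_range must align")
    if len(J) == 1:
        return n_range[0]
    span = J.max() - J.min()
    if span <= 0:
        warnings.warn("constant cost curve; selecting smallest N", stacklevel=2)
        return n_range[0]
    x = (np.asarray(n_range, float) - n_range[0]) / (n_range[-1] - n_range[0])
    y = (J - J.min()) / span
    dist = 1.0 - x - y
    # ties (within float roundoff) break toward the smallest N
    best = int(np.flatnonzero(dist >= dist.max() - 1e-9)[0])
    return n_range[best]


def decompose_reach(trial: ReachTrial, cfg: DecompositionConfig | None = None) -> DecompositionResult:
    """Fit every candidate N, select the knee, report reconstruction quality.

    N+1 is warm-started from the N fit plus one new submovement at the peak
    of the residual speed, so the cost curve is non-increasing in N.
    """
    cfg = cfg or DecompositionConfig()
    fits, costs = {}, []
    prev_params = None
    for N in cfg.n_range:
        x0 = None
        if prev_params is not None and len(prev_params) // 5 == N - 1:
            x0 = _warm_start(prev_params, trial, cfg)
        subs, cost = decompose_fixed_n(trial, N, cfg, x0=x0)
        # nested-model guarantee: adding a zero-amplitude submovement can
        # never raise the cost, so never accept a worse fit than N-1's
        if costs and cost > costs[-1] and x0 is not None:
            x, cost_ws = _fit_once(x0, trial, cfg)
            if cost_ws < cost:
                subs, cost = _params_to_subs(x), cost_ws
            cost = min(cost, costs[-1])
        fits[N] = subs
        costs.append(cost)
        prev_params = np.concatenate([s.as_tuple() for s in subs])
    cost_curve = np.array(costs)
    n_star = select_optimal_n(cost_curve, cfg.n_range)
    grid = trial.t
    recon = superpose(fits[n_star], grid)
    recon_vaf = vaf(trial.v.ravel(), recon.ravel())
    return DecompositionResult(trial.trial_id, cfg.n_range, cost_curve, fits, n_star, recon_vaf)


def _warm_start(prev_params: np.ndarray, trial: ReachTrial, cfg: DecompositionConfig) -> np.ndarray:
    residual = trial.v - _velocities(prev_params, trial.t).sum(axis=0)
    t = trial.t.samples
    t_peak = t[int(np.argmax(np.linalg.norm(residual, axis=1)))]
    t0 = float(np.clip(t_peak - cfg.d_init / 2, 0.0, t[-1] - cfg.d_min))
    A = _projected_amplitude(residual, trial.t, t0, cfg.d_init)
    return np.concatenate([prev_params, [t0, cfg.d_init, *A]])


def decompose_dataset(ds, cfg: DecompositionConfig | None = None) -> dict:
    """Decompose every retained trial; returns {trial_id: DecompositionResult}."""
    cfg = cfg or DecompositionConfig()
    return {tr.trial_id: decompose_reach(tr, cfg) for tr in ds.retained}
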