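"""Gamma pupil response function and the three-predictor pupil GLM.

The pupil time course on each trial is modelled as a linear combination of
three predictors convolved with a pupil response function (PRF): impulses
at stimulus onset and offset (transient constriction/dilation) and a boxcar
spanning the 6 s presentation (sustained luminance response).  Each
predictor is normalized to unit integral before convolution, so the fitted
β-weights are in mm.

The PRF is a shifted Gamma density

    h(t) = ((t - δ)/τ)^(n-1) · exp(-(t - δ)/τ) / (τ · (n-1)!)   for t ≥ δ

with integer filter count n ∈ [1, 8], change rate τ ∈ [10, 800] ms and
delay δ ∈ [0, 200] ms.  h integrates to 1 and peaks at δ + (n-1)·τ.

Fitting is two-stage, as in the underlying analysis: the PRF is estimated
once per participant from the grand-average trace across conditions, then
frozen while per-condition β-weights are estimated by (validity-weighted)
ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "PRFParams",
    "GLMFit",
    "EpochAverage",
    "gamma_prf",
    "build_design",
    "fit_prf",
    "fit_condition_betas",
    "average_epochs",
    "difference_trace",
    "window_mean",
]

N_BOUNDS = (1, 8)
TAU_BOUNDS_MS = (10.0, 800.0)
DELTA_BOUNDS_MS = (0.0, 200.0)


@dataclass(frozen=True)
class PRFParams:
    """Shifted-Gamma PRF parameters: n (count), tau and delta in ms."""

    n: int
    tau_ms: float
    delta_ms: float

    def __post_init__(self):
        if not (N_BOUNDS[0] <= self.n <= N_BOUNDS[1]) or self.n != int(self.n):
            raise ValueError(f"n must be an integer in {N_BOUNDS}")
        if not (TAU_BOUNDS_MS[0] <= self.tau_ms <= TAU_BOUNDS_MS[1]):
            raise ValueError(f"tau must lie in {TAU_BOUNDS_MS} ms")
        if not (DELTA_BOUNDS_MS[0] <= self.delta_ms <= DELTA_BOUNDS_MS[1]):
            raise ValueError(f"delta must lie in {DELTA_BOUNDS_MS} ms")

    @property
    def mode_s(self) -> float:
        """Time-to-peak of the kernel, seconds."""
        return (self.delta_ms + (self.n - 1) * self.tau_ms) / 1000.0


@dataclass
class GLMFit:
    beta_onset: float
    beta_offset: float
    beta_sustained: float
    r_squared: float
    degenerate: bool = False

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta_onset, self.beta_offset, self.beta_sustained])


@dataclass
class EpochAverage:
    """Condition-average time course on the epoch grid."""

    rel_time: np.ndarray  # s from stimulus onset
    pupil: np.ndarray  # mm (baseline-corrected)
    valid: np.ndarray  # bool
    n_epochs: int = 0


def gamma_prf(t_grid: np.ndarray, params: PRFParams) -> np.ndarray:
    """Evaluate the shifted-Gamma kernel on ``t_grid`` (seconds).

    Zero for t < delta (causality); unit mass over an unbounded grid.
    """
    tau = params.tau_ms / 1000.0
    delta = params.delta_ms / 1000.0
    t = np.asarray(t_grid, float)
    s = np.maximum(t - delta, 0.0) / tau
    with np.errstate(invalid="ignore"):
        h = s ** (params.n - 1) * np.exp(-s) / (tau * math.factorial(params.n - 1))
    h[t < delta] = 0.0
    return h


def gamma_prf_continuous(t_grid: np.ndarray, n: float, tau_ms: float,
                         delta_ms: float) -> np.ndarray:
    """Gamma-function generalization of the kernel to non-integer filter
    counts ((n-1)! -> Gamma(n)); provided as a non-default alternative and
    identical to :func:`gamma_prf` at integer n."""
    from scipy.special import gamma as gamma_fn

    if n < 1 or not (TAU_BOUNDS_MS[0] <= tau_ms <= TAU_BOUNDS_MS[1]) or not (
        DELTA_BOUNDS_MS[0] <= delta_ms <= DELTA_BOUNDS_MS[1]
    ):
        raise ValueError("parameters out of bounds")
    tau = tau_ms / 1000.0
    delta = delta_ms / 1000.0
    t = np.asarray(t_grid, float)
    s = np.maximum(t - delta, 0.0) / tau
    with np.errstate(invalid="ignore"):
        h = s ** (n - 1) * np.exp(-s) / (tau * gamma_fn(n))
    h[t < delta] = 0.0
    return h


def build_design(
    trial_timing: tuple[float, float],
    dt: float,
    prf: PRFParams,
    t_start: float = -1.0,
    t_end: float = 7.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix on the epoch grid: onset, offset and sustained regressors.

    ``trial_timing`` is (onset, offset) in epoch-relative seconds (onset is
    normally 0).  Each predictor has unit integral before convolution with
    the PRF: the impulses are 1/dt at a single sample, the boxcar is
    1/duration over the presentation.
    """
    onset, offset = trial_timing
    if offset <= onset:
        raise ValueError("offset must follow onset")
    n = int(round((t_end - t_start) / dt)) + 1
    grid = t_start + np.arange(n) * dt
    onset_p = np.zeros(n)
    offset_p = np.zeros(n)
    sustained_p = np.zeros(n)
    # index-based placement: immune to 1e-14 jitter on the time grid
    i_on = int(np.argmin(np.abs(grid - onset)))
    i_off = int(np.argmin(np.abs(grid - offset)))
    onset_p[i_on] = 1.0 / dt
    offset_p[i_off] = 1.0 / dt
    dur = offset - onset
    sustained_p[i_on:i_off] = 1.0 / dur
    kernel = gamma_prf(np.arange(n) * dt, prf)
    mass = kernel.sum() * dt  # renormalize the sampled kernel to unit mass
    if mass > 0:              # (matters only when tau is near the grid step)
        kernel = kernel / mass
    X = np.empty((n, 3))
    for k, p in enumerate((onset_p, offset_p, sustained_p)):
        X[:, k] = np.convolve(p, kernel)[:n] * dt
    return grid, X


def _weighted_ols(X: np.ndarray, y: np.ndarray, valid: np.ndarray) -> GLMFit:
    Xv, yv = X[valid], y[valid]
    if Xv.shape[0] < X.shape[1]:
        raise ValueError("too few valid samples for the GLM")
    if np.linalg.matrix_rank(Xv) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
    resid = yv - Xv @ beta
    sse = float(resid @ resid)
    sst = float(yv @ yv)  # uncentered: traces are baseline-corrected
    degenerate = sst == 0.0
    r2 = 0.0 if degenerate else max(0.0, 1.0 - sse / sst)
    return GLMFit(*beta, r_squared=r2, degenerate=degenerate)


def fit_condition_betas(trace: EpochAverage, design: np.ndarray,
                        design_grid: np.ndarray | None = None) -> GLMFit:
    """Validity-weighted OLS of a condition-average trace on a fixed design."""
    if design_grid is not None and (
        len(design_grid) != len(trace.rel_time)
        or not np.allclose(design_grid, trace.rel_time, atol=1e-9)
    ):
        raise ValueError("design grid does not match the trace grid")
    if design.shape[0] != len(trace.pupil):
        raise ValueError("design grid does not match the trace grid")
    return _weighted_ols(design, np.asarray(trace.pupil, float),
                         np.asarray(trace.valid, bool))


def fit_prf(
    mean_trace: EpochAverage,
    trial_timing: tuple[float, float] = (0.0, 6.0),
    n_starts: int = 5,
    seed: int = 0,
    n_bounds: tuple[int, int] = N_BOUNDS,
    tau_bounds: tuple[float, float] = TAU_BOUNDS_MS,
    delta_bounds: tuple[float, float] = DELTA_BOUNDS_MS,
) -> tuple[PRFParams, GLMFit]:
    """Best-fitting PRF for a participant's grand-average trace.

    n is enumerated over its integer range; for each n, (τ, δ) are found by
    bounded continuous optimization from ``n_starts`` quasi-random starts;
    β-weights are profiled out by OLS inside the objective.  Returns the
    global best parameters and the corresponding fit.
    """
    y = np.asarray(mean_trace.pupil, float)
    valid = np.asarray(mean_trace.valid, bool)
    if not valid.any():
        raise ValueError("all samples invalid: cannot fit the PRF")
    t = np.asarray(mean_trace.rel_time, float)
    dt = float(np.median(np.diff(t)))
    t0, t1 = float(t[0]), float(t[-1])

    if not np.any(y[valid] != 0.0):
        params = PRFParams(1, tau_bounds[0], delta_bounds[0])
        return params, GLMFit(0.0, 0.0, 0.0, 0.0, degenerate=True)

    rng = np.random.default_rng(seed)
    starts = np.column_stack([
        rng.uniform(tau_bounds[0], tau_bounds[1], n_starts),
        rng.uniform(delta_bounds[0], delta_bounds[1], n_starts),
    ])
    starts[0] = (250.0, 100.0)  # canonical start

    def sse_for(n: int, tau: float, delta: float) -> float:
        prf = PRFParams(n, float(np.clip(tau, *tau_bounds)), float(np.clip(delta, *delta_bounds)))
        _, X = build_design(trial_timing, dt, prf, t_start=t0, t_end=t1)
        Xv, yv = X[valid], y[valid]
        beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
        r = yv - Xv @ beta
        return float(r @ r)

    best = (math.inf, None)
    for n in range(n_bounds[0], n_bounds[1] + 1):
        for x0 in starts:
            res = optimize.minimize(
                lambda x: sse_for(n, x[0], x[1]), x0,
                method="Nelder-Mead",
                options={"xatol": 0.05, "fatol": 1e-12, "maxiter": 400},
            )
            tau = float(np.clip(res.x[0], *tau_bounds))
            delta = float(np.clip(res.x[1], *delta_bounds))
            if res.fun < best[0]:
                best = (res.fun, PRFParams(n, tau, delta))
    params = best[1]
    _, X = build_design(trial_timing, dt, params, t_start=t0, t_end=t1)
    fit = _weighted_ols(X, y, valid)
    return params, fit


def average_epochs(epochs) -> EpochAverage:
    """Pointwise validity-weighted mean across epochs sharing a grid."""
    if not epochs:
        raise ValueError("no epochs to average")
    t = np.asarray(epochs[0].rel_time, float)
    P = np.stack([np.asarray(e.pupil, float) for e in epochs])
    V = np.stack([np.asarray(e.valid, bool) for e in epochs])
    for e in epochs:
        if len(e.rel_time) != len(t) or not np.allclose(e.rel_time, t, atol=1e-9):
            raise ValueError("epochs are not on a common grid")
    w = V.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(w > 0, np.where(V, P, 0.0).sum(axis=0) / np.maximum(w, 1), np.nan)
    return EpochAverage(rel_time=t, pupil=mean, valid=w > 0, n_epochs=len(epochs))


def difference_trace(dark: EpochAverage, light: EpochAverage) -> EpochAverage:
    """Dark-minus-light pointwise difference: the net luminance response."""
    if len(dark.rel_time) != len(light.rel_time) or not np.allclose(
        dark.rel_time, light.rel_time, atol=1e-9
    ):
        raise ValueError("dark and light averages are on different grids")
    valid = np.asarray(dark.valid, bool) & np.asarray(light.valid, bool)
    diff = np.where(valid, dark.pupil - light.pupil, np.nan)
    return EpochAverage(rel_time=dark.rel_time, pupil=diff, valid=valid,
                        n_epochs=min(dark.n_epochs, light.n_epochs))


def window_mean(trace: EpochAverage, start: float = 1.0, end: float = 6.0) -> float:
    """Validity-weighted mean pupil size over [start, end) seconds from onset."""
    t = np.asarray(trace.rel_time, float)
    sel = (t >= start) & (t < end) & np.asarray(trace.valid, bool)
    if not sel.any():
        raise ValueError(f"no valid samples in window [{start}, {end}) s")
    return float(np.mean(np.asarray(trace.pupil, float)[sel]))
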