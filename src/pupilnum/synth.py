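"""Forward simulation of pupillometry sessions and 2AFC numerosity judgments.

Pupil traces are generated by the same forward model the analysis assumes:
three unit-integral predictors (onset impulse, offset impulse, sustained
boxcar) convolved with a shifted-Gamma pupil response function, scaled by
per-condition β-weights, riding on a baseline with additive AR(1) Gaussian
noise.  The condition effect is a multiplicative gain on the sustained β
only: higher perceived numerosity -> stronger sustained luminance response
(constriction for white stimuli, dilation for black).

Blink artifacts are Poisson-placed drops to ~0 mm with 20 ms linear ramps,
so they trip both the minimum-size and the velocity exclusion rules.

2AFC responses come from a cumulative-Gaussian observer:
P(probe judged more numerous) = lapse/2 + (1 - lapse)·Φ((probe - PSE)/σ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .preprocess import PupilTrace
from .prf_glm import PRFParams, build_design

__all__ = [
    "SimTrialSpec",
    "SimConfig",
    "ObserverSpec",
    "simulate_trial",
    "inject_artifacts",
    "simulate_session",
    "make_session_design",
    "simulate_2afc",
]

# sustained gain per (numerosity, connectedness): ordered by perceived
# numerosity, with 18-isolated and 24-connected nearly equivalent (the
# illusion makes 24 connected dots look like about 18).
DEFAULT_GAINS = {
    (18, "connected"): 0.80,
    (18, "isolated"): 1.05,
    (24, "connected"): 1.00,
    (24, "isolated"): 1.30,
}


@dataclass(frozen=True)
class SimTrialSpec:
    onset_time: float  # s, stimulus onset within the session
    numerosity: int = 18
    connectedness: str = "isolated"
    polarity: str = "white"
    duration: float = 6.0
    pre: float = 1.0  # fixation before stimulus
    post: float = 1.0  # trial continues after offset

    def __post_init__(self):
        if self.duration <= 0 or self.onset_time < self.pre:
            raise ValueError("duration must be > 0 and onset_time >= pre")

    @property
    def offset_time(self) -> float:
        return self.onset_time + self.duration


@dataclass(frozen=True)
class SimConfig:
    prf: PRFParams = PRFParams(4, 250.0, 100.0)
    beta_onset: float = -0.10  # mm; transient constriction at appearance
    beta_offset: float = -0.05  # mm
    beta_sustained: float = 0.90  # mm; sign set by polarity, gain by condition
    sustained_gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))
    noise_sd: float = 0.05  # mm, stationary AR(1) sd
    noise_ar1: float = 0.995  # per-sample coefficient at sampling_rate
    blink_rate: float = 2.0  # events / min
    blink_duration_ms: float = 100.0
    sampling_rate: float = 500.0
    baseline_diameter: float = 4.0  # mm
    gaze_jitter_sd: float = 0.3  # deg

    def __post_init__(self):
        if self.sampling_rate <= 0 or self.noise_sd < 0 or not 0 <= self.noise_ar1 < 1:
            raise ValueError("invalid noise/sampling configuration")

    def condition_betas(self, numerosity: int, connectedness: str, polarity: str):
        """(β_onset, β_offset, β_sustained) for one condition cell."""
        gain = self.sustained_gains.get((numerosity, connectedness), 1.0)
        sign = -1.0 if polarity == "white" else 1.0
        return np.array([self.beta_onset, self.beta_offset,
                         sign * gain * self.beta_sustained])


@dataclass(frozen=True)
class ObserverSpec:
    pse: float  # dots
    sigma: float  # dots
    lapse: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0 or not 0 <= self.lapse <= 0.5:
            raise ValueError("sigma must be > 0 and lapse in [0, 0.5]")

    def p_more(self, probe) -> np.ndarray:
        return self.lapse / 2 + (1 - self.lapse) * stats.norm.cdf(
            (np.asarray(probe, float) - self.pse) / self.sigma
        )


def _ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    w = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n)
    w[0] = rng.normal(0.0, sd)
    return signal.lfilter([1.0], [1.0, -phi], w)


def _model_deviation(spec: SimTrialSpec, cfg: SimConfig, t0: float, t1: float,
                     dt: float) -> np.ndarray:
    """Noiseless β-weighted model deviation on [t0, t1) at resolution dt."""
    grid, X = build_design(
        (spec.onset_time, spec.offset_time), dt, cfg.prf, t_start=t0, t_end=t1
    )
    betas = cfg.condition_betas(spec.numerosity, spec.connectedness, spec.polarity)
    return X @ betas


def simulate_trial(spec: SimTrialSpec, cfg: SimConfig,
                   rng: np.random.Generator | int = 0) -> PupilTrace:
    """One trial's trace from t=0 (fixation onset at onset_time - pre) to
    trial end (offset_time + post)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dt = 1.0 / cfg.sampling_rate
    t0 = spec.onset_time - spec.pre
    t1 = spec.offset_time + spec.post
    dev = _model_deviation(spec, cfg, t0, t1 - dt / 2, dt)
    n = len(dev)
    t = t0 + np.arange(n) * dt
    pupil = cfg.baseline_diameter + dev + _ar1_noise(n, cfg.noise_sd, cfg.noise_ar1, rng)
    gaze_x = rng.normal(0.0, cfg.gaze_jitter_sd, n)
    gaze_y = rng.normal(0.0, cfg.gaze_jitter_sd, n)
    return PupilTrace(time=t, pupil=pupil, gaze_x=gaze_x, gaze_y=gaze_y,
                      sampling_rate=cfg.sampling_rate)


def inject_artifacts(trace: PupilTrace, cfg: SimConfig,
                     rng: np.random.Generator | int = 0) -> PupilTrace:
    """Poisson-placed blinks: 20 ms linear ramp down, ~0 mm plateau for
    blink_duration, 20 ms ramp up."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if cfg.blink_rate <= 0:
        return trace
    duration_min = (trace.time[-1] - trace.time[0]) / 60.0
    n_blinks = rng.poisson(cfg.blink_rate * duration_min)
    if n_blinks == 0:
        return trace
    dt = 1.0 / trace.sampling_rate
    ramp = max(1, int(round(0.020 / dt)))
    plateau = max(1, int(round(cfg.blink_duration_ms / 1000.0 / dt)))
    p = trace.pupil.copy()
    n = len(p)
    for start in rng.integers(ramp, max(n - plateau - ramp, ramp + 1), n_blinks):
        down = np.linspace(1.0, 0.0, ramp, endpoint=False)
        up = np.linspace(0.0, 1.0, ramp, endpoint=False)
        p[start - ramp: start] *= down
        p[start: start + plateau] = 0.01  # closed lid: essentially no pupil
        end = min(start + plateau + ramp, n)
        p[start + plateau: end] *= up[: end - start - plateau]
    return replace(trace, pupil=p)


def make_session_design(
    n_trials: int = 60,
    numerosity: int = 18,
    polarity: str = "white",
    connectedness_seq: list[str] | None = None,
    rng: np.random.Generator | int = 0,
    inter_onset: float = 9.0,
    first_onset: float = 1.0,
) -> list[SimTrialSpec]:
    """Session layout: connected and isolated trials intermixed in
    pseudo-random order, one numerosity and polarity per session."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if connectedness_seq is None:
        seq = ["connected", "isolated"] * (n_trials // 2 + 1)
        seq = list(rng.permutation(seq[:n_trials]))
    else:
        seq = list(connectedness_seq)
    return [
        SimTrialSpec(onset_time=first_onset + i * inter_onset, numerosity=numerosity,
                     connectedness=seq[i], polarity=polarity)
        for i in range(n_trials)
    ]


def simulate_session(
    design: list[SimTrialSpec],
    cfg: SimConfig,
    rng: np.random.Generator | int = 0,
    with_artifacts: bool = False,
) -> tuple[PupilTrace, pd.DataFrame]:
    """Continuous session trace plus the aligned event table.

    Trials may not overlap (each occupies [onset - pre, offset + post)).
    An empty design yields a short baseline-only trace.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dt = 1.0 / cfg.sampling_rate
    spans = sorted((s.onset_time - s.pre, s.offset_time + s.post) for s in design)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping trials: [{a0}, {a1}) and [{b0}, {b1})")
    t_end = (spans[-1][1] + 1.0) if spans else 5.0
    n = int(round(t_end / dt))
    t = np.arange(n) * dt
    # one FFT convolution for the whole session: β-weighted impulses and
    # boxcars accumulated into a single predictor train
    pred = np.zeros(n)
    from .prf_glm import gamma_prf

    for spec in design:
        b_on, b_off, b_sus = cfg.condition_betas(
            spec.numerosity, spec.connectedness, spec.polarity
        )
        i_on = int(round(spec.onset_time / dt))
        i_off = int(round(spec.offset_time / dt))
        pred[i_on] += b_on / dt
        pred[i_off] += b_off / dt
        pred[i_on:i_off] += b_sus / spec.duration
    kernel = gamma_prf(np.arange(n) * dt, cfg.prf)
    dev = signal.fftconvolve(pred, kernel)[:n] * dt
    pupil = cfg.baseline_diameter + dev + _ar1_noise(n, cfg.noise_sd, cfg.noise_ar1, rng)
    trace = PupilTrace(
        time=t, pupil=pupil,
        gaze_x=rng.normal(0.0, cfg.gaze_jitter_sd, n),
        gaze_y=rng.normal(0.0, cfg.gaze_jitter_sd, n),
        sampling_rate=cfg.sampling_rate,
    )
    if with_artifacts:
        trace = inject_artifacts(trace, cfg, rng)
    events = pd.DataFrame(
        {
            "trial": np.arange(len(design)),
            "onset_s": [s.onset_time for s in design],
            "offset_s": [s.offset_time for s in design],
            "numerosity": [s.numerosity for s in design],
            "connectedness": [s.connectedness for s in design],
            "polarity": [s.polarity for s in design],
        }
    )
    return trace, events


def simulate_2afc(
    observer: ObserverSpec,
    probe_levels,
    trials_per_level: int,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Binomial response counts per probe level from the Gaussian observer."""
    if trials_per_level < 1:
        raise ValueError("trials_per_level must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    probes = np.asarray(probe_levels, float)
    p = observer.p_more(probes)
    n_more = rng.binomial(trials_per_level, p)
    return pd.DataFrame(
        {"probe": probes, "n_trials": trials_per_level, "n_more": n_more}
    )
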