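"""Cumulative-Gaussian psychometric fitting, PSE and the numerosity bias index.

In the 2AFC task the observer reports which of two arrays is more numerous;
the proportion of "probe more numerous" responses as a function of probe
numerosity is fitted with a cumulative Gaussian Φ((x - PSE)/σ), whose
median is the point of subjective equality (PSE).  The connectedness
illusion shifts the PSE below the reference numerosity N; the bias index

    Bias = 100 · (PSE / N - 1)

expresses that shift in percent (negative = underestimation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PsychometricFit",
    "fit_cumulative_gaussian",
    "bias_index",
    "predicted_perceived_numerosity",
]

SIGMA_FLOOR = 1e-3


@dataclass
class PsychometricFit:
    pse: float  # dots (median of the fitted function)
    sigma: float  # dots
    log_likelihood: float
    converged: bool
    pinned: bool = False  # sigma hit its lower bound (response step)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    required = {"probe", "n_trials", "n_more"}
    if not required <= set(t.columns):
        raise ValueError(f"response table needs columns {sorted(required)}")
    if (t["n_more"] < 0).any() or (t["n_more"] > t["n_trials"]).any():
        raise ValueError("n_more must lie in [0, n_trials]")
    t = t.groupby("probe", as_index=False)[["n_trials", "n_more"]].sum()
    if t["probe"].nunique() < 3:
        raise ValueError("need at least 3 distinct probe levels")
    return t


def _nll(params, x, n, k, lapse):
    pse, log_sigma = params
    sigma = np.exp(log_sigma)
    p = lapse / 2 + (1 - lapse) * stats.norm.cdf((x - pse) / sigma)
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_cumulative_gaussian(table: pd.DataFrame, lapse: float = 0.0,
                            free_lapse: bool = False) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of a 2AFC response table.

    ``table`` holds probe numerosity, trial count and "probe more" count per
    level.  The Bernoulli likelihood is maximized over (PSE, σ); lapse is
    fixed (0 by default) unless ``free_lapse``, which estimates it in
    [0, 0.5].  Perfect-step data pin σ at a small floor with a warning;
    all-identical responses are non-identifiable and raise.
    """
    t = _validate_table(table)
    x = t["probe"].to_numpy(float)
    n = t["n_trials"].to_numpy(float)
    k = t["n_more"].to_numpy(float)
    prop = k / n
    if np.all(k == 0) or np.all(k == n):
        raise ValueError("responses all identical: PSE is not identifiable")

    # perfect separation: a step from all-0 to all-1 drives sigma to zero
    order = np.argsort(x)
    p_sorted = prop[order]
    if set(np.unique(p_sorted)) <= {0.0, 1.0} and np.all(np.diff(p_sorted) >= 0):
        i = int(np.argmax(p_sorted == 1.0))
        pse = float((x[order][i - 1] + x[order][i]) / 2.0)
        warnings.warn("separated responses: sigma pinned at its lower bound")
        return PsychometricFit(pse=pse, sigma=SIGMA_FLOOR, log_likelihood=0.0,
                               converged=True, pinned=True)

    # probit-regression start
    z = stats.norm.ppf(np.clip(prop, 0.02, 0.98))
    slope, intercept = np.polyfit(x, z, 1)
    sigma0 = 1.0 / max(abs(slope), 1e-3)
    pse0 = -intercept / slope if slope != 0 else float(np.mean(x))
    pse0 = float(np.clip(pse0, x.min() - 3 * sigma0, x.max() + 3 * sigma0))

    if free_lapse:
        def nll3(params):
            pse_, log_sigma_, lam = params
            lam = float(np.clip(lam, 0.0, 0.5))
            return _nll((pse_, log_sigma_), x, n, k, lam)

        res = optimize.minimize(
            nll3, np.array([pse0, np.log(sigma0), 0.02]), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000},
        )
    else:
        res = optimize.minimize(
            _nll, np.array([pse0, np.log(sigma0)]), args=(x, n, k, lapse),
            method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
    pse = float(res.x[0])
    sigma = float(np.exp(res.x[1]))
    pinned = False
    if sigma < SIGMA_FLOOR:
        sigma = SIGMA_FLOOR
        pinned = True
        warnings.warn("separated responses: sigma pinned at its lower bound")
    return PsychometricFit(
        pse=pse, sigma=sigma, log_likelihood=-float(res.fun),
        converged=bool(res.success), pinned=pinned,
    )


def bias_index(pse: float, reference_numerosity: float) -> float:
    """Percentage deviation of the PSE from the reference numerosity:
    100·(PSE/N − 1).  Negative values mean underestimation."""
    if reference_numerosity <= 0:
        raise ValueError("reference numerosity must be > 0")
    return 100.0 * (pse / reference_numerosity - 1.0)


def predicted_perceived_numerosity(physical: float, bias_percent: float) -> float:
    """Apparent numerosity of a physical count under a given bias."""
    return physical * (1.0 + bias_percent / 100.0)
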