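"""Condition-level statistics: 2x2 repeated-measures ANOVA, paired t with
Cohen's d, and the bivariate contour ellipse area (BCEA) fixation control.

The ANOVA is the textbook fully-within two-factor decomposition: each
effect (numerosity, connectedness, their interaction) is tested against
its own participant-by-effect interaction, and partial eta squared is
SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaEffect",
    "rm_anova_2x2",
    "paired_t",
    "bcea",
    "condition_matrix_from_frame",
]


@dataclass
class AnovaEffect:
    name: str
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    degenerate: bool = False  # zero error variance: F unbounded


def condition_matrix_from_frame(
    df: pd.DataFrame,
    value: str,
    subject: str = "participant",
    factor_a: str = "numerosity",
    factor_b: str = "connectedness",
) -> np.ndarray:
    """Pivot a tidy per-participant table into the (n_subj, 2, 2) cell array.

    Participants with incomplete cells are dropped (listwise deletion).
    """
    wide = df.pivot_table(index=subject, columns=[factor_a, factor_b], values=value)
    if wide.shape[1] != 4:
        raise ValueError("expected exactly 4 condition cells (2x2 design)")
    wide = wide.dropna()
    a_levels = sorted({c[0] for c in wide.columns})
    b_levels = sorted({c[1] for c in wide.columns})
    out = np.empty((len(wide), 2, 2))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            out[:, i, j] = wide[(a, b)].to_numpy(float)
    return out


def rm_anova_2x2(matrix: np.ndarray) -> dict[str, AnovaEffect]:
    """Two-way fully-within ANOVA on an (n_subjects, 2, 2) cell array.

    Returns effects keyed 'A' (first factor), 'B' (second factor) and 'AxB',
    each with F(1, n-1), p, and partial eta squared.
    """
    Y = np.asarray(matrix, float)
    if Y.ndim != 3 or Y.shape[1:] != (2, 2):
        raise ValueError("matrix must have shape (n_subjects, 2, 2)")
    if not np.isfinite(Y).all():
        raise ValueError("incomplete design: cells contain non-finite values")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")

    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))
    a = Y.mean(axis=(0, 2))  # factor A marginal means
    b = Y.mean(axis=(0, 1))
    ab = Y.mean(axis=0)
    sa = Y.mean(axis=2)  # subject x A
    sb = Y.mean(axis=1)

    ss_a = 2.0 * n * np.sum((a - grand) ** 2)
    ss_b = 2.0 * n * np.sum((b - grand) ** 2)
    ss_ab = n * np.sum((ab - a[:, None] - b[None, :] + grand) ** 2)
    ss_as = 2.0 * np.sum((sa - subj[:, None] - a[None, :] + grand) ** 2)
    ss_bs = 2.0 * np.sum((sb - subj[:, None] - b[None, :] + grand) ** 2)
    resid = (
        Y
        - sa[:, :, None]
        - sb[:, None, :]
        - ab[None, :, :]
        + subj[:, None, None]
        + a[None, :, None]
        + b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    out: dict[str, AnovaEffect] = {}
    for name, ss_eff, ss_err in (
        ("A", ss_a, ss_as),
        ("B", ss_b, ss_bs),
        ("AxB", ss_ab, ss_abs),
    ):
        df_eff, df_err = 1, n - 1
        degenerate = ss_err <= 1e-300
        if degenerate:
            F = math.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        else:
            F = (ss_eff / df_eff) / (ss_err / df_err)
            p = float(stats.f.sf(F, df_eff, df_err))
        etap2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out[name] = AnovaEffect(
            name=name, F=float(F), df=(df_eff, df_err), p=p,
            partial_eta_sq=float(etap2), ss_effect=float(ss_eff),
            ss_error=float(ss_err), degenerate=degenerate,
        )
    return out


def paired_t(a, b) -> dict:
    """Paired two-sided t-test with Cohen's d for paired data
    (mean difference over the SD of the differences)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("a and b must be equal-length 1-D arrays, n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    d = float(diff.mean() / sd)
    return {"t": float(res.statistic), "df": len(a) - 1,
            "p": float(res.pvalue), "cohens_d": d}


def bcea(gaze_x, gaze_y, coverage: float = 0.68) -> float:
    """Bivariate contour ellipse area (deg^2) covering ``coverage`` of the
    gaze samples: 2π·k·σx·σy·√(1-ρ²) with k = −ln(1−P)."""
    x = np.asarray(gaze_x, float)
    y = np.asarray(gaze_y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired gaze samples")
    if not (0 < coverage < 1):
        raise ValueError("coverage must lie in (0, 1)")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate gaze samples: zero variance")
    rho = float(np.corrcoef(x, y)[0, 1])
    if abs(rho) >= 1.0 - 1e-12:
        raise ValueError("degenerate gaze samples: |rho| = 1")
    k = -math.log(1.0 - coverage)
    return float(2 * math.pi * k * sx * sy * math.sqrt(1 - rho**2))
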