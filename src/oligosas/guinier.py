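"""Guinier analysis: low-Q estimation of Rg and I(0).

In the Guinier regime ln I(Q) is linear in Q^2:

    ln I(Q) = ln I(0) - (Rg^2 / 3) * Q^2,       valid for Q*Rg <~ 1.3

A weighted linear regression of ln I on Q^2 over an automatically chosen
low-Q window yields Rg = sqrt(-3*slope) and I(0) = exp(intercept), with
standard errors propagated from the regression covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile_io import ScatteringProfile


class GuinierError(RuntimeError):
    """Raised when no valid Guinier fit can be obtained."""


@dataclass
class GuinierResult:
    """Result of a Guinier fit.

    rg, rg_se : radius of gyration and its standard error, A.
    i0, i0_se : zero-angle intensity and its standard error.
    q_window : (qmin, qmax) of the fitted window, 1/A.
    n_points : number of points in the window.
    qrg_max : q_window[1] * rg (dimensionless validity indicator).
    """

    rg: float
    rg_se: float
    i0: float
    i0_se: float
    q_window: tuple[float, float]
    n_points: int
    qrg_max: float

    def to_dict(self) -> dict:
        return {
            "rg": self.rg, "rg_se": self.rg_se,
            "i0": self.i0, "i0_se": self.i0_se,
            "q_window": list(self.q_window),
            "n_points": self.n_points, "qrg_max": self.qrg_max,
        }


_MIN_WINDOW = 5


def _wls(q2: np.ndarray, ln_i: np.ndarray, w: np.ndarray):
    """Weighted least squares of ln_i on [1, q2]; returns
    (slope, intercept, slope_se, intercept_se)."""
    X = np.column_stack([np.ones_like(q2), q2])
    WX = X * w[:, None]
    cov = np.linalg.inv(X.T @ WX)
    beta = cov @ (WX.T @ ln_i)
    intercept, slope = beta
    se = np.sqrt(np.diag(cov))
    return slope, intercept, se[1], se[0]


def guinier_fit(profile: ScatteringProfile, qrg_limit: float = 1.3) -> GuinierResult:
    """Fit the Guinier law over an automatically selected low-Q window.

    The window starts at the lowest usable Q (first contiguous run of
    points with I > 0), grows upward point by point while the running fit
    keeps qmax*Rg within ``qrg_limit``, then shrinks from the top until
    the constraint holds. Weights are (I/sigma)^2, the variance of ln I
    to first order.

    Raises
    ------
    GuinierError
        If fewer than 5 usable low-Q points exist, or the fitted slope is
        non-negative (no Guinier decay).
    """
    q, i, s = profile.q, profile.intensity, profile.sigma
    usable = i > 0
    if not usable[0]:
        # skip leading unusable points, then demand a contiguous positive run
        first = np.argmax(usable) if usable.any() else len(q)
    else:
        first = 0
    run_end = first
    while run_end < len(q) and i[run_end] > 0:
        run_end += 1
    idx = np.arange(first, run_end)
    if idx.size < _MIN_WINDOW:
        raise GuinierError(
            f"only {idx.size} usable (I > 0) low-Q points; need >= {_MIN_WINDOW}"
        )

    q2 = q[idx] ** 2
    ln_i = np.log(i[idx])
    w = (i[idx] / s[idx]) ** 2

    def fit(end: int):
        slope, intercept, s_se, i_se = _wls(q2[:end], ln_i[:end], w[:end])
        if slope >= 0:
            return None
        rg = float(np.sqrt(-3.0 * slope))
        return slope, intercept, s_se, i_se, rg

    # grow the window from the minimum size, skipping windows too short or
    # too noisy to show decay; keep the largest window whose own fit
    # satisfies qmax * Rg <= limit, and stop once a valid fit exceeds it
    res, end = None, None
    for trial_end in range(_MIN_WINDOW, idx.size + 1):
        trial = fit(trial_end)
        if trial is None:
            continue
        if np.sqrt(q2[trial_end - 1]) * trial[4] > qrg_limit:
            if res is not None:
                break
            continue
        res, end = trial, trial_end

    if res is None:
        raise GuinierError("non-Guinier behaviour: fitted slope >= 0 (no decay)")
    slope, intercept, slope_se, intercept_se, rg = res
    i0 = float(np.exp(intercept))
    rg_se = float(3.0 / (2.0 * rg) * slope_se)
    qmax = float(np.sqrt(q2[end - 1]))
    return GuinierResult(
        rg=rg,
        rg_se=rg_se,
        i0=i0,
        i0_se=float(i0 * intercept_se),
        q_window=(float(np.sqrt(q2[0])), qmax),
        n_points=int(end),
        qrg_max=float(qmax * rg),
    )
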