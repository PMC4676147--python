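"""Data-driven defaults for the WPLA tuning parameters.

All rules are deterministic functions of the observed matrix D built on the
median absolute deviation, a scale estimate that ignores both recurrent
signal blocks (a minority of entries) and arbitrarily wild outliers:

* ``alpha1 = (sqrt(n) + sqrt(p)) * 1.48 * MAD`` — the universal nuclear-norm
  level for an n x p matrix with i.i.d. noise of scale sigma_hat.
* ``alpha2 = 0.1 * alpha1`` — fixed ratio between the TV and rank penalties.
* ``beta = (1.4826 * MAD)^2 * beta0`` with beta0 = 1 (uniform prior) or 2
  (Jeffreys prior): residuals beyond one robust noise scale get downweighted.
* ``rho0 = 0.1 * sigma_max(D)`` — initial ADMM penalty, then residual-balanced.

The two Gaussian-consistency constants (1.48 for alpha1, 1.4826 for beta) are
deliberately kept distinct, one per rule; pass ``mad_constant`` to unify
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningDefaults",
    "mad",
    "default_alpha1",
    "default_alpha2",
    "default_beta",
    "default_rho0",
    "tuning_defaults",
]

ALPHA1_FLOOR = 1e-8


@dataclass(frozen=True)
class TuningDefaults:
    sigma_hat: float
    alpha1: float
    alpha2: float
    beta: float
    rho0: float


def mad(D: np.ndarray) -> float:
    """Median absolute deviation from the global median, over all entries."""
    D = np.asarray(D, dtype=np.float64)
    if D.size == 0:
        raise ValueError("mad of an empty matrix is undefined")
    return float(np.median(np.abs(D - np.median(D))))


def default_alpha1(D: np.ndarray, mad_constant: float = 1.48) -> float:
    """Nuclear-norm weight ``(sqrt(n) + sqrt(p)) * mad_constant * MAD(D)``.

    A degenerate (constant) matrix gives MAD 0; the result is floored at a
    tiny positive value with a warning so downstream solves stay defined.
    """
    D = np.atleast_2d(np.asarray(D, dtype=np.float64))
    n, p = D.shape
    a1 = (np.sqrt(n) + np.sqrt(p)) * mad_constant * mad(D)
    if a1 < ALPHA1_FLOOR:
        warnings.warn(
            "MAD(D) is zero (degenerate input); flooring alpha1 at 1e-8",
            RuntimeWarning,
            stacklevel=2,
        )
        return ALPHA1_FLOOR
    return float(a1)


def default_alpha2(alpha1: float) -> float:
    """TV weight, fixed at one tenth of the nuclear-norm weight."""
    return 0.1 * alpha1


def default_beta(D: np.ndarray, beta0: float = 1.0, mad_constant: float = 1.4826) -> float:
    """Weight-penalty level ``(mad_constant * MAD(D))^2 * beta0``."""
    if beta0 not in (1, 2):
        warnings.warn(
            f"beta0={beta0} is non-standard (expected 1 or 2)", RuntimeWarning, stacklevel=2
        )
    m = mad(D)
    if m == 0.0:
        warnings.warn(
            "MAD(D) is zero (degenerate input); beta defaults to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return float((mad_constant * m) ** 2 * beta0)


def default_rho0(D: np.ndarray) -> float:
    """Initial ADMM parameter: one tenth of the largest singular value of D."""
    D = np.asarray(D, dtype=np.float64)
    if not np.any(D):
        raise ValueError("rho0 is undefined for an all-zero matrix")
    return 0.1 * float(np.linalg.norm(D, ord=2))


def tuning_defaults(D: np.ndarray, beta0: float = 1.0) -> TuningDefaults:
    """Bundle all default rules for one matrix."""
    D = np.atleast_2d(np.asarray(D, dtype=np.float64))
    sigma_hat = 1.4826 * mad(D)
    a1 = default_alpha1(D)
    beta = default_beta(D, beta0=beta0)
    if beta <= 0:
        beta = ALPHA1_FLOOR
    rho0 = default_rho0(D) if np.any(D) else 0.1
    return TuningDefaults(
        sigma_hat=sigma_hat,
        alpha1=a1,
        alpha2=default_alpha2(a1),
        beta=beta,
        rho0=rho0,
    )
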