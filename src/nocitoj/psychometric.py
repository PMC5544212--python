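"""Logistic psychometric model for temporal order judgments.

The model links the stimulus onset asynchrony (SOA, signed ms; negative
means the left target led) to the probability of reporting one particular
order.  With threshold ``alpha`` (the point of subjective simultaneity,
PSS) and steepness ``beta`` (1/ms), the core function is

    f(x) = 1 / (1 + exp(-beta * (x - alpha)))

optionally mixed with a symmetric lapse rate ``lam``:

    psi(x) = lam + (1 - 2*lam) * f(x)

``alpha`` is the SOA at which both orders are reported equally often;
``beta`` measures judgment precision and maps to the just noticeable
difference as JND = ln(3)/beta (the 50%-to-75% distance).  The derivative
of f at the PSS is beta/4, which is how a "slope" in probability-per-ms
units relates to the raw beta reported here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PsychometricParams",
    "response_probability",
    "trial_likelihood",
    "jnd",
]


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of one condition's logistic psychometric function.

    Parameters
    ----------
    alpha : float
        Threshold / PSS in ms.
    beta : float
        Logistic steepness in 1/ms; must be positive.
    lapse : float, default 0
        Symmetric stimulus-independent error rate, in [0, 0.5).
    """

    alpha: float
    beta: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValueError(f"alpha must be finite, got {self.alpha}")
        if not (math.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError(f"lapse must lie in [0, 0.5), got {self.lapse}")


def response_probability(soa, params: PsychometricParams):
    """Probability that the reference order is reported at a given SOA.

    Evaluates ``psi(x) = lapse + (1 - 2*lapse) / (1 + exp(-beta*(x - alpha)))``.
    Accepts a scalar SOA or an array; returns the same shape.
    """
    from scipy.special import expit

    x = np.asarray(soa, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("SOA must be finite")
    core = expit(params.beta * (x - params.alpha))
    p = params.lapse + (1.0 - 2.0 * params.lapse) * core
    if np.ndim(soa) == 0:
        return float(p)
    return p


def trial_likelihood(response, soa, params: PsychometricParams):
    """Bernoulli likelihood of one binary first-judgment.

    ``response`` encodes "reference stimulus judged first" as 1 (else 0).
    Returns ``psi(soa)`` for response 1 and ``1 - psi(soa)`` for response 0;
    the two branches sum to one.
    """
    r = np.asarray(response)
    if not np.all((r == 0) | (r == 1)):
        raise ValueError("response must be binary (0/1)")
    p = response_probability(soa, params)
    out = np.where(r == 1, p, 1.0 - np.asarray(p))
    if np.ndim(response) == 0 and np.ndim(soa) == 0:
        return float(out)
    return out


def jnd(params: PsychometricParams) -> float:
    """Just noticeable difference, the 50%-to-75% SOA distance: ln(3)/beta.

    Defined on the underlying lapse-free logistic; requires ``lapse == 0``.
    """
    if params.lapse != 0.0:
        raise ValueError("JND is defined on the lapse-free logistic (lapse=0)")
    return math.log(3.0) / params.beta
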