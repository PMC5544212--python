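"""Bayesian adaptive PSI engine for temporal order judgments.

The PSI method maintains a posterior over a discrete grid of
(alpha, beta) psychometric parameters and, on every trial, presents the
SOA from the candidate set that minimizes the expected posterior entropy
over the parameters — i.e. the stimulus expected to be most informative
given everything observed so far.  After the response, the posterior is
updated by Bayes' rule and the cycle repeats.  Point estimates are the
posterior marginal mean of alpha and the exponentiated posterior marginal
mean of log beta (slopes are scale parameters, so they are gridded and
averaged on a log scale).

Defaults: alpha uniform on [-200, 200] ms in 41 steps (spanning the most
extreme SOAs used in the experiments), beta log-spaced on [0.005, 0.5]
1/ms in 25 steps, uniform prior on alpha and on log beta, lapse fixed
at 0 during fitting.

Tie-breaking in SOA selection is deterministic: among minimizers of the
expected entropy (within 1e-12), the smallest |SOA| wins, and a remaining
+/- tie resolves to the negative SOA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .psychometric import PsychometricParams, response_probability

__all__ = [
    "ParameterGrid",
    "PsiState",
    "init_psi",
    "select_soa",
    "update_posterior",
    "estimate",
    "DEFAULT_ALPHA_RANGE",
    "DEFAULT_BETA_RANGE",
]

DEFAULT_ALPHA_RANGE = (-200.0, 200.0, 41)
DEFAULT_BETA_RANGE = (0.005, 0.5, 25)

_TIE_TOL = 1e-12


@dataclass
class ParameterGrid:
    """Discrete (alpha, beta) candidate grid with a prior.

    ``prior`` has shape ``(len(alpha_values), len(beta_values))`` and sums
    to 1.  ``beta_values`` should be log-spaced (they are treated as a
    scale parameter throughout).
    """

    alpha_values: np.ndarray
    beta_values: np.ndarray
    prior: np.ndarray
    lapse: float = 0.0

    def __post_init__(self) -> None:
        self.alpha_values = np.asarray(self.alpha_values, dtype=float)
        self.beta_values = np.asarray(self.beta_values, dtype=float)
        if self.alpha_values.ndim != 1 or self.beta_values.ndim != 1:
            raise ValueError("grids must be one-dimensional")
        if np.any(np.diff(self.alpha_values) <= 0) or np.any(
            np.diff(self.beta_values) <= 0
        ):
            raise ValueError("grid values must be strictly increasing")
        if np.any(self.beta_values <= 0):
            raise ValueError("beta grid must be positive")
        self.prior = np.asarray(self.prior, dtype=float)
        if self.prior.shape != (self.alpha_values.size, self.beta_values.size):
            raise ValueError("prior shape must match alpha x beta grid")
        if np.any(self.prior < 0):
            raise ValueError("prior weights must be nonnegative")
        total = self.prior.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("prior is not normalizable")
        if abs(total - 1.0) > 1e-12:
            self.prior = self.prior / total

    @classmethod
    def default(
        cls,
        alpha_range: tuple[float, float, int] = DEFAULT_ALPHA_RANGE,
        beta_range: tuple[float, float, int] = DEFAULT_BETA_RANGE,
        lapse: float = 0.0,
    ) -> "ParameterGrid":
        """Uniform prior on alpha and on log beta over the default spans."""
        a_lo, a_hi, n_a = alpha_range
        b_lo, b_hi, n_b = beta_range
        alphas = np.linspace(a_lo, a_hi, int(n_a))
        betas = np.geomspace(b_lo, b_hi, int(n_b))
        prior = np.full((int(n_a), int(n_b)), 1.0 / (int(n_a) * int(n_b)))
        return cls(alphas, betas, prior, lapse=lapse)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.alpha_values.size, self.beta_values.size)


@dataclass
class PsiState:
    """Full state of one adaptive series: grid, posterior, SOA candidates
    and the precomputed likelihood cache ``psi(soa | alpha, beta)``."""

    grid: ParameterGrid
    soa_set: np.ndarray
    posterior: np.ndarray
    likelihood_cache: np.ndarray  # (n_soa, n_alpha, n_beta)
    trial_count: int = 0
    history: list = field(default_factory=list)  # (soa, response) pairs
    # per-(SOA, grid point) Bernoulli response entropy, precomputed from
    # the likelihood cache at init; purely derived, not serialized
    _response_entropy: np.ndarray | None = None

    # -- serialization (session resumption) --------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha_values": self.grid.alpha_values.tolist(),
                "beta_values": self.grid.beta_values.tolist(),
                "prior": self.grid.prior.tolist(),
                "lapse": self.grid.lapse,
                "soa_set": self.soa_set.tolist(),
                "posterior": self.posterior.tolist(),
                "trial_count": self.trial_count,
                "history": [[float(s), int(r)] for s, r in self.history],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PsiState":
        d = json.loads(payload)
        grid = ParameterGrid(
            np.asarray(d["alpha_values"]),
            np.asarray(d["beta_values"]),
            np.asarray(d["prior"]),
            lapse=d["lapse"],
        )
        state = init_psi(grid, np.asarray(d["soa_set"]))
        state.posterior = np.asarray(d["posterior"], dtype=float)
        state.trial_count = int(d["trial_count"])
        state.history = [(float(s), int(r)) for s, r in d["history"]]
        return state


_CACHE_CLIP = 1e-12


def _likelihood_cache(grid: ParameterGrid, soa_set: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    a = grid.alpha_values[None, :, None]
    b = grid.beta_values[None, None, :]
    x = soa_set[:, None, None]
    core = expit(b * (x - a))
    cache = grid.lapse + (1.0 - 2.0 * grid.lapse) * core
    # keep entries strictly inside (0, 1): expit saturates to exactly 0/1
    # at extreme SOA x steep-slope corners, which would let the posterior
    # vanish identically even though the true likelihood never does
    return np.clip(cache, _CACHE_CLIP, 1.0 - _CACHE_CLIP)


def _bernoulli_entropy(cache: np.ndarray) -> np.ndarray:
    return -(xlogy(cache, cache) + xlogy(1.0 - cache, 1.0 - cache))


def init_psi(grid: ParameterGrid, soa_set) -> PsiState:
    """Initialize a series: posterior = prior, likelihood cache filled."""
    soas = np.asarray(soa_set, dtype=float)
    if soas.size == 0:
        raise ValueError("soa_set must be nonempty")
    cache = _likelihood_cache(grid, soas)
    return PsiState(
        grid=grid,
        soa_set=soas,
        posterior=grid.prior.copy(),
        likelihood_cache=cache,
        _response_entropy=_bernoulli_entropy(cache),
    )


def _tie_break(soa_set: np.ndarray, objective: np.ndarray) -> float:
    """Smallest |SOA| among minimizers; a remaining +/- tie goes negative."""
    best = objective.min()
    candidates = soa_set[objective <= best + _TIE_TOL]
    min_abs = np.abs(candidates).min()
    finalists = candidates[np.abs(candidates) <= min_abs + _TIE_TOL]
    return float(finalists.min())


def expected_entropies(state: PsiState) -> np.ndarray:
    """Expected posterior entropy E[H | x] for every candidate SOA.

    E[H|x] = sum_r p(r|x) * H(posterior | x, r) with
    p(r|x) = sum_theta p(r|x,theta) * posterior(theta).  Expanding the
    entropy of the normalized update gives the information-theoretic
    identity E[H|x] = H(posterior) - Hb(p1(x)) + sum_theta
    posterior(theta) * Hb(L(x,theta)), where Hb is the Bernoulli entropy:
    the expected posterior entropy is the current entropy minus the
    mutual information between the response and the parameters.
    """
    p = state.posterior.reshape(-1)
    L = state.likelihood_cache.reshape(state.soa_set.size, -1)
    hL = state._response_entropy
    if hL is None:
        hL = _bernoulli_entropy(state.likelihood_cache)
        state._response_entropy = hL
    hL = hL.reshape(state.soa_set.size, -1)
    p1 = L @ p
    h_post = -xlogy(p, p).sum()
    h_response = -(xlogy(p1, p1) + xlogy(1.0 - p1, 1.0 - p1))
    return h_post - h_response + hL @ p


def select_soa(state: PsiState) -> float:
    """Pick the SOA minimizing expected posterior entropy (deterministic)."""
    if np.max(state.posterior) == 1.0:  # exact point mass only
        warnings.warn(
            "posterior is degenerate (all mass on one grid point); "
            "returning tie-break default",
            RuntimeWarning,
            stacklevel=2,
        )
        return _tie_break(state.soa_set, np.zeros(state.soa_set.size))
    return _tie_break(state.soa_set, expected_entropies(state))


def update_posterior(state: PsiState, soa: float, response: int) -> PsiState:
    """Bayes update of the posterior after observing (soa, response).

    Mutates and returns ``state``: posterior(theta) proportional to
    current(theta) * p(response | soa, theta), renormalized.
    """
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")
    idx = np.flatnonzero(np.isclose(state.soa_set, soa))
    if idx.size == 0:
        raise ValueError(f"SOA {soa} is not in the candidate set")
    L = state.likelihood_cache[idx[0]]
    like = L if response == 1 else 1.0 - L
    post = state.posterior * like
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("posterior vanished during update")
    state.posterior = post / total
    state.trial_count += 1
    state.history.append((float(soa), int(response)))
    return state


def estimate(state: PsiState) -> PsychometricParams:
    """Posterior-mean estimate: alpha on the natural scale, beta via the
    posterior mean of log beta."""
    p_alpha = state.posterior.sum(axis=1)
    p_beta = state.posterior.sum(axis=0)
    alpha = float(p_alpha @ state.grid.alpha_values)
    beta = float(np.exp(p_beta @ np.log(state.grid.beta_values)))
    return PsychometricParams(alpha=alpha, beta=beta, lapse=state.grid.lapse)
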