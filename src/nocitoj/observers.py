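"""Simulated TOJ observers embodying prior entry.

A nociceptive cue on one hand draws attention to that side, so the cued
visual target is perceived earlier than the uncued one.  In the
left/right frame (negative SOA = left target first; response 1 = right
target reported first) a left-hand cue therefore produces a positive
generative PSS: the right target must physically lead by the shift
magnitude to be perceived simultaneous with the attended left target.
A right-hand cue mirrors the sign, and a bilateral cue produces no
lateralized shift.  The shift magnitude depends on the cell of the
design (target position near/far from the trunk, and in the second
experiment the hand-target congruency).

The response process is Bernoulli: P(right perceived first) follows the
logistic psychometric function at the trial's SOA with the observer's
condition-specific PSS, slope and lapse.  In "which second" blocks the
reported label is the complement of the perceived-first side; no extra
modality-specific noise is modeled.  Trials are i.i.d. given the
condition (no fatigue or drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import psi as _psi
from .design import BILATERAL, UNILATERAL_LEFT, UNILATERAL_RIGHT, ExperimentConfig, schedule_session
from .io import SessionLog
from .psychometric import PsychometricParams, response_probability

__all__ = [
    "ObserverSpec",
    "CohortSpec",
    "true_alpha",
    "simulate_response",
    "simulate_session",
    "simulate_cohort",
    "exp1_default_cohort",
    "exp2_default_cohort",
    "null_cohort",
]

_BETA_FLOOR = 1e-3


@dataclass
class ObserverSpec:
    """Ground-truth generative parameters of one simulated participant.

    ``shift_map`` gives, per analysis cell (``(position,)`` or
    ``(position, congruency)``), the attentional PSS shift magnitude in ms
    (positive = cued side prioritized).  ``bilateral_shift`` defaults to
    0 per cell and can be overridden.
    """

    shift_map: dict
    true_beta: float
    lapse: float = 0.0
    bilateral_shift: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_beta <= 0:
            raise ValueError("true_beta must be positive")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")
        self.shift_map = {tuple(k): float(v) for k, v in self.shift_map.items()}
        self.bilateral_shift = {
            tuple(k): float(v) for k, v in self.bilateral_shift.items()
        }


def true_alpha(observer: ObserverSpec, cue_condition: str, cell: tuple) -> float:
    """Generative PSS (left/right frame) for one trial context.

    Left cue -> +shift (the uncued right target must lead to appear
    simultaneous), right cue -> -shift, bilateral -> 0 unless overridden.
    """
    cell = tuple(cell)
    if cue_condition == BILATERAL:
        return observer.bilateral_shift.get(cell, 0.0)
    if cell not in observer.shift_map:
        raise KeyError(f"no shift defined for cell {cell}")
    shift = observer.shift_map[cell]
    if cue_condition == UNILATERAL_LEFT:
        return +shift
    if cue_condition == UNILATERAL_RIGHT:
        return -shift
    raise KeyError(f"unknown cue condition {cue_condition!r}")


def simulate_response(
    observer: ObserverSpec,
    soa: float,
    cue_condition: str,
    cell: tuple,
    modality: str,
    rng: np.random.Generator,
) -> str:
    """Draw one reported label ('left'/'right') for a trial."""
    alpha = true_alpha(observer, cue_condition, cell)
    params = PsychometricParams(alpha=alpha, beta=observer.true_beta, lapse=observer.lapse)
    p_right_first = response_probability(soa, params)
    perceived_first = "right" if rng.random() < p_right_first else "left"
    if modality == "first":
        return perceived_first
    if modality == "second":
        return "left" if perceived_first == "right" else "right"
    raise ValueError(f"unknown response modality {modality!r}")


def _block_cell(row) -> tuple:
    if row.hand_congruency is None or (
        isinstance(row.hand_congruency, float) and np.isnan(row.hand_congruency)
    ):
        return (row.visual_position,)
    return (row.visual_position, row.hand_congruency)


def simulate_session(
    observer: ObserverSpec,
    config: ExperimentConfig,
    seed: int,
    grid: _psi.ParameterGrid | None = None,
    participant_id: str = "sim",
) -> SessionLog:
    """Run a full session: schedule, then the PSI loop per series.

    Each (block x cue condition) series drives its own fresh PSI engine;
    SOAs are selected online by expected-entropy minimization, responses
    drawn from the observer, and the posterior updated trial by trial.
    Deterministic given (observer, config, seed, grid).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_ss, resp_ss = ss.spawn(2)
    schedule = schedule_session(config, sched_ss)
    rng = np.random.default_rng(resp_ss)
    if grid is None:
        grid = _psi.ParameterGrid.default()

    # all series share one likelihood cache (same grid, same SOA set)
    template = _psi.init_psi(grid, np.asarray(config.soa_set))
    states: dict = {}
    soas = np.empty(len(schedule))
    responses = []
    for i, row in enumerate(schedule.itertuples(index=False)):
        key = (row.block_id, row.cue_condition)
        state = states.get(key)
        if state is None:
            state = _psi.PsiState(
                grid=grid,
                soa_set=template.soa_set,
                posterior=grid.prior.copy(),
                likelihood_cache=template.likelihood_cache,
                _response_entropy=template._response_entropy,
            )
            states[key] = state
        soa = _psi.select_soa(state)
        cell = _block_cell(row)
        reported = simulate_response(
            observer, soa, row.cue_condition, cell, row.response_modality, rng
        )
        # the engine tracks the perceived-first judgment, which is
        # recoverable deterministically from the reported label
        if row.response_modality == "first":
            perceived_first = reported
        else:
            perceived_first = "left" if reported == "right" else "right"
        _psi.update_posterior(state, soa, 1 if perceived_first == "right" else 0)
        soas[i] = soa
        responses.append(reported)

    trials = schedule.copy()
    trials["soa_ms"] = soas
    trials["response"] = responses

    est_rows = []
    for (block_id, cue), state in states.items():
        params = _psi.estimate(state)
        est_rows.append(
            {
                "block_id": block_id,
                "cue_condition": cue,
                "pss": params.alpha,
                "slope": params.beta,
                "n_trials": state.trial_count,
            }
        )
    estimates = pd.DataFrame(est_rows)
    return SessionLog(
        participant_id=participant_id,
        config=config,
        seed=int(seed) if np.isscalar(seed) else -1,
        trials=trials,
        estimates=estimates,
        meta={
            "grid_alpha": [float(grid.alpha_values[0]), float(grid.alpha_values[-1]), int(grid.alpha_values.size)],
            "grid_beta": [float(grid.beta_values[0]), float(grid.beta_values[-1]), int(grid.beta_values.size)],
            "true_beta": observer.true_beta,
            "lapse": observer.lapse,
        },
    )


@dataclass
class CohortSpec:
    """Population layer: per-cell mean shifts and between-participant SDs.

    Shifts are Gaussian across participants per cell, with correlation
    ``shift_correlation`` between any two cells of the same participant
    (individuals with a strong attentional bias show it in every cell, so
    cell shifts are far from independent within a participant).  Slopes
    are Gaussian on the log scale (floored at a small positive value).
    """

    n: int
    cell_shift_means: dict
    cell_shift_sds: dict
    # slope calibrated so that the dispersion of recovered group PSS and
    # the size of the group statistics match the reported human data
    # (slopes are shown only graphically there); JND ~ 13.7 ms
    beta_mean: float = 0.08
    log_beta_sd: float = 0.25
    lapse: float = 0.02
    bilateral_sd: float = 0.0
    shift_correlation: float = 0.8

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        if any(v < 0 for v in self.cell_shift_sds.values()) or self.bilateral_sd < 0:
            raise ValueError("SDs must be nonnegative")
        if not (0.0 <= self.shift_correlation <= 1.0):
            raise ValueError("shift_correlation must lie in [0, 1]")
        self.cell_shift_means = {tuple(k): float(v) for k, v in self.cell_shift_means.items()}
        self.cell_shift_sds = {tuple(k): float(v) for k, v in self.cell_shift_sds.items()}


def draw_observer(cohort: CohortSpec, rng: np.random.Generator) -> ObserverSpec:
    # equicorrelated Gaussian cell shifts via a shared participant factor:
    # z_cell = sqrt(rho)*u + sqrt(1-rho)*e_cell with u, e ~ N(0,1)
    rho = cohort.shift_correlation
    u = rng.standard_normal()
    shifts = {
        cell: mean
        + cohort.cell_shift_sds[cell]
        * (np.sqrt(rho) * u + np.sqrt(1.0 - rho) * rng.standard_normal())
        for cell, mean in cohort.cell_shift_means.items()
    }
    beta = float(
        np.exp(rng.normal(np.log(cohort.beta_mean), cohort.log_beta_sd))
    )
    beta = max(beta, _BETA_FLOOR)
    bilateral = {}
    if cohort.bilateral_sd > 0:
        bilateral = {
            cell: rng.normal(0.0, cohort.bilateral_sd)
            for cell in cohort.cell_shift_means
        }
    return ObserverSpec(
        shift_map=shifts,
        true_beta=beta,
        lapse=cohort.lapse,
        bilateral_shift=bilateral,
    )


def simulate_cohort(
    cohort: CohortSpec,
    config: ExperimentConfig,
    seed: int,
    grid: _psi.ParameterGrid | None = None,
) -> list[SessionLog]:
    """Simulate ``cohort.n`` sessions with per-observer derived seeds."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(cohort.n)
    logs = []
    for i, child in enumerate(children):
        draw_ss, sess_ss = child.spawn(2)
        observer = draw_observer(cohort, np.random.default_rng(draw_ss))
        log = simulate_session(
            observer, config, sess_ss, grid=grid, participant_id=f"P{i + 1:02d}"
        )
        log.seed = int(seed) if np.isscalar(seed) else -1
        log.meta["participant_index"] = i
        log.meta["true_shift_map"] = {
            "|".join(k): v for k, v in observer.shift_map.items()
        }
        log.meta["true_beta"] = observer.true_beta
        logs.append(log)
    return logs


def exp1_default_cohort(n: int = 17) -> CohortSpec:
    """Cohort matching the first experiment's group-level effects:
    near-cell mean shift 10.95 ms (SD 7.29), far 5.34 ms (SD 6.36)."""
    return CohortSpec(
        n=n,
        cell_shift_means={("near",): 10.95, ("far",): 5.34},
        cell_shift_sds={("near",): 7.29, ("far",): 6.36},
    )


def exp2_default_cohort(n: int = 23) -> CohortSpec:
    """Cohort matching the second experiment: congruent-hand cells shift
    10.94 ms (SD 8.33), incongruent 7.85 ms (SD 6.64), at both positions."""
    means = {
        ("near", "congruent"): 10.94,
        ("far", "congruent"): 10.94,
        ("near", "incongruent"): 7.85,
        ("far", "incongruent"): 7.85,
    }
    sds = {
        ("near", "congruent"): 8.33,
        ("far", "congruent"): 8.33,
        ("near", "incongruent"): 6.64,
        ("far", "incongruent"): 6.64,
    }
    return CohortSpec(n=n, cell_shift_means=means, cell_shift_sds=sds)


def null_cohort(n: int = 17, experiment: str = "exp1") -> CohortSpec:
    """Cohort with every attentional shift exactly zero (type-I studies)."""
    if experiment == "exp1":
        cells = [("near",), ("far",)]
    else:
        cells = [
            ("near", "congruent"),
            ("far", "congruent"),
            ("near", "incongruent"),
            ("far", "incongruent"),
        ]
    zeros = {c: 0.0 for c in cells}
    return CohortSpec(n=n, cell_shift_means=zeros, cell_shift_sds=dict(zeros))
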