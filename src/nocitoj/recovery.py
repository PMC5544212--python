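"""Parameter-recovery and calibration studies.

These studies quantify what the adaptive engine and the analysis
pipeline can recover under known ground truth:

* single-series recovery — bias / absolute error / RMSE of the PSS
  estimate for an on-grid lapse-free observer as a function of the trial
  budget (estimator consistency: RMSE must not increase with more trials);
* null calibration — the type-I error rate of the one-sample t-test on
  the combined unilateral PSS across cohorts simulated with every
  attentional shift at zero (should sit at the nominal level);
* effect-structure recovery — the probability that a cohort generated
  with a larger near-cell than far-cell shift yields a positive
  unilateral near-far PSS difference and a positive-signed interaction
  contrast in the 2x2 ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import psi as _psi
from .analysis import run_paper_analysis
from .design import build_exp1_config
from .observers import (
    CohortSpec,
    ObserverSpec,
    exp1_default_cohort,
    null_cohort,
    simulate_cohort,
)
from .psychometric import PsychometricParams, response_probability

__all__ = [
    "run_series",
    "series_recovery_study",
    "rmse_by_budget",
    "null_calibration_study",
    "effect_recovery_study",
]


def run_series(
    true_params: PsychometricParams,
    soa_set,
    n_trials: int,
    rng: np.random.Generator,
    grid: _psi.ParameterGrid | None = None,
) -> PsychometricParams:
    """One adaptive series against a synthetic observer; returns the
    posterior-mean estimate after ``n_trials`` trials."""
    if grid is None:
        grid = _psi.ParameterGrid.default()
    state = _psi.init_psi(grid, np.asarray(soa_set, dtype=float))
    for _ in range(n_trials):
        soa = _psi.select_soa(state)
        p = response_probability(soa, true_params)
        r = 1 if rng.random() < p else 0
        _psi.update_posterior(state, soa, r)
    return _psi.estimate(state)


def series_recovery_study(
    true_alpha: float = 10.0,
    true_beta: float = 0.041135,
    n_trials: int = 40,
    n_replicates: int = 100,
    seed: int = 0,
    soa_set=None,
    grid: _psi.ParameterGrid | None = None,
) -> pd.DataFrame:
    """Replicated single-series recovery for one on-grid observer.

    The default truth (alpha = 10 ms, beta = 0.041135 1/ms) sits exactly
    on the default grid.  Returns one row per replicate with the alpha
    and beta estimates and their errors.
    """
    if soa_set is None:
        soa_set = build_exp1_config().soa_set
    truth = PsychometricParams(true_alpha, true_beta)
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(ss.spawn(n_replicates)):
        est = run_series(truth, soa_set, n_trials, np.random.default_rng(child), grid=grid)
        rows.append(
            {
                "replicate": i,
                "alpha_hat": est.alpha,
                "beta_hat": est.beta,
                "alpha_error": est.alpha - true_alpha,
                "abs_alpha_error": abs(est.alpha - true_alpha),
            }
        )
    return pd.DataFrame(rows)


def rmse_by_budget(
    budgets=(20, 80, 320),
    n_replicates: int = 200,
    true_alpha: float = 10.0,
    true_beta: float = 0.041135,
    seed: int = 0,
    soa_set=None,
) -> pd.DataFrame:
    """PSS RMSE per trial budget (consistency: non-increasing in budget)."""
    if soa_set is None:
        soa_set = build_exp1_config().soa_set
    truth = PsychometricParams(true_alpha, true_beta)
    grid = _psi.ParameterGrid.default()
    ss = np.random.SeedSequence(seed)
    rows = []
    for b, budget_ss in zip(budgets, ss.spawn(len(budgets))):
        errs = []
        for child in budget_ss.spawn(n_replicates):
            est = run_series(truth, soa_set, b, np.random.default_rng(child), grid=grid)
            errs.append(est.alpha - true_alpha)
        errs = np.asarray(errs)
        rows.append(
            {
                "n_trials": b,
                "bias": errs.mean(),
                "rmse": float(np.sqrt((errs**2).mean())),
                "median_abs_error": float(np.median(np.abs(errs))),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)


def _combined_unilateral_by_cell(results: dict) -> pd.DataFrame:
    combined = results["combined"]
    return combined.pivot(index="participant_id", columns="cell", values="pss_unilateral")


def null_calibration_study(
    n_cohorts: int = 400,
    n_participants: int = 17,
    alpha_level: float = 0.05,
    seed: int = 0,
    cohort: CohortSpec | None = None,
) -> pd.DataFrame:
    """Type-I calibration: rejection rate of the one-sample t on combined
    unilateral PSS across cohorts generated with zero shifts everywhere.

    One test per cohort (the near cell), so rejections are independent
    across cohorts and the rate has plain binomial error.
    """
    config = build_exp1_config()
    if cohort is None:
        cohort = null_cohort(n=n_participants)
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(ss.spawn(n_cohorts)):
        logs = simulate_cohort(cohort, config, child, grid=None)
        res = run_paper_analysis(logs)
        t_near = res["ttests"]["unilateral_near"]
        rows.append(
            {
                "cohort": i,
                "mean_pss_near": t_near.mean,
                "p_near": t_near.p,
                "reject_near": t_near.p <= alpha_level,
            }
        )
    return pd.DataFrame(rows)


def effect_recovery_study(
    n_replicates: int = 200,
    n_participants: int = 17,
    seed: int = 0,
    cohort: CohortSpec | None = None,
) -> pd.DataFrame:
    """Sign recovery of the near > far effect structure.

    Each replicate simulates a default first-experiment cohort
    (near 10.95 ms > far 5.34 ms), runs the full pipeline and records the
    unilateral near-far mean difference and the signed interaction
    effect (unilateral near-far advantage minus bilateral near-far
    difference) together with the ANOVA interaction F.
    """
    config = build_exp1_config()
    if cohort is None:
        cohort = exp1_default_cohort(n=n_participants)
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(ss.spawn(n_replicates)):
        logs = simulate_cohort(cohort, config, child, grid=None)
        res = run_paper_analysis(logs)
        pss = res["pss_matrix"]  # (n, cue[uni,bi], position[near,far])
        uni_diff = (pss[:, 0, 0] - pss[:, 0, 1]).mean()
        inter = ((pss[:, 0, 0] - pss[:, 0, 1]) - (pss[:, 1, 0] - pss[:, 1, 1])).mean()
        f_inter = res["anova_pss"].effects.set_index("effect").loc[
            "cue_condition:position", "F"
        ]
        rows.append(
            {
                "replicate": i,
                "mean_near": pss[:, 0, 0].mean(),
                "mean_far": pss[:, 0, 1].mean(),
                "unilateral_near_minus_far": uni_diff,
                "interaction_effect": inter,
                "interaction_F": float(f_inter),
                "positive_diff": uni_diff > 0,
                "positive_interaction": inter > 0,
            }
        )
    return pd.DataFrame(rows)
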