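"""From trial logs to the study's measures and statistics.

Pipeline, per participant:

1.  decode responses — "which second" reports are converted to the
    implied first-judgments and both response-modality blocks of a cell
    are pooled (merging reduces decisional response biases);
2.  fit each (cell x cue condition) pool of trials with a batch Bayes
    update over the same parameter grid the adaptive engine uses
    (order-independent, so the batch fit equals sequential updating);
3.  combine the two unilateral cue conditions into one signed PSS:
    (PSS_left_cue + (-PSS_right_cue)) / 2 in the left/right frame, so a
    positive value means the cued side was prioritized; bilateral cells
    stay in the left/right frame.

Group level: one-sample t-tests of each cell's PSS against 0 with
Cohen's d = t/sqrt(n); a 2x2 fully-within ANOVA from sums of squares
(cue condition x position for the first experiment, position x hand
congruency for the second) with partial eta squared
F*df1/(F*df1 + df2), Greenhouse-Geisser epsilon (identically 1 for
two-level factors, so the correction is vacuous here), 1-df
within-subject contrast F-tests of one factor at each level of the
other, and within-subject (Cousineau) confidence intervals for the
figures.  All p values are two-sided and uncorrected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import psi as _psi
from .design import BILATERAL, UNILATERAL_LEFT, UNILATERAL_RIGHT, ExperimentConfig
from .io import SessionLog
from .psychometric import PsychometricParams

__all__ = [
    "ConditionEstimate",
    "TTestResult",
    "AnovaTable",
    "remap_to_cue_frame",
    "merge_modalities",
    "fit_condition",
    "combine_unilateral",
    "one_sample_t",
    "rm_anova_2x2",
    "cousineau_ci",
    "run_paper_analysis",
    "cohens_d_from_t",
    "partial_eta_sq",
    "participant_estimates",
]


# --------------------------------------------------------------------------
# result containers

@dataclass
class ConditionEstimate:
    participant_id: str
    cell: tuple
    cue_condition: str
    pss: float
    slope: float
    n_trials: int
    flags: str = ""


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean: float
    sd: float
    n: int
    degenerate: bool = False


@dataclass
class AnovaTable:
    """2x2 fully-within ANOVA: main effects, interaction, contrasts."""

    effects: pd.DataFrame  # rows: A, B, A:B
    contrasts: pd.DataFrame  # simple effects of A at each level of B, and B at A
    factor_a: str
    factor_b: str


# --------------------------------------------------------------------------
# effect-size identities

def cohens_d_from_t(t: float, n: int) -> float:
    """One-sample Cohen's d from t and sample size: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return t / np.sqrt(n)


def partial_eta_sq(f: float, df_num: int, df_den: int) -> float:
    """Partial eta squared from F: F*df1 / (F*df1 + df2)."""
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    return (f * df_num) / (f * df_num + df_den)


# --------------------------------------------------------------------------
# trial-level transforms

def _implied_first(response: str, modality: str) -> str:
    if modality == "first":
        return response
    if modality == "second":
        return "left" if response == "right" else "right"
    raise ValueError(f"unknown response modality {modality!r}")


def merge_modalities(trials: pd.DataFrame) -> pd.DataFrame:
    """Pool both response-modality blocks of one cell as first-judgments.

    'Which second' reports are converted to the implied first-judgment
    (reported-second side implies the other side was perceived first);
    already-first-coded rows pass through, so the transform is idempotent.
    Output length equals the input length.  If only one modality is
    present a ``single_modality`` flag column marks every row.
    """
    out = trials.copy()
    out["first_judgment"] = [
        _implied_first(r, m)
        for r, m in zip(out["response"], out["response_modality"])
    ]
    out["response"] = out["first_judgment"]
    out["response_modality"] = "first"
    out = out.drop(columns="first_judgment")
    modalities = set(trials["response_modality"])
    if modalities < {"first", "second"}:
        import warnings

        warnings.warn(
            "only one response modality present; proceeding on available data",
            UserWarning,
            stacklevel=2,
        )
        out["single_modality"] = True
    return out


def remap_to_cue_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Re-express unilateral-cue trials in the cued/uncued frame.

    In the cue frame, negative SOA = cued-side target first and
    response 1 = cued side reported first.  Right-cue trials flip the
    SOA sign and mirror the labels; left-cue trials keep the SOA and only
    recode the response.  Applying the remap twice to right-cue trials
    restores the original.  Bilateral trials are rejected (they are
    analyzed in the left/right frame).
    """
    if (trials["cue_condition"] == BILATERAL).any():
        raise ValueError("bilateral trials cannot be remapped to the cue frame")
    out = trials.copy()
    right = out["cue_condition"] == UNILATERAL_RIGHT
    out.loc[right, "soa_ms"] = -out.loc[right, "soa_ms"]
    flip = {"left": "right", "right": "left"}
    out.loc[right, "response"] = out.loc[right, "response"].map(flip)
    # response 1 = cued side first: left for left cues, right-after-flip
    # became 'left' for right cues, so 'left' always denotes the cued side
    out["cued_first"] = (out["response"] == "left").astype(int)
    return out


# --------------------------------------------------------------------------
# fitting

def fit_condition(
    trials: pd.DataFrame,
    grid: _psi.ParameterGrid | None = None,
) -> tuple[PsychometricParams, str]:
    """Batch Bayes fit of pooled first-judgment trials on the PSI grid.

    The posterior is the prior times the product of Bernoulli trial
    likelihoods (computed in log space), so the result is identical to
    running sequential adaptive updates over the same trials in any
    order.  Returns (params, flags); ``flags`` is ``"boundary"`` when all
    responses are identical.
    """
    if grid is None:
        grid = _psi.ParameterGrid.default()
    soas = np.asarray(trials["soa_ms"], dtype=float)
    resp = np.asarray((trials["response"] == "right").astype(int))
    if soas.size < 10 or np.unique(soas).size < 3:
        raise ValueError("need >= 10 trials spanning >= 3 distinct SOAs")
    from scipy.special import expit

    a = grid.alpha_values[:, None]
    b = grid.beta_values[None, :]
    # the likelihood product only depends on the counts per (SOA, response)
    pairs, counts = np.unique(np.column_stack([soas, resp]), axis=0, return_counts=True)
    with np.errstate(divide="ignore"):
        log_post = np.log(grid.prior)
        for (x, r), k in zip(pairs, counts):
            p = grid.lapse + (1.0 - 2.0 * grid.lapse) * expit(b * (x - a))
            log_post += k * np.log(p if r == 1 else 1.0 - p)
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    alpha = float(post.sum(axis=1) @ grid.alpha_values)
    beta = float(np.exp(post.sum(axis=0) @ np.log(grid.beta_values)))
    flags = "boundary" if resp.min() == resp.max() else ""
    return PsychometricParams(alpha, beta, grid.lapse), flags


def combine_unilateral(pss_left_cue: float, pss_right_cue: float) -> float:
    """Average the left-cue PSS and the sign-flipped right-cue PSS.

    Both inputs are in the left/right frame; the result is positive when
    the cued side was prioritized (prior entry)."""
    return (pss_left_cue + (-pss_right_cue)) / 2.0


# --------------------------------------------------------------------------
# statistics

def one_sample_t(values, popmean: float = 0.0) -> TTestResult:
    """Classical one-sample t-test against 0 with d = mean/SD = t/sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 2 finite values")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return TTestResult(
            t=np.inf if mean != popmean else 0.0,
            df=n - 1,
            p=0.0 if mean != popmean else 1.0,
            cohens_d=np.inf if mean != popmean else 0.0,
            mean=mean,
            sd=sd,
            n=n,
            degenerate=True,
        )
    res = stats.ttest_1samp(x, popmean)
    t = float(res.statistic)
    return TTestResult(
        t=t,
        df=n - 1,
        p=float(res.pvalue),
        cohens_d=t / np.sqrt(n),
        mean=mean,
        sd=sd,
        n=n,
    )


def _rm_f_1df(diff: np.ndarray) -> tuple[float, int, int, float]:
    """1-df within-subject F on a per-participant difference: F = t^2."""
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return (np.inf if diff.mean() != 0 else 0.0), 1, n - 1, 0.0
    t = diff.mean() / (sd / np.sqrt(n))
    f = t * t
    p = float(stats.f.sf(f, 1, n - 1))
    return float(f), 1, n - 1, p


def rm_anova_2x2(
    data: np.ndarray,
    factor_a: str = "A",
    factor_b: str = "B",
    a_levels: tuple = ("a1", "a2"),
    b_levels: tuple = ("b1", "b2"),
) -> AnovaTable:
    """Two-way fully-within ANOVA on an (n, 2, 2) participant x A x B array.

    Each term's F uses its own effect-by-subject error stratum, computed
    from sums of squares.  Greenhouse-Geisser epsilon is identically 1
    for two-level factors (sphericity cannot be violated), so it is
    reported as 1 and no df correction applies.  Contrast rows test one
    factor at each fixed level of the other as 1-df within-subject Fs.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[1] != 4:
        if y.ndim == 3 and y.shape[1:] == (2, 2):
            pass
        else:
            raise ValueError("data must be (n, 2, 2) or (n, 4)")
    if y.ndim == 2:
        y = y.reshape(-1, 2, 2)
    if not np.all(np.isfinite(y)):
        raise ValueError("incomplete matrix: missing or non-finite cells")
    n = y.shape[0]
    if n < 3:
        raise ValueError("need n >= 3 participants")

    grand = y.mean()
    subj = y.mean(axis=(1, 2))  # (n,)
    a_mean = y.mean(axis=(0, 2))  # (2,)
    b_mean = y.mean(axis=(0, 1))  # (2,)
    cell = y.mean(axis=0)  # (2, 2)
    ia = y.mean(axis=2)  # (n, 2) subject x A
    ib = y.mean(axis=1)  # (n, 2) subject x B

    ss_a = 2 * n * ((a_mean - grand) ** 2).sum()
    ss_b = 2 * n * ((b_mean - grand) ** 2).sum()
    ss_as = 2 * ((ia - a_mean[None, :] - subj[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((ib - b_mean[None, :] - subj[:, None] + grand) ** 2).sum()
    inter = cell - a_mean[:, None] - b_mean[None, :] + grand
    ss_ab = n * (inter**2).sum()
    resid = (
        y
        - ia[:, :, None]
        - ib[:, None, :]
        - cell[None, :, :]
        + a_mean[None, :, None]
        + b_mean[None, None, :]
        + subj[:, None, None]
        - grand
    )
    ss_abs = (resid**2).sum()

    rows = []
    for name, ss_eff, ss_err in (
        (factor_a, ss_a, ss_as),
        (factor_b, ss_b, ss_bs),
        (f"{factor_a}:{factor_b}", ss_ab, ss_abs),
    ):
        df1, df2 = 1, n - 1
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        rows.append(
            {
                "effect": name,
                "F": float(f),
                "df_num": df1,
                "df_den": df2,
                "p": p,
                "partial_eta_sq": partial_eta_sq(f, df1, df2)
                if np.isfinite(f)
                else 1.0,
                "gg_epsilon": 1.0,
                "ss_effect": float(ss_eff),
                "ss_error": float(ss_err),
            }
        )
    effects = pd.DataFrame(rows)

    crows = []
    for j, b_lab in enumerate(b_levels):
        f, d1, d2, p = _rm_f_1df(y[:, 0, j] - y[:, 1, j])
        crows.append(
            {
                "contrast": f"{factor_a} at {factor_b}={b_lab}",
                "F": f,
                "df_num": d1,
                "df_den": d2,
                "p": p,
                "partial_eta_sq": partial_eta_sq(f, d1, d2) if np.isfinite(f) else 1.0,
            }
        )
    for i, a_lab in enumerate(a_levels):
        f, d1, d2, p = _rm_f_1df(y[:, i, 0] - y[:, i, 1])
        crows.append(
            {
                "contrast": f"{factor_b} at {factor_a}={a_lab}",
                "F": f,
                "df_num": d1,
                "df_den": d2,
                "p": p,
                "partial_eta_sq": partial_eta_sq(f, d1, d2) if np.isfinite(f) else 1.0,
            }
        )
    contrasts = pd.DataFrame(crows)
    return AnovaTable(effects=effects, contrasts=contrasts, factor_a=factor_a, factor_b=factor_b)


def cousineau_ci(data: np.ndarray, level: float = 0.95) -> pd.DataFrame:
    """Within-subject confidence intervals after Cousineau normalization.

    Each value is replaced by value - participant mean + grand mean, which
    removes between-participant offsets; the interval per cell is then
    mean +/- t(1-(1-level)/2, n-1) * SD_normalized/sqrt(n).  The optional
    Morey small-J correction is not applied (plain Cousineau).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be (n participants, k cells)")
    n, k = y.shape
    if n < 2:
        raise ValueError("need n >= 2 participants")
    norm = y - y.mean(axis=1, keepdims=True) + y.mean()
    sd = norm.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(1 - (1 - level) / 2, n - 1)
    mean = y.mean(axis=0)
    half = tcrit * sd / np.sqrt(n)
    return pd.DataFrame(
        {"cell": range(k), "mean": mean, "half_width": half,
         "lo": mean - half, "hi": mean + half}
    )


# --------------------------------------------------------------------------
# the full battery

def participant_estimates(
    log: SessionLog, grid: _psi.ParameterGrid | None = None
) -> list[ConditionEstimate]:
    """Fit every (cell x cue condition) of one participant's log.

    Both modality blocks of a cell are merged (2 x trials_per_series
    pooled trials per fit), then each cue condition is fitted in the
    left/right frame.
    """
    if grid is None:
        grid = _psi.ParameterGrid.default()
    config = log.config
    trials = merge_modalities(log.trials)
    out = []
    for cell in config.cells():
        mask = trials["visual_position"] == cell[0]
        if len(cell) > 1:
            mask &= trials["hand_congruency"] == cell[1]
        for cue in config.cue_conditions:
            sub = trials[mask & (trials["cue_condition"] == cue)]
            params, flags = fit_condition(sub, grid=grid)
            out.append(
                ConditionEstimate(
                    participant_id=log.participant_id,
                    cell=cell,
                    cue_condition=cue,
                    pss=params.alpha,
                    slope=params.beta,
                    n_trials=len(sub),
                    flags=flags,
                )
            )
    return out


def _combined_cells(estimates: list[ConditionEstimate], config: ExperimentConfig):
    """Per participant x cell: combined-unilateral (and bilateral) PSS/slope."""
    df = pd.DataFrame([{**asdict(e), "cell": tuple(e.cell)} for e in estimates])
    rows = []
    for (pid, cell), grp in df.groupby(["participant_id", "cell"], sort=False):
        by_cue = grp.set_index("cue_condition")
        pss_l = by_cue.loc[UNILATERAL_LEFT, "pss"]
        pss_r = by_cue.loc[UNILATERAL_RIGHT, "pss"]
        row = {
            "participant_id": pid,
            "cell": cell,
            "pss_unilateral": combine_unilateral(pss_l, pss_r),
            "slope_unilateral": (
                by_cue.loc[UNILATERAL_LEFT, "slope"]
                + by_cue.loc[UNILATERAL_RIGHT, "slope"]
            )
            / 2.0,
        }
        if BILATERAL in by_cue.index:
            row["pss_bilateral"] = by_cue.loc[BILATERAL, "pss"]
            row["slope_bilateral"] = by_cue.loc[BILATERAL, "slope"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_paper_analysis(
    logs: list[SessionLog],
    experiment: str | None = None,
    grid: _psi.ParameterGrid | None = None,
) -> dict:
    """The complete statistical battery on a set of session logs.

    Returns a results bundle (plain dict, JSON-serializable apart from the
    DataFrames) with per-participant estimates, one-sample t-tests of each
    cell's PSS against zero, the experiment's 2x2 within-participant ANOVA
    on PSS and on slope, its contrasts, and Cousineau CIs per cell.
    """
    if not logs:
        raise ValueError("no session logs supplied")
    names = {log.config.name for log in logs}
    if len(names) > 1:
        raise ValueError(f"mixed configurations: {sorted(names)}")
    config = logs[0].config
    if experiment is None:
        experiment = config.name
    ref = config.to_dict()
    for log in logs:
        if log.config.to_dict() != ref:
            raise ValueError(f"participant {log.participant_id}: config differs")

    estimates: list[ConditionEstimate] = []
    for log in logs:
        estimates.extend(participant_estimates(log, grid=grid))
    combined = _combined_cells(estimates, config)

    cells = config.cells()
    wide_pss = combined.pivot(index="participant_id", columns="cell", values="pss_unilateral")[cells]
    wide_slope = combined.pivot(index="participant_id", columns="cell", values="slope_unilateral")[cells]

    ttests = {}
    for cell in cells:
        ttests[f"unilateral_{'_'.join(cell)}"] = one_sample_t(wide_pss[cell].to_numpy())
    has_bilateral = BILATERAL in config.cue_conditions
    if has_bilateral:
        wide_pss_bi = combined.pivot(index="participant_id", columns="cell", values="pss_bilateral")[cells]
        wide_slope_bi = combined.pivot(index="participant_id", columns="cell", values="slope_bilateral")[cells]
        for cell in cells:
            ttests[f"bilateral_{'_'.join(cell)}"] = one_sample_t(wide_pss_bi[cell].to_numpy())

    results: dict = {
        "experiment": experiment,
        "n_participants": len(logs),
        "estimates": pd.DataFrame([asdict(e) for e in estimates]),
        "combined": combined,
        "ttests": ttests,
    }

    if has_bilateral:
        # first experiment: cue condition (unilateral vs bilateral) x position
        def stack(uni: pd.DataFrame, bi: pd.DataFrame) -> np.ndarray:
            arr = np.empty((len(uni), 2, 2))
            arr[:, 0, 0] = uni[("near",)]
            arr[:, 0, 1] = uni[("far",)]
            arr[:, 1, 0] = bi[("near",)]
            arr[:, 1, 1] = bi[("far",)]
            return arr

        pss_mat = stack(wide_pss, wide_pss_bi)
        slope_mat = stack(wide_slope, wide_slope_bi)
        kwargs = dict(
            factor_a="cue_condition",
            factor_b="position",
            a_levels=("unilateral", "bilateral"),
            b_levels=("near", "far"),
        )
    else:
        # second experiment: position x hand congruency, unilateral only
        pss_mat = np.empty((len(wide_pss), 2, 2))
        slope_mat = np.empty_like(pss_mat)
        for i, pos in enumerate(("near", "far")):
            for j, cong in enumerate(("congruent", "incongruent")):
                pss_mat[:, i, j] = wide_pss[(pos, cong)]
                slope_mat[:, i, j] = wide_slope[(pos, cong)]
        kwargs = dict(
            factor_a="position",
            factor_b="congruency",
            a_levels=("near", "far"),
            b_levels=("congruent", "incongruent"),
        )

    results["anova_pss"] = rm_anova_2x2(pss_mat, **kwargs)
    results["anova_slope"] = rm_anova_2x2(slope_mat, **kwargs)
    results["cousineau_pss"] = cousineau_ci(pss_mat.reshape(len(logs), 4))
    results["pss_matrix"] = pss_mat
    results["slope_matrix"] = slope_mat
    return results


def results_to_json(results: dict) -> dict:
    """JSON-serializable view of a results bundle (full precision)."""
    out = {
        "experiment": results["experiment"],
        "n_participants": results["n_participants"],
        "ttests": {k: asdict(v) for k, v in results["ttests"].items()},
        "anova_pss": {
            "effects": results["anova_pss"].effects.to_dict("records"),
            "contrasts": results["anova_pss"].contrasts.to_dict("records"),
        },
        "anova_slope": {
            "effects": results["anova_slope"].effects.to_dict("records"),
            "contrasts": results["anova_slope"].contrasts.to_dict("records"),
        },
        "cousineau_pss": results["cousineau_pss"].to_dict("records"),
    }
    return out


def report_text(results: dict) -> str:
    """Human-readable report in the printed style: t(df) = x, p, d; F(1,df)."""
    lines = [f"Experiment: {results['experiment']}  (n = {results['n_participants']})", ""]
    lines.append("One-sample t-tests of PSS vs 0")
    for name, r in results["ttests"].items():
        lines.append(
            f"  {name}: t({r.df}) = {r.t:.2f}, p = {r.p:.4g}, d = {r.cohens_d:.2f}"
            f"  (M = {r.mean:.2f}, SD = {r.sd:.2f})"
        )
    for label in ("anova_pss", "anova_slope"):
        tab = results[label]
        lines.append("")
        lines.append(f"Repeated-measures ANOVA ({label.split('_')[1].upper()}): "
                     f"{tab.factor_a} x {tab.factor_b}")
        for _, row in tab.effects.iterrows():
            lines.append(
                f"  {row['effect']}: F({row['df_num']},{row['df_den']}) = "
                f"{row['F']:.2f}, p = {row['p']:.4g}, eta2p = {row['partial_eta_sq']:.2f}"
            )
        for _, row in tab.contrasts.iterrows():
            lines.append(
                f"  contrast {row['contrast']}: F({row['df_num']},{row['df_den']}) = "
                f"{row['F']:.2f}, p = {row['p']:.4g}, eta2p = {row['partial_eta_sq']:.2f}"
            )
    return "\n".join(lines) + "\n"
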