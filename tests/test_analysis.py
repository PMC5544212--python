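import numpy as np
import pandas as pd
import pytest

from nocitoj import (
    cohens_d_from_t,
    combine_unilateral,
    cousineau_ci,
    fit_condition,
    merge_modalities,
    one_sample_t,
    partial_eta_sq,
    remap_to_cue_frame,
    rm_anova_2x2,
    run_paper_analysis,
)
from nocitoj.analysis import results_to_json, report_text
from nocitoj.design import UNILATERAL_LEFT, UNILATERAL_RIGHT
from nocitoj.psi import ParameterGrid, init_psi, update_posterior, estimate


def make_trials(soas, responses, cue=UNILATERAL_LEFT, modality="first", position="near"):
    return pd.DataFrame(
        {
            "soa_ms": soas,
            "response": responses,
            "cue_condition": cue,
            "response_modality": modality,
            "visual_position": position,
            "hand_congruency": None,
            "block_id": "near_" + modality,
        }
    )


class TestEffectSizeIdentities:
    def test_cohens_d_from_t(self):
        assert cohens_d_from_t(6.19, 17) == pytest.approx(1.50, abs=0.005)
        assert cohens_d_from_t(5.96, 23) == pytest.approx(1.24, abs=0.005)

    def test_partial_eta_sq(self):
        assert partial_eta_sq(24.37, 1, 16) == pytest.approx(0.60, abs=0.005)
        assert partial_eta_sq(16.80, 1, 22) == pytest.approx(0.43, abs=0.005)


class TestRemap:
    def test_right_cue_flips_sign_and_labels(self):
        trials = make_trials([-30.0], ["left"], cue=UNILATERAL_RIGHT)
        out = remap_to_cue_frame(trials)
        assert out["soa_ms"].iloc[0] == 30.0
        assert out["response"].iloc[0] == "right"
        assert out["cued_first"].iloc[0] == 0  # cued (right) side was second

    def test_left_cue_passes_through(self):
        trials = make_trials([-30.0], ["left"], cue=UNILATERAL_LEFT)
        out = remap_to_cue_frame(trials)
        assert out["soa_ms"].iloc[0] == -30.0
        assert out["cued_first"].iloc[0] == 1

    def test_involution_on_right_cue(self):
        trials = make_trials([-30.0, 55.0], ["left", "right"], cue=UNILATERAL_RIGHT)
        twice = remap_to_cue_frame(remap_to_cue_frame(trials))
        assert twice["soa_ms"].tolist() == trials["soa_ms"].tolist()
        assert twice["response"].tolist() == trials["response"].tolist()

    def test_bilateral_rejected(self):
        trials = make_trials([10.0], ["left"], cue="bilateral")
        with pytest.raises(ValueError):
            remap_to_cue_frame(trials)


class TestMerge:
    def test_second_report_implies_other_side_first(self):
        trials = make_trials([10.0], ["left"], modality="second")
        with pytest.warns(UserWarning):  # only one modality in this toy frame
            merged = merge_modalities(trials)
        assert merged["response"].iloc[0] == "right"

    def test_pools_both_blocks(self):
        first = make_trials([10.0] * 20, ["left"] * 20, modality="first")
        second = make_trials([10.0] * 20, ["left"] * 20, modality="second")
        merged = merge_modalities(pd.concat([first, second], ignore_index=True))
        assert len(merged) == 40

    def test_idempotent_on_first_coded_data(self):
        first = make_trials([10.0, -30.0], ["left", "right"], modality="first")
        with pytest.warns(UserWarning):
            once = merge_modalities(first)
        with pytest.warns(UserWarning):
            twice = merge_modalities(once)
        assert once["response"].tolist() == twice["response"].tolist()

    def test_single_modality_warns(self):
        first = make_trials([10.0] * 3, ["left"] * 3, modality="first")
        with pytest.warns(UserWarning, match="one response modality"):
            merged = merge_modalities(first)
        assert merged["single_modality"].all()


class TestFitCondition:
    def test_noiseless_on_grid_recovery(self, default_grid):
        # responses generated exactly at the logistic probabilities by
        # using many repeats per SOA and a steep on-grid function
        alpha0, beta0 = 20.0, 0.5
        soas = np.repeat([-200, -90, -30, -10, 10, 30, 55, 90, 200], 11)
        p = 1 / (1 + np.exp(-beta0 * (soas - alpha0)))
        resp = np.where(p > 0.5, "right", "left")
        params, flags = fit_condition(make_trials(soas, resp), grid=default_grid)
        step = np.diff(default_grid.alpha_values).min()
        assert abs(params.alpha - alpha0) <= step
        assert flags == ""

    def test_mirroring_negates_pss(self, default_grid):
        rng = np.random.default_rng(2)
        soas = rng.choice([-90, -55, -30, -10, 10, 30, 55, 90], 60).astype(float)
        p = 1 / (1 + np.exp(-0.08 * (soas - 12.0)))
        resp = np.where(rng.random(60) < p, "right", "left")
        direct, _ = fit_condition(make_trials(soas, resp), grid=default_grid)
        flip = {"left": "right", "right": "left"}
        mirrored, _ = fit_condition(
            make_trials(-soas, [flip[r] for r in resp]), grid=default_grid
        )
        assert mirrored.alpha == pytest.approx(-direct.alpha, abs=1e-9)
        assert mirrored.beta == pytest.approx(direct.beta, rel=1e-9)

    def test_batch_equals_sequential_updates(self, small_grid):
        rng = np.random.default_rng(5)
        soa_set = [-90.0, -30.0, -10.0, 10.0, 30.0, 90.0]
        soas = rng.choice(soa_set, 25)
        resp = np.where(rng.random(25) < 0.5, "right", "left")
        batch, _ = fit_condition(make_trials(soas, resp), grid=small_grid)
        state = init_psi(small_grid, soa_set)
        for s, r in zip(soas, resp):
            update_posterior(state, float(s), 1 if r == "right" else 0)
        seq = estimate(state)
        assert batch.alpha == pytest.approx(seq.alpha, abs=1e-9)
        assert batch.beta == pytest.approx(seq.beta, rel=1e-9)

    def test_too_few_trials_rejected(self, default_grid):
        with pytest.raises(ValueError):
            fit_condition(make_trials([10.0] * 5, ["left"] * 5), grid=default_grid)

    def test_all_identical_responses_flagged(self, default_grid):
        soas = [-90.0, -30.0, -10.0, 10.0, 30.0, 90.0] * 2
        params, flags = fit_condition(
            make_trials(soas, ["right"] * 12), grid=default_grid
        )
        assert flags == "boundary"


class TestCombineUnilateral:
    @pytest.mark.parametrize(
        "left, right, expected",
        [(7.0, -7.0, 7.0), (0.0, 0.0, 0.0), (10.2, -6.4, 8.3)],
    )
    def test_formula(self, left, right, expected):
        assert combine_unilateral(left, right) == pytest.approx(expected)


class TestOneSampleT:
    def test_d_identity_against_printed_values(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, 17)
        res = one_sample_t(x)
        assert res.cohens_d == pytest.approx(res.t / np.sqrt(17), abs=1e-9)
        assert res.df == 16
        assert res.cohens_d == pytest.approx(res.mean / res.sd, abs=1e-9)

    def test_matches_scipy(self):
        from scipy import stats

        x = [3.0, -1.0, 4.5, 2.0, 0.5]
        res = one_sample_t(x)
        ref = stats.ttest_1samp(x, 0.0)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_degenerate_flagged(self):
        res = one_sample_t([3.0, 3.0, 3.0])
        assert res.degenerate

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])


class TestRmAnova:
    # hand-computed 4-participant matrix: exact sums of squares give
    # F_A = 726, F_B = 72, F_AB = 24/7
    MATRIX = np.array(
        [[12, 8, 5, 3], [15, 9, 7, 6], [9, 7, 4, 2], [14, 10, 8, 5]], dtype=float
    )

    def test_manual_ss_oracle(self):
        tab = rm_anova_2x2(self.MATRIX).effects.set_index("effect")
        assert tab.loc["A", "F"] == pytest.approx(726.0, rel=1e-12)
        assert tab.loc["B", "F"] == pytest.approx(72.0, rel=1e-12)
        assert tab.loc["A:B", "F"] == pytest.approx(24.0 / 7.0, rel=1e-12)
        assert (tab["df_num"] == 1).all() and (tab["df_den"] == 3).all()

    def test_f_equals_squared_paired_t_on_contrasts(self):
        # independent derivation: in a 2x2 fully-within design each F is
        # the squared paired t on the per-participant contrast
        rng = np.random.default_rng(14)
        y = rng.normal(size=(9, 2, 2)) + np.array([[1.0, 0.2], [0.1, 0.0]])
        tab = rm_anova_2x2(y).effects.set_index("effect")
        from scipy import stats

        d_a = y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1)
        d_b = y[:, :, 0].mean(axis=1) - y[:, :, 1].mean(axis=1)
        d_ab = y[:, 0, 0] - y[:, 0, 1] - y[:, 1, 0] + y[:, 1, 1]
        for name, d in (("A", d_a), ("B", d_b), ("A:B", d_ab)):
            t = stats.ttest_1samp(d, 0.0)
            assert tab.loc[name, "F"] == pytest.approx(t.statistic**2, rel=1e-9)
            assert tab.loc[name, "p"] == pytest.approx(t.pvalue, rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(31)
        y = rng.normal(size=(8, 2, 2))
        tab = rm_anova_2x2(y).effects
        rows = []
        for i in range(8):
            for a in range(2):
                for b in range(2):
                    rows.append({"s": i, "A": f"a{a}", "B": f"b{b}", "y": y[i, a, b]})
        ref = pg.rm_anova(
            dv="y", within=["A", "B"], subject="s", data=pd.DataFrame(rows)
        )
        assert tab["F"].to_numpy() == pytest.approx(ref["F"].to_numpy(), rel=1e-8)
        assert tab["p"].to_numpy() == pytest.approx(ref["p_unc"].to_numpy(), rel=1e-8)

    def test_location_invariance(self):
        shifted = rm_anova_2x2(self.MATRIX + 100.0).effects
        base = rm_anova_2x2(self.MATRIX).effects
        assert shifted["F"].to_numpy() == pytest.approx(base["F"].to_numpy())

    def test_eta_identity_and_epsilon(self):
        tab = rm_anova_2x2(self.MATRIX).effects
        for _, row in tab.iterrows():
            ident = row["F"] * row["df_num"] / (row["F"] * row["df_num"] + row["df_den"])
            assert row["partial_eta_sq"] == pytest.approx(ident, abs=1e-9)
            assert row["gg_epsilon"] == 1.0

    def test_contrasts_are_simple_effect_ts(self):
        from scipy import stats

        tab = rm_anova_2x2(self.MATRIX, a_levels=("u", "v"), b_levels=("x", "z"))
        y = self.MATRIX.reshape(-1, 2, 2)
        row = tab.contrasts.set_index("contrast").loc["A at B=x"]
        t = stats.ttest_1samp(y[:, 0, 0] - y[:, 1, 0], 0.0)
        assert row["F"] == pytest.approx(t.statistic**2, rel=1e-9)

    def test_incomplete_matrix_rejected(self):
        bad = self.MATRIX.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x2(bad)
        with pytest.raises(ValueError):
            rm_anova_2x2(self.MATRIX[:2])


class TestCousineau:
    MATRIX = np.array([[4.0, 8.0], [6.0, 12.0], [5.0, 7.0]])

    def test_manual_oracle(self):
        ci = cousineau_ci(self.MATRIX)
        assert ci["mean"].to_numpy() == pytest.approx([5.0, 9.0])
        # normalized columns are (5,4,6) and (9,10,8): SD exactly 1
        expected_half = 4.302652729911275 / np.sqrt(3)
        assert ci["half_width"].to_numpy() == pytest.approx([expected_half] * 2)

    def test_normalization_equalizes_row_means(self):
        y = self.MATRIX
        norm = y - y.mean(axis=1, keepdims=True) + y.mean()
        assert norm.mean(axis=1) == pytest.approx([y.mean()] * 3)

    def test_between_participant_offsets_removed(self):
        offset = self.MATRIX + np.array([[100.0], [0.0], [-50.0]])
        base = cousineau_ci(self.MATRIX)
        shifted = cousineau_ci(offset)
        assert shifted["half_width"].to_numpy() == pytest.approx(
            base["half_width"].to_numpy()
        )

    def test_needs_two_participants(self):
        with pytest.raises(ValueError):
            cousineau_ci(self.MATRIX[:1])


class TestRunPaperAnalysis:
    def test_structure_and_effect_direction(self, tiny_exp1_logs):
        res = run_paper_analysis(tiny_exp1_logs)
        assert res["n_participants"] == 4
        assert set(res["ttests"]) == {
            "unilateral_near",
            "unilateral_far",
            "bilateral_near",
            "bilateral_far",
        }
        # strong precise generating effect (12 vs 6 ms): recovered order
        assert res["ttests"]["unilateral_near"].mean > res["ttests"]["unilateral_far"].mean
        assert res["anova_pss"].factor_a == "cue_condition"
        # per-participant estimates: 4 participants x 2 cells x 3 cues
        assert len(res["estimates"]) == 24
        assert (res["estimates"]["n_trials"] == 40).all()

    def test_deterministic_bundle(self, tiny_exp1_logs):
        import json

        a = json.dumps(results_to_json(run_paper_analysis(tiny_exp1_logs)))
        b = json.dumps(results_to_json(run_paper_analysis(tiny_exp1_logs)))
        assert a == b

    def test_report_lists_statistics(self, tiny_exp1_logs):
        text = report_text(run_paper_analysis(tiny_exp1_logs))
        assert "t(3)" in text and "F(1,3)" in text and "eta2p" in text

    def test_exp2_factors(self, exp2_config):
        from nocitoj.observers import CohortSpec, simulate_cohort

        cohort = CohortSpec(
            n=3,
            cell_shift_means={
                ("near", "congruent"): 10.0,
                ("far", "congruent"): 10.0,
                ("near", "incongruent"): 6.0,
                ("far", "incongruent"): 6.0,
            },
            cell_shift_sds={
                ("near", "congruent"): 0.0,
                ("far", "congruent"): 0.0,
                ("near", "incongruent"): 0.0,
                ("far", "incongruent"): 0.0,
            },
        )
        res = run_paper_analysis(simulate_cohort(cohort, exp2_config, 6))
        effects = set(res["anova_pss"].effects["effect"])
        assert effects == {"position", "congruency", "position:congruency"}
        assert not any(k.startswith("bilateral") for k in res["ttests"])

    def test_mixed_configs_rejected(self, tiny_exp1_logs, exp2_config):
        from nocitoj.observers import ObserverSpec, simulate_session

        obs = ObserverSpec(
            shift_map={
                ("near", "congruent"): 0.0,
                ("far", "congruent"): 0.0,
                ("near", "incongruent"): 0.0,
                ("far", "incongruent"): 0.0,
            },
            true_beta=0.08,
        )
        other = simulate_session(obs, exp2_config, seed=1)
        with pytest.raises(ValueError, match="mixed"):
            run_paper_analysis([tiny_exp1_logs[0], other])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            run_paper_analysis([])
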