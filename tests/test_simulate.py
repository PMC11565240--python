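import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import dbmtransit as dt
from dbmtransit.simulate import _modulate_rows
from dbmtransit.states import STATES


def identity_config(n=200, seed=5):
    eye = np.stack([np.eye(4)] * 4)
    return dt.SimConfig(
        n_subjects=n,
        transition_matrices=eye,
        initial_state_probs=(0.4, 0.3, 0.2, 0.1),
        seed=seed,
    )


class TestSimulateCohort:
    def test_identity_dynamics_freeze_states(self):
        panel, _ = dt.simulate_cohort(identity_config())
        per_subject = panel.groupby("subject_id")["state"].nunique()
        assert (per_subject == 1).all()

    def test_fixed_seed_is_bit_identical(self):
        cfg = dt.default_config(n_subjects=300, seed=9)
        a, _ = dt.simulate_cohort(cfg)
        b, _ = dt.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        aa = dt.simulate_anthropometry(a, cfg)
        bb = dt.simulate_anthropometry(b, cfg)
        pd.testing.assert_frame_equal(aa, bb)

    def test_empirical_frequencies_match_generating_matrices(self):
        # no covariate effects: per-interval conditional frequencies must sit
        # within 3 binomial Monte-Carlo SEs of the generating entries
        cfg = dt.default_config(n_subjects=50_000, seed=17)
        panel, _ = dt.simulate_cohort(cfg)
        counts = dt.count_transitions(panel)
        P, SE, defined = dt.mle_transitions(counts)
        true = np.asarray(cfg.transition_matrices)
        row_n = counts.row_totals()
        checked = violations = 0
        for t in range(4):
            for i in range(4):
                if row_n[t, i] < 50:
                    continue
                mc_se = np.sqrt(true[t, i] * (1 - true[t, i]) / row_n[t, i])
                bad = np.abs(P[t, i] - true[t, i]) > 3 * np.maximum(mc_se, 1e-12)
                checked += 4
                violations += int(bad.sum())
        assert checked >= 40
        # 3-sigma two-sided: expect ~0.3% violations; allow a small margin
        assert violations <= max(2, int(0.02 * checked))

    def test_initial_state_frequencies(self):
        cfg = dt.default_config(n_subjects=50_000, seed=23)
        panel, _ = dt.simulate_cohort(cfg)
        base = panel[panel["round"] == 1]["state"]
        p0 = np.asarray(cfg.initial_state_probs)
        for i, s in enumerate(STATES):
            freq = (base == s).mean()
            se = np.sqrt(p0[i] * (1 - p0[i]) / len(base))
            assert abs(freq - p0[i]) <= 3 * se + 1e-12

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda c: setattr(c, "n_subjects", 0),
            lambda c: setattr(c, "initial_state_probs", (0.5, 0.5, 0.2, -0.2)),
            lambda c: setattr(c, "round_ages", (1.0, 1.0, 8.0, 12.0, 15.0)),
        ],
    )
    def test_invalid_configs_rejected(self, mutate):
        cfg = dt.default_config(n_subjects=10, seed=0)
        mutate(cfg)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_non_stochastic_matrix_rejected(self):
        cfg = dt.default_config(n_subjects=10, seed=0)
        mats = np.asarray(cfg.transition_matrices).copy()
        mats[0, 0, 0] += 0.01
        cfg.transition_matrices = mats
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_null_effects_give_covariate_independent_transitions(self):
        # chi-squared of destination vs wealth stratum among round-1 normals,
        # across 100 seeds: non-significant at alpha=0.001 in >=95 of them
        significant = 0
        for seed in range(100):
            cfg = dt.default_config(n_subjects=2000, seed=seed)
            panel, _ = dt.simulate_cohort(cfg)
            wide = panel.pivot(index="subject_id", columns="round", values="state")
            w1 = panel[panel["round"] == 1].set_index("subject_id")["wealth_q"]
            origin_normal = wide[1] == "normal"
            tab = pd.crosstab(w1[origin_normal], wide[2][origin_normal])
            _, p, _, _ = chi2_contingency(tab, correction=False)
            significant += p < 0.001
        assert significant <= 5


class TestCovariateModulation:
    def test_row_stochasticity_preserved(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(4), size=50)
        origin = rng.integers(0, 4, size=50)
        delta = rng.normal(0, 1.5, size=50)
        out = _modulate_rows(rows, origin, {("stunting", "entry"): delta})
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out >= 0).all()

    def test_entry_probability_is_exact_logit_shift(self):
        cfg = dt.benchmark_config(n_subjects=10, seed=0, entry_log_odds=0.693)
        truth = dt.SimTruth(cfg)
        base = truth.entry_probability(0, "normal", "stunting", {"wealth_q": "Q1"})
        shifted = truth.entry_probability(0, "normal", "stunting", {"wealth_q": "Q4"})
        expected = 1 / (1 + np.exp(-(np.log(base / (1 - base)) + 0.693)))
        assert shifted == pytest.approx(expected, abs=1e-12)
        # baseline matrices give every non-stunted origin the same entry mass
        assert base == pytest.approx(
            truth.entry_probability(0, "overweight", "stunting", {"wealth_q": "Q1"}), abs=1e-12
        )


class TestAnthropometry:
    def test_truncation_contract(self):
        panel = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "round": 1,
                "age_years": [8.0, 22.0, 2.0, 22.0],
                "state": ["normal", "cso", "overweight", "normal"],
            }
        )
        cfg = dt.default_config(n_subjects=4, seed=3)
        out = dt.simulate_anthropometry(panel, cfg)
        assert out.loc[0, "haz"] >= -2 and out.loc[0, "baz"] <= 1
        assert out.loc[1, "haz"] < -2 and out.loc[1, "bmi"] > 25
        assert out.loc[2, "whz"] > 2
        assert out.loc[3, "bmi"] <= 25
        # age-inappropriate indices stay missing
        assert np.isnan(out.loc[0, "whz"]) and np.isnan(out.loc[0, "bmi"])

    def test_roundtrip_classification(self, default_cohort):
        panel, _, cfg = default_cohort
        measured = dt.simulate_anthropometry(panel, cfg)
        classified = dt.classify_panel(measured.drop(columns=["state"]))
        assert (classified["state"] == panel["state"]).all()

    def test_negative_age_rejected(self):
        panel = pd.DataFrame(
            {"subject_id": ["a"], "round": [1], "age_years": [-1.0], "state": ["normal"]}
        )
        with pytest.raises(ValueError, match="age"):
            dt.simulate_anthropometry(panel, dt.default_config(n_subjects=1))


class TestAttrition:
    def test_zero_dropout_is_identity(self, default_cohort):
        panel, _, cfg = default_cohort
        out = dt.apply_attrition(panel, cfg)
        pd.testing.assert_frame_equal(out, panel.reset_index(drop=True))

    def test_certain_dropout_leaves_one_round(self):
        cfg = dt.default_config(
            n_subjects=50, seed=1, attrition=dt.AttritionSpec(dropout=1.0)
        )
        panel, _ = dt.simulate_cohort(cfg)
        out = dt.apply_attrition(panel, cfg)
        assert (out.groupby("subject_id")["round"].max() == 1).all()
        assert len(out) == 50

    def test_monotone_dropout_no_gaps(self):
        cfg = dt.default_config(
            n_subjects=2000, seed=2, attrition=dt.AttritionSpec(dropout=0.15)
        )
        panel, _ = dt.simulate_cohort(cfg)
        out = dt.apply_attrition(panel, cfg)
        per = out.groupby("subject_id")["round"]
        assert (per.max() == per.count()).all()  # rounds 1..last, no holes

    def test_complete_case_survival_closed_form(self):
        cfg = dt.default_config(
            n_subjects=10_000, seed=4, attrition=dt.AttritionSpec(dropout=0.03)
        )
        panel, _ = dt.simulate_cohort(cfg)
        out = dt.apply_attrition(panel, cfg)
        complete = (out.groupby("subject_id")["round"].count() == 5).sum()
        frac = complete / 10_000
        expected = (1 - 0.03) ** 4
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(frac - expected) <= 3 * se

    def test_field_missingness_rate(self):
        cfg = dt.default_config(
            n_subjects=5000, seed=6, attrition=dt.AttritionSpec(field_missingness=0.1)
        )
        panel, _ = dt.simulate_cohort(cfg)
        panel = dt.simulate_anthropometry(panel, cfg)
        out = dt.apply_attrition(panel, cfg)
        miss = out["haz"].isna().mean()
        assert abs(miss - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / len(out))

    def test_covariate_dependent_dropout(self):
        att = dt.AttritionSpec(dropout=0.05, dropout_logit_shifts={("residence", "urban"): 1.5})
        cfg = dt.default_config(n_subjects=8000, seed=8, attrition=att)
        panel, _ = dt.simulate_cohort(cfg)
        out = dt.apply_attrition(panel, cfg)
        last = out.groupby("subject_id")["round"].max()
        res1 = panel[panel["round"] == 1].set_index("subject_id")["residence"]
        complete = (last == 5).groupby(res1).mean()
        assert complete["urban"] < complete["rural"]
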