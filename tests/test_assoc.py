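"""Logistic model contracts: oracles, invariances, error behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vdrmr.assoc import (CaseControlLogit, ConvergenceError,
                         RankDeficiencyError, SeparationError,
                         fit_interaction_model, fit_logistic, fit_main_model)
from vdrmr.simulate import (CovariateEffects, SimCohortParams,
                            simulate_cohort)


def design_2x2(n11, n10, n01, n00) -> tuple[pd.DataFrame, np.ndarray]:
    """Expand a 2x2 (exposed/unexposed x case/control) table to rows."""
    x = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
    y = np.concatenate([np.ones(n11), np.zeros(n10),
                        np.ones(n01), np.zeros(n00)])
    return pd.DataFrame({"const": 1.0, "x": x}), y


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        design = pd.DataFrame({"const": np.ones(100)})
        y = np.repeat([1, 0], 50)
        table = fit_logistic(design, y)
        assert table.loc["const", "estimate"] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("cells", [
        (30, 70, 20, 80), (5, 12, 9, 40), (100, 50, 60, 200)])
    def test_matches_2x2_closed_form(self, cells):
        n11, n10, n01, n00 = cells
        design, y = design_2x2(*cells)
        table = fit_logistic(design, y)
        log_or = np.log(n11 * n00 / (n10 * n01))
        se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
        assert table.loc["x", "estimate"] == pytest.approx(log_or, abs=1e-6)
        assert table.loc["x", "se"] == pytest.approx(se, abs=1e-6)

    def test_row_duplication_scales_se(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = rng.binomial(1, 1 / (1 + np.exp(-0.5 * x)))
        design = pd.DataFrame({"const": 1.0, "x": x})
        t1 = fit_logistic(design, y)
        t2 = fit_logistic(pd.concat([design, design], ignore_index=True),
                          np.concatenate([y, y]))
        assert np.allclose(t1["estimate"], t2["estimate"], atol=1e-6)
        assert np.allclose(t1["se"] / np.sqrt(2), t2["se"], atol=1e-6)

    def test_rank_deficiency_raises(self):
        design = pd.DataFrame({"const": np.ones(40), "x": np.ones(40)})
        y = np.repeat([1, 0], 20)
        with pytest.raises(RankDeficiencyError):
            fit_logistic(design, y)

    def test_separation_raises(self):
        x = np.concatenate([np.full(20, 1.0), np.full(20, -1.0)])
        y = (x > 0).astype(float)
        with pytest.raises((SeparationError, ConvergenceError)):
            fit_logistic(pd.DataFrame({"const": 1.0, "x": x}), y)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"const": np.ones(10)}), np.ones(10))


class TestModelInvariances:
    def test_affine_covariate_recoding_leaves_slopes(self, sim_cohort):
        giv = sim_cohort.dosages["rsVDR0001"]
        model = CaseControlLogit(sim_cohort, giv_vdr=giv)
        base = model.fit().params
        design2 = model.design.copy()
        design2["pc1"] = design2["pc1"] * 10 + 3  # affine recode
        from vdrmr.assoc import fit_logistic as fl
        recoded = fl(design2, model.outcome)["estimate"]
        assert recoded["giv_vdr"] == pytest.approx(base["giv_vdr"], abs=1e-6)
        assert recoded["sex_F"] == pytest.approx(base["sex_F"], abs=1e-6)

    def test_wald_close_to_lrt_at_large_n(self, sim_cohort):
        import statsmodels.api as sm
        giv = sim_cohort.dosages["rsVDR0001"]
        model = CaseControlLogit(sim_cohort, giv_vdr=giv)
        res = model.fit()
        full = sm.Logit(np.asarray(model.outcome, float),
                        np.asarray(model.design, float)).fit(disp=0)
        reduced_cols = [c for c in model.design.columns if c != "giv_vdr"]
        red = sm.Logit(np.asarray(model.outcome, float),
                       np.asarray(model.design[reduced_cols], float)
                       ).fit(disp=0)
        lrt = 2 * (full.llf - red.llf)
        wald = (res.params["giv_vdr"] / res.bse["giv_vdr"]) ** 2
        assert wald == pytest.approx(lrt, rel=0.15)  # O(1/n) agreement

    def test_constant_giv_rank_deficient(self, sim_cohort):
        const = pd.Series(1.0, index=sim_cohort.dosages.index)
        with pytest.raises(RankDeficiencyError):
            fit_main_model(sim_cohort, const, term="giv_vdr")
        with pytest.raises(RankDeficiencyError):
            fit_interaction_model(sim_cohort,
                                  sim_cohort.dosages["rsVDR0001"], const)


class TestMainModel:
    def test_recovers_simulated_effect(self, sim_cohort):
        # sim_cohort was generated with a log(1.3) dosage effect
        res = fit_main_model(sim_cohort, sim_cohort.dosages["rsVDR0001"],
                             term="giv_vdr")
        lo, hi = np.log(res.or_ci95[0]), np.log(res.or_ci95[1])
        assert lo < np.log(1.3) < hi
        assert res.n_cases == 1500 and res.study_label == "SIM"

    def test_null_wald_p_uniform(self):
        """Under beta = 0 the Wald p of the instrument term is U(0,1)."""
        ps = []
        for rep in range(200):
            cohort = simulate_cohort(SimCohortParams(
                n_cases=250, n_controls=250, seed=10_000 + rep))
            res = fit_main_model(cohort, cohort.dosages["rsVDR0001"],
                                 term="giv_vdr")
            ps.append(res.p_value)
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_standardize_flag_rescales(self, sim_cohort):
        score = sim_cohort.dosages["rsD0001"] * 0.3
        raw = fit_main_model(sim_cohort, score, term="giv_25ohd")
        std = fit_main_model(sim_cohort, score, term="giv_25ohd",
                             standardize_25ohd=True)
        sd = score.std(ddof=1)
        assert std.log_or == pytest.approx(raw.log_or * sd, rel=1e-6)
        # Wald z is invariant to the linear rescaling
        assert std.p_value == pytest.approx(raw.p_value, rel=1e-6)


class TestInteractionModel:
    def test_returns_all_three_terms(self, sim_cohort):
        giv_v = sim_cohort.dosages["rsVDR0001"]
        giv_d = sim_cohort.dosages["rsD0001"] * 0.2
        out = fit_interaction_model(sim_cohort, giv_v, giv_d)
        assert set(out) == {"giv_vdr", "giv_25ohd", "giv_vdr:giv_25ohd"}
        b3 = out["giv_vdr:giv_25ohd"]
        assert b3.se > 0 and 0 < b3.p_value <= 1

    def test_detects_strong_interaction(self):
        params = SimCohortParams(
            n_cases=4000, n_controls=4000, beta_interaction=1.2,
            score_snp_betas=[0.3] * 8, seed=21,
            covariate_effects=CovariateEffects())
        cohort = simulate_cohort(params)
        giv_v = cohort.dosages["rsVDR0001"]
        betas = cohort.attrs["score_snp_betas"]
        giv_d = cohort.dosages[list(betas)].to_numpy() @ np.asarray(
            list(betas.values()))
        out = fit_interaction_model(cohort, giv_v,
                                    pd.Series(giv_d, index=giv_v.index))
        b3 = out["giv_vdr:giv_25ohd"]
        assert b3.p_value < 0.01
        assert b3.log_or > 0

    def test_summary_mentions_cohort(self, sim_cohort):
        giv_v = sim_cohort.dosages["rsVDR0001"]
        giv_d = sim_cohort.dosages["rsD0001"] * 0.2
        model = CaseControlLogit(sim_cohort, giv_vdr=giv_v, giv_25ohd=giv_d,
                                 interaction=True)
        text = model.fit().summary()
        assert "1500 cases" in text and "giv_vdr:giv_25ohd" in text
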