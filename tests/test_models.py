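"""Candidate models: AICc, ranking, degeneracies, recovery, prediction."""

import numpy as np
import pandas as pd
import pytest

from harvestsel.models import (
    ModelSpec,
    SmoothSpec,
    aicc,
    build_candidate_set,
    fit_model,
    predict_curve,
    rank_models,
)


def _linear_dataset(seed=0, n_bear=15, n_year=2, n_day=20, beta_life=0.05,
                    sd_bear=0.4, sd_by=0.2, phi=0.0, sd_resid=0.5):
    """Directly simulated distance-style data with known coefficients."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_bear):
        ub = rng.normal(0, sd_bear)
        life = float(rng.integers(0, 4))
        age = float(rng.integers(4, 15))
        for t in range(n_year):
            ut = rng.normal(0, sd_by)
            rl = life + (n_year - 1 - t)
            e = np.empty(n_day)
            e[0] = rng.normal(0, sd_resid)
            for d in range(1, n_day):
                e[d] = phi * e[d - 1] + rng.normal(0, sd_resid * np.sqrt(1 - phi**2))
            for d in range(n_day):
                jd = d - 10.0
                y = 6.0 + beta_life * rl - 0.002 * jd + 0.005 * age + ub + ut + e[d]
                rows.append(dict(
                    bear_id=f"B{b}", bear_year=f"B{b}_{t}", date=d,
                    log_dist=y, age=age + t, julian_date=jd, road_density=0.8,
                    remaining_lifespan=rl, fate="survived",
                ))
    return pd.DataFrame(rows)


class TestAicc:
    def test_hand_arithmetic(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_converges_to_aic_for_large_n(self):
        assert aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-6)

    def test_always_exceeds_aic(self):
        assert aicc(-50.0, 4, 30) > -2 * -50.0 + 2 * 4

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)


class TestModelSpec:
    def test_fate_and_lifespan_never_cooccur(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", "y", linear_terms=("fate", "remaining_lifespan"))

    def test_by_smooth_requires_main_effect(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", "y", smooth_terms=(SmoothSpec("hour", by="fate"),))


class TestCandidateSets:
    def test_movement_ladder_has_by_fate_smooths(self):
        specs = build_candidate_set("movement", "male")
        fate = next(s for s in specs if "fate" in s.linear_terms)
        by_covs = {sm.cov for sm in fate.smooth_terms if sm.by == "fate"}
        assert by_covs == {"hour", "julian_date"}

    def test_distance_ladder_is_purely_linear(self):
        for spec in build_candidate_set("distance"):
            assert not spec.smooth_terms

    def test_every_candidate_extends_the_intercept_only_spec(self):
        for trait in ("movement", "activity", "distance"):
            specs = build_candidate_set(trait)
            base = specs[0]
            assert not base.linear_terms and not base.smooth_terms
            for s in specs:
                assert set(base.linear_terms) <= set(s.linear_terms)
                assert s.random and s.ar1

    def test_unknown_trait_is_an_error(self):
        with pytest.raises(ValueError):
            build_candidate_set("boldness")


class TestFitModel:
    def test_reduces_to_ols_closed_form(self):
        data = _linear_dataset(seed=2, n_bear=8, n_year=1, n_day=15)
        spec = ModelSpec("ols", "log_dist",
                         linear_terms=("age", "julian_date", "remaining_lifespan"),
                         random=False, ar1=False)
        fit = fit_model(spec, data)
        df = fit._data
        x = np.column_stack([np.ones(len(df)), df["age"], df["julian_date"],
                             df["remaining_lifespan"]])
        beta = np.linalg.solve(x.T @ x, x.T @ df["log_dist"].to_numpy())
        got = fit.coefficients["estimate"].to_numpy()
        assert np.abs(got - beta).max() < 1e-8

    def test_known_slope_recovered_within_two_se(self):
        hits = 0
        for seed in range(20):
            data = _linear_dataset(seed=seed, beta_life=0.05)
            spec = ModelSpec("life", "log_dist",
                             linear_terms=("age", "julian_date", "remaining_lifespan"))
            fit = fit_model(spec, data)
            row = fit.coefficients.set_index("term").loc["remaining_lifespan"]
            hits += abs(row["estimate"] - 0.05) <= 2 * row["se"]
        assert hits >= 18

    def test_ar1_phi_recovered_at_n_5000(self):
        data = _linear_dataset(seed=5, n_bear=20, n_year=2, n_day=125, phi=0.5)
        assert len(data) == 5000
        spec = ModelSpec("phi", "log_dist", linear_terms=("remaining_lifespan",))
        fit = fit_model(spec, data)
        assert 0.3 < fit.ar1_phi < 0.7

    def test_variance_components_recovered(self):
        data = _linear_dataset(seed=9, n_bear=60, n_year=3, n_day=25,
                               sd_bear=0.5, sd_by=0.3, sd_resid=0.6)
        spec = ModelSpec("vc", "log_dist", linear_terms=("remaining_lifespan",))
        fit = fit_model(spec, data)
        assert fit.s2_bear == pytest.approx(0.25, abs=0.1)
        assert fit.s2_bearyear == pytest.approx(0.09, abs=0.05)
        assert fit.s2_resid == pytest.approx(0.36, abs=0.05)

    def test_rank_deficient_design_is_an_error(self):
        data = _linear_dataset(seed=3, n_bear=6, n_year=1, n_day=10)
        data["copy"] = data["age"]
        spec = ModelSpec("bad", "log_dist", linear_terms=("age", "copy"),
                         random=False, ar1=False)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_model(spec, data)

    def test_marginal_r2_zero_for_intercept_only_fixed_part(self):
        data = _linear_dataset(seed=4, n_bear=10, n_year=2, n_day=10)
        fit = fit_model(ModelSpec("null", "log_dist"), data)
        assert fit.marginal_r2 == pytest.approx(0.0, abs=1e-10)


class TestRanking:
    def test_singleton(self):
        data = _linear_dataset(seed=6, n_bear=6, n_year=1, n_day=10)
        fit = fit_model(ModelSpec("only", "log_dist"), data)
        r = rank_models([fit])
        assert r.best.name == "only"
        assert r.table["delta_aicc"].tolist() == [0.0]

    def test_lower_aicc_wins_and_close_ties_prefer_fewer_parameters(self):
        data = _linear_dataset(seed=7, n_bear=10, n_year=2, n_day=15)
        f1 = fit_model(ModelSpec("null", "log_dist"), data)
        f2 = fit_model(ModelSpec("life", "log_dist",
                                 linear_terms=("remaining_lifespan",)), data)
        r = rank_models([f1, f2])
        assert r.table.iloc[0]["aicc"] <= r.table.iloc[1]["aicc"]
        close = r.table[r.table["delta_aicc"] < 2.0]
        assert r.best.k == close["k"].min()

    def test_all_failed_is_an_error(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestPrediction:
    def test_prediction_matches_fitted_fixed_effects_at_training_point(self):
        data = _linear_dataset(seed=8, n_bear=8, n_year=1, n_day=10)
        spec = ModelSpec("life", "log_dist",
                         linear_terms=("age", "remaining_lifespan"))
        fit = fit_model(spec, data)
        row = fit._data.iloc[3]
        curve = predict_curve(fit, "remaining_lifespan",
                              [row["remaining_lifespan"]],
                              holding={"age": row["age"]})
        coef = fit.coefficients.set_index("term")["estimate"]
        expected = (coef["(Intercept)"] + coef["age"] * row["age"]
                    + coef["remaining_lifespan"] * row["remaining_lifespan"])
        assert curve["fit"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_backtransform_exponentiates(self):
        data = _linear_dataset(seed=8, n_bear=8, n_year=1, n_day=10)
        fit = fit_model(ModelSpec("null", "log_dist"), data)
        raw = predict_curve(fit, "julian_date", [0.0])
        exp = predict_curve(fit, "julian_date", [0.0], backtransform=True)
        assert exp["fit"].iloc[0] == pytest.approx(np.exp(raw["fit"].iloc[0]))

    def test_ci_width_shrinks_with_sample_size(self):
        small = _linear_dataset(seed=12, n_bear=10, n_year=1, n_day=5)
        big = _linear_dataset(seed=12, n_bear=10, n_year=1, n_day=50)
        spec = ModelSpec("life", "log_dist", linear_terms=("remaining_lifespan",))
        w = []
        for data in (small, big):
            fit = fit_model(spec, data)
            c = predict_curve(fit, "remaining_lifespan", [1.0])
            w.append(float(c["hi"].iloc[0] - c["lo"].iloc[0]))
        assert w[1] < w[0]

    def test_extrapolation_warns(self):
        data = _linear_dataset(seed=8, n_bear=8, n_year=1, n_day=10)
        spec = ModelSpec("life", "log_dist", linear_terms=("remaining_lifespan",))
        fit = fit_model(spec, data)
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_curve(fit, "remaining_lifespan", [99.0])


def test_smooth_fit_recovers_a_known_nonlinear_shape():
    """A quadratic diel signal fit with a penalized smooth: the fitted curve
    tracks the truth and the smooth spends more than one degree of freedom."""
    rng = np.random.default_rng(21)
    rows = []
    for b in range(12):
        ub = rng.normal(0, 0.3)
        for d in range(30):
            for h in range(2, 12):
                rows.append(dict(
                    bear_id=f"B{b}", bear_year=f"B{b}_0", date=d, hour=float(h),
                    log_rate=4.0 - 0.08 * (h - 6.0) ** 2 + ub + rng.normal(0, 0.4),
                ))
    data = pd.DataFrame(rows)
    spec = ModelSpec("sm", "log_rate", smooth_terms=(SmoothSpec("hour"),), ar1=False)
    fit = fit_model(spec, data)
    edf = fit.smooths.set_index("term").loc["s(hour)", "edf"]
    assert edf > 1.5
    grid = np.arange(2.0, 12.0)
    curve = predict_curve(fit, "hour", grid)
    truth = 4.0 - 0.08 * (grid - 6.0) ** 2
    assert np.corrcoef(curve["fit"], truth)[0, 1] > 0.99
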