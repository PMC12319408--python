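import numpy as np
import pandas as pd
import pytest

from respicall.errors import InsufficientDataError
from respicall.lmm import LmmResult
from respicall.simulate import (
    CallSimParams,
    CohortParams,
    simulate_calls,
    simulate_cohort,
)
from respicall.calls import features_table
from respicall.stats import (
    CALL_TRAITS,
    consistency_analysis,
    fit_call_models,
    fit_rmr_model,
    repeatability,
)


def _measured(trials: pd.DataFrame) -> pd.DataFrame:
    """Treat true RMR as the measured value (no trace noise)."""
    return trials.rename(columns={"true_rmr_ml_o2_h": "rmr_ml_o2_h"})


@pytest.fixture(scope="module")
def cohort():
    ind, trials = simulate_cohort(CohortParams(), rng=11)
    return ind, _measured(trials)


class TestRmrModel:
    def test_recovers_generating_slopes(self, cohort):
        _, trials = cohort
        res = fit_rmr_model(trials)
        est = dict(zip(res.terms, res.beta))
        se = dict(zip(res.terms, res.se))
        assert abs(est["calendar_day"] - (-0.01)) < 2 * se["calendar_day"]
        assert abs(est["mass_g"] - 0.18) < 2 * se["mass_g"]
        assert abs(est["year_2024"] - (-0.24)) < 2 * se["year_2024"]

    def test_quadratic_variant_has_extra_term(self, cohort):
        _, trials = cohort
        res = fit_rmr_model(trials, variant="quadratic-day")
        assert "calendar_day_sq" in res.terms
        # data are generated linear in day, so the quadratic term is null
        p = dict(zip(res.terms, res.pvalues))["calendar_day_sq"]
        assert p > 0.05

    def test_log10_variant(self, cohort):
        _, trials = cohort
        res = fit_rmr_model(trials, variant="log10")
        assert "log10_mass_g" in res.terms
        est = dict(zip(res.terms, res.beta))
        assert est["log10_mass_g"] > 0  # RMR increases with mass

    def test_unknown_variant(self, cohort):
        with pytest.raises(ValueError):
            fit_rmr_model(cohort[1], variant="cubic")


@pytest.fixture(scope="module")
def features():
    ind, trials = simulate_cohort(CohortParams(), rng=21)
    events, recordings = simulate_calls(trials, ind, CallSimParams(), rng=22)
    feats = features_table(events, recordings)
    feats = feats.merge(
        recordings[
            ["recording_id", "year", "calendar_day", "mass_g",
             "true_rmr_ml_o2_h"]
        ],
        on="recording_id",
    ).rename(columns={"true_rmr_ml_o2_h": "rmr_ml_o2_h"})
    return feats


class TestCallModels:
    def test_five_models_fit(self, features):
        fits = fit_call_models(features)
        assert set(fits) == set(CALL_TRAITS)
        for res in fits.values():
            assert isinstance(res, LmmResult)
            assert res.v_res > 0

    def test_mass_slope_recovered_for_dominant_frequency(self, features):
        res = fit_call_models(features)["dominant_frequency_hz"]
        est = dict(zip(res.terms, res.beta))["mass_g"]
        se = dict(zip(res.terms, res.se))["mass_g"]
        assert abs(est - (-63.96)) < 2 * se

    def test_null_rmr_effect_not_significant_typically(self, features):
        # single-replicate sanity check; the full type-I simulation lives
        # in the acceptance suite
        res = fit_call_models(features)["call_duration_s"]
        p = dict(zip(res.terms, res.pvalues))["rmr_ml_o2_h"]
        assert 0.0 <= p <= 1.0


class TestRepeatability:
    def test_point_estimate_formula(self):
        res = LmmResult(
            terms=["(Intercept)"], beta=np.zeros(1), se=np.ones(1),
            tvalues=np.zeros(1), pvalues=np.ones(1),
            v_ind=0.4, v_res=0.6, loglik=0.0, loglik_ml=0.0,
            n_obs=10, n_groups=5, reml=True, boundary=False,
        )
        assert res.repeatability == pytest.approx(0.4)

    def test_perfect_grouping_gives_r_near_one(self):
        rows = []
        for i in range(20):
            for _ in range(3):
                rows.append({"individual_id": f"i{i}", "y": float(i)})
        df = pd.DataFrame(rows)
        est = repeatability(df, "y", [], n_boot=20, seed=1)
        assert est.r > 0.99

    def test_estimate_on_default_cohort(self, cohort):
        _, trials = cohort
        est = repeatability(
            trials, "rmr_ml_o2_h", ["mass_g", "calendar_day"], n_boot=100, seed=5
        )
        assert 0.0 <= est.ci_low <= est.r <= est.ci_high <= 1.0
        assert est.n_obs == len(trials)

    def test_seed_required(self, cohort):
        with pytest.raises(ValueError):
            repeatability(cohort[1], "rmr_ml_o2_h", ["mass_g"], n_boot=10)

    def test_no_repeats_rejected(self):
        df = pd.DataFrame(
            {"individual_id": ["a", "b", "c"], "y": [1.0, 2.0, 3.0], "x": 0.0}
        )
        with pytest.raises(InsufficientDataError):
            repeatability(df, "y", ["x"], n_boot=10, seed=1)


class TestConsistency:
    def test_identical_rmr_gives_zero_slope(self):
        rows = []
        for i in range(10):
            for day in (150, 151 + i):
                rows.append(
                    {
                        "individual_id": f"i{i}",
                        "year": 2023,
                        "calendar_day": day,
                        "rmr_ml_o2_h": 0.9,
                    }
                )
        res = consistency_analysis(pd.DataFrame(rows))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.n == 10

    def test_deterministic_decline_contrast(self, rng):
        """RMR tracks calendar day exactly: the raw slope is the decline
        rate; the day-residualized slope vanishes."""
        rows = []
        for i in range(20):
            d0 = int(rng.integers(130, 180))
            gap = int(rng.integers(5, 40))
            for day in (d0, d0 + gap):
                rows.append(
                    {
                        "individual_id": f"i{i}",
                        "year": 2023,
                        "calendar_day": day,
                        "rmr_ml_o2_h": 3.0 - 0.01 * day,
                    }
                )
        df = pd.DataFrame(rows)
        raw = consistency_analysis(df)
        resid = consistency_analysis(df, use_day_residuals=True)
        assert raw.slope == pytest.approx(0.01, abs=1e-9)
        assert abs(resid.slope) < 1e-9

    def test_cross_year_pairs_excluded(self):
        rows = [
            {"individual_id": "a", "year": 2023, "calendar_day": 150, "rmr_ml_o2_h": 1.0},
            {"individual_id": "a", "year": 2024, "calendar_day": 160, "rmr_ml_o2_h": 2.0},
        ]
        for i in range(5):
            for day in (150, 160 + 2 * i):
                rows.append(
                    {
                        "individual_id": f"b{i}",
                        "year": 2023,
                        "calendar_day": day,
                        "rmr_ml_o2_h": 1.0,
                    }
                )
        res = consistency_analysis(pd.DataFrame(rows))
        assert res.n == 5  # individual 'a' (cross-year only) dropped

    def test_three_captures_use_first_and_last(self):
        rows = []
        for i in range(5):
            for day, r in ((140, 1.0), (150, 5.0), (170 + i, 1.0 + 0.01 * i)):
                rows.append(
                    {
                        "individual_id": f"i{i}",
                        "year": 2023,
                        "calendar_day": day,
                        "rmr_ml_o2_h": r,
                    }
                )
        res = consistency_analysis(pd.DataFrame(rows))
        pairs = res.pairs
        assert (pairs["day_first"] == 140).all()
        assert (pairs["day_last"] >= 170).all()
        assert (pairs["day_first"] == 140).all()

    def test_too_few_individuals(self):
        rows = [
            {"individual_id": "a", "year": 2023, "calendar_day": d, "rmr_ml_o2_h": 1.0}
            for d in (150, 160)
        ]
        with pytest.raises(InsufficientDataError):
            consistency_analysis(pd.DataFrame(rows))
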