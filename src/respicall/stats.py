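"""Call-trait and RMR mixed models, repeatability, and RMR consistency.

All models share the same structure: Gaussian response, fixed covariates,
and a random intercept for individual identity.  Repeatability is the
adjusted intraclass correlation ``R = V_ind / (V_ind + V_res)`` from the
covariate-conditioned REML fit, with a parametric-bootstrap percentile CI
and a boundary-corrected likelihood-ratio test of ``V_ind = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from respicall.errors import InsufficientDataError
from respicall.lmm import LmmResult, fit_lmm, lrt_random_intercept

CALL_TRAITS = (
    "call_duration_s",
    "pulse_number",
    "dominant_frequency_hz",
    "call_rate_per_s",
    "call_effort",
)

REFERENCE_YEAR = 2023


@dataclass
class RepeatabilityEstimate:
    """Adjusted repeatability with bootstrap CI and boundary LRT."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    lrt: float
    v_ind: float
    v_res: float
    n_boot: int
    seed: int
    n_obs: int
    n_groups: int

    def as_dict(self) -> dict:
        return {
            "R": self.r,
            "ci_95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "lrt": self.lrt,
            "v_ind": self.v_ind,
            "v_res": self.v_res,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


@dataclass
class ConsistencyResult:
    """OLS of |RMR_last - RMR_first| on the day gap between those trials."""

    slope: float
    intercept: float
    t: float
    p: float
    n: int
    residualized: bool
    pairs: pd.DataFrame = field(repr=False, default=None)


def _design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Design matrix with intercept and year dummy (reference 2023)."""
    X = pd.DataFrame(index=df.index)
    X["(Intercept)"] = 1.0
    for term in terms:
        if term == "year":
            X["year_2024"] = (df["year"].astype(int) != REFERENCE_YEAR).astype(float)
        else:
            X[term] = pd.to_numeric(df[term]).astype(float)
    return X


# ---------------------------------------------------------------------------
# Table-1-style call-trait models
# ---------------------------------------------------------------------------

def fit_call_models(
    df: pd.DataFrame, traits: tuple[str, ...] = CALL_TRAITS
) -> dict[str, LmmResult]:
    """One mixed model per call trait.

    ``df`` holds one row per recording: the five trait means, plus
    ``rmr_ml_o2_h`` (absolute, not mass-divided), ``mass_g``, ``temp_c``,
    ``calendar_day``, ``year`` and ``individual_id``.  Singular fits
    (V_ind at the zero boundary) are reported with ``boundary=True``, not
    raised.
    """
    covars = ["rmr_ml_o2_h", "temp_c", "calendar_day", "mass_g", "year"]
    data = df.dropna(subset=list(traits) + covars + ["individual_id"])
    X = _design(data, covars)
    results = {}
    for trait in traits:
        results[trait] = fit_lmm(
            data[trait].to_numpy(dtype=float),
            X,
            data["individual_id"].to_numpy(),
        )
    return results


# ---------------------------------------------------------------------------
# Table-2-style RMR model
# ---------------------------------------------------------------------------

def fit_rmr_model(df: pd.DataFrame, variant: str = "linear") -> LmmResult:
    """Mixed model of per-trial RMR.

    Variants: ``linear`` (calendar day + mass + year), ``quadratic-day``
    (adds day^2), ``log10`` (log10 RMR on log10 mass + day + year).
    """
    data = df.dropna(subset=["rmr_ml_o2_h", "calendar_day", "mass_g", "year"]).copy()
    if variant == "linear":
        X = _design(data, ["calendar_day", "mass_g", "year"])
        y = data["rmr_ml_o2_h"].to_numpy(dtype=float)
    elif variant == "quadratic-day":
        X = _design(data, ["calendar_day", "mass_g", "year"])
        X["calendar_day_sq"] = pd.to_numeric(data["calendar_day"]).astype(float) ** 2
        y = data["rmr_ml_o2_h"].to_numpy(dtype=float)
    elif variant == "log10":
        data["log10_mass_g"] = np.log10(data["mass_g"].astype(float))
        X = _design(data, ["calendar_day", "log10_mass_g", "year"])
        y = np.log10(data["rmr_ml_o2_h"].to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return fit_lmm(y, X, data["individual_id"].to_numpy())


# ---------------------------------------------------------------------------
# Repeatability
# ---------------------------------------------------------------------------

def repeatability(
    df: pd.DataFrame,
    response: str,
    covariates: list[str],
    group: str = "individual_id",
    n_boot: int = 1000,
    seed: int | None = None,
) -> RepeatabilityEstimate:
    """Adjusted repeatability of ``response`` conditioned on ``covariates``.

    Point estimate from the REML fit; 95% CI from a parametric bootstrap
    (simulate new responses from the fitted model, refit, take the 2.5/97.5
    percentiles of R); p-value from the boundary-mixture LRT of V_ind = 0.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the parametric bootstrap")
    data = df.dropna(subset=[response] + covariates + [group])
    groups = data[group].to_numpy()
    uniq, inv = np.unique(groups, return_inverse=True)
    counts = np.bincount(inv)
    if len(uniq) < 2 or counts.max() < 2:
        raise InsufficientDataError(
            "repeatability needs >= 2 individuals and repeated measures"
        )

    X = _design(data, covariates)
    y = data[response].to_numpy(dtype=float)
    fit = fit_lmm(y, X, groups)

    lrt, p_value = lrt_random_intercept(y, X, groups)

    rng = np.random.default_rng(seed)
    Xm = X.to_numpy(dtype=float)
    mu = Xm @ fit.beta
    sd_ind = np.sqrt(fit.v_ind)
    sd_res = np.sqrt(fit.v_res)
    r_boot = np.empty(n_boot)
    for b in range(n_boot):
        b_i = rng.normal(0.0, sd_ind, size=len(uniq))
        y_star = mu + b_i[inv] + rng.normal(0.0, sd_res, size=len(y))
        r_boot[b] = fit_lmm(y_star, Xm, inv).repeatability
    ci_low, ci_high = np.percentile(r_boot, [2.5, 97.5])

    return RepeatabilityEstimate(
        r=fit.repeatability,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p_value,
        lrt=lrt,
        v_ind=fit.v_ind,
        v_res=fit.v_res,
        n_boot=n_boot,
        seed=seed,
        n_obs=fit.n_obs,
        n_groups=fit.n_groups,
    )


def call_trait_repeatability(
    df: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> dict[str, RepeatabilityEstimate]:
    """Repeatability of each per-recording call-trait mean, temperature-adjusted."""
    return {
        trait: repeatability(
            df, trait, ["temp_c"], n_boot=n_boot, seed=seed
        )
        for trait in CALL_TRAITS
    }


# ---------------------------------------------------------------------------
# First/last consistency of RMR
# ---------------------------------------------------------------------------

def _first_last_pairs(trials: pd.DataFrame) -> pd.DataFrame:
    """Temporal first and last within-year trial per repeat individual.

    Cross-year pairs are excluded; when an individual has trials in both
    years, the year containing >= 2 trials is kept and the stray year
    dropped.
    """
    rows = []
    for ind, g in trials.groupby("individual_id"):
        year_groups = [
            gy.sort_values("calendar_day")
            for _, gy in g.groupby("year")
            if len(gy) >= 2
        ]
        if not year_groups:
            continue
        # at most one qualifying year in practice; prefer the larger gap
        gy = max(
            year_groups,
            key=lambda x: x["calendar_day"].iloc[-1] - x["calendar_day"].iloc[0],
        )
        first, last = gy.iloc[0], gy.iloc[-1]
        rows.append(
            {
                "individual_id": ind,
                "year": first["year"],
                "day_first": first["calendar_day"],
                "day_last": last["calendar_day"],
                "gap_days": last["calendar_day"] - first["calendar_day"],
                "rmr_first": first["rmr_ml_o2_h"],
                "rmr_last": last["rmr_ml_o2_h"],
            }
        )
    return pd.DataFrame(rows)


def consistency_analysis(
    trials: pd.DataFrame, use_day_residuals: bool = False
) -> ConsistencyResult:
    """Regress |RMR_last - RMR_first| on days between first and last trial.

    The residualized variant first removes the seasonal trend (simple OLS
    of RMR on calendar day across all trials) and differences the
    residuals instead, testing whether consistency decays with time after
    accounting for the within-season decline.
    """
    trials = trials.dropna(subset=["rmr_ml_o2_h", "calendar_day", "year"]).copy()
    if use_day_residuals:
        lr = sps.linregress(
            trials["calendar_day"].astype(float), trials["rmr_ml_o2_h"].astype(float)
        )
        trials["rmr_ml_o2_h"] = trials["rmr_ml_o2_h"] - (
            lr.intercept + lr.slope * trials["calendar_day"].astype(float)
        )

    pairs = _first_last_pairs(trials)
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"only {len(pairs)} repeat-capture individuals; need >= 3"
        )
    dep = (pairs["rmr_last"] - pairs["rmr_first"]).abs().to_numpy(dtype=float)
    gap = pairs["gap_days"].to_numpy(dtype=float)
    if np.ptp(gap) == 0:
        raise InsufficientDataError("all day gaps identical; slope undefined")
    reg = sps.linregress(gap, dep)
    n = len(pairs)
    if reg.stderr > 0:
        t = reg.slope / reg.stderr
    else:
        t = 0.0 if reg.slope == 0 else np.inf
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return ConsistencyResult(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        t=float(t),
        p=float(p),
        n=n,
        residualized=use_day_residuals,
        pairs=pairs,
    )
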