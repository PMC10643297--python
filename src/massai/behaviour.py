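"""Farmer decision models: double-hurdle adoption/intensity and crop yield.

Each soil-fertility-management practice (inorganic fertilizer, manure,
legumes, conservation structures) is decided per plot-year through a
double-hurdle model: a logit first hurdle gives the probability of adopting
the practice on the plot, and a GLM second hurdle gives the intensity
(amount, or land share) conditional on adoption.  Crop yields come from a
bounded GLM on the same predictor set.  The subsidy share of the running
policy scenario enters these models as an ordinary predictor, which is how
policy reaches the nutrient ledger.

Between-replication stochasticity is expressed by drawing every coefficient
within its estimated confidence interval (truncated normal by default,
uniform optionally) once per replication; within a replication the drawn
coefficients are fixed, so run-to-run variation reflects parameter
uncertainty rather than yearly noise.

The estimation counterpart, :func:`fit_double_hurdle`, recovers a
coefficient table pair from observed decisions (logit on the adoption
indicator, log-linear model on positive amounts, Wald intervals) and is used
to verify parameter recovery on synthetic decision data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .ecology import Param

__all__ = [
    "MODEL_NAMES",
    "CoefficientTable",
    "draw_within_bounds",
    "draw_coefficients",
    "assemble_context",
    "hurdle_decision",
    "decide_all",
    "predict_yield",
    "winsorise_drift_adjust",
    "fit_double_hurdle",
]

#: behavioural sub-models recognised by the engine
MODEL_NAMES = ("adopt_fert", "qty_fert", "adopt_manure", "qty_manure",
               "adopt_legume", "share_legume", "adopt_swc",
               "yield_maize", "yield_legume")

_LINKS = {
    "logit": expit,
    "log": np.exp,
    "identity": lambda x: x,
}


@dataclass
class CoefficientTable:
    """Named predictors -> (estimate, CI bounds) for one behavioural model.

    ``link`` is the inverse-link applied to the linear predictor; ``bounds``
    clamp the predicted outcome (adoption probabilities are naturally bounded
    by the logit; amounts and yields get explicit caps).
    """

    name: str
    coef: Mapping[str, Param]
    link: str = "logit"
    bounds: tuple = (0.0, np.inf)

    def __post_init__(self):
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        lo, hi = self.bounds
        if not lo <= hi:
            raise ValueError("bounds.min must be <= bounds.max")
        self.coef = dict(self.coef)

    @property
    def predictors(self) -> tuple:
        return tuple(self.coef)

    def estimates(self) -> pd.Series:
        return pd.Series({k: p.estimate for k, p in self.coef.items()})

    def linear_predictor(self, ctx: pd.DataFrame, coefs: pd.Series | None = None):
        """beta' x over the rows of the context frame."""
        coefs = self.estimates() if coefs is None else coefs
        missing = [p for p in coefs.index if p not in ctx.columns]
        if missing:
            raise KeyError(
                f"context is missing predictor(s) {missing} required by model "
                f"{self.name!r}")
        X = ctx[list(coefs.index)].to_numpy(dtype=float)
        return X @ coefs.to_numpy(dtype=float)

    def predict(self, ctx: pd.DataFrame, coefs: pd.Series | None = None):
        """Inverse-link of the linear predictor, clamped to bounds."""
        eta = self.linear_predictor(ctx, coefs)
        return np.clip(_LINKS[self.link](eta), self.bounds[0], self.bounds[1])


def draw_within_bounds(estimate: float, lo: float, hi: float,
                       rng: np.random.Generator, how: str = "truncnorm") -> float:
    """One stochastic realisation of a coefficient within its CI.

    ``truncnorm``: Normal(estimate, (hi-lo)/(2*1.96)) truncated to [lo, hi]
    (a 95 % interval maps back to the implied standard error).  ``uniform``:
    flat on [lo, hi].  Degenerate intervals return the estimate.
    """
    if hi <= lo:
        return estimate
    if how == "uniform":
        return float(rng.uniform(lo, hi))
    if how != "truncnorm":
        raise ValueError(f"unknown draw rule {how!r}")
    sd = (hi - lo) / (2 * 1.96)
    a, b = (lo - estimate) / sd, (hi - estimate) / sd
    return float(stats.truncnorm.rvs(a, b, loc=estimate, scale=sd, random_state=rng))


def draw_coefficients(table: CoefficientTable, rng: np.random.Generator,
                      how: str = "truncnorm") -> pd.Series:
    """Realise every coefficient of a table for one replication."""
    return pd.Series({name: draw_within_bounds(p.estimate, p.lo, p.hi, rng, how)
                      for name, p in table.coef.items()})


def assemble_context(households: pd.DataFrame, plots: pd.DataFrame,
                     s_t: float, legume_planted=None) -> pd.DataFrame:
    """Build the per-plot predictor frame for the decision and yield models.

    One row per plot (aligned with ``plots``), merging household attributes
    onto plots, adding the intercept, the scenario subsidy share ``s_t``,
    farm-type dummies and the cross-practice linkage flag ``legume_planted``
    (legume decisions feed the fertilizer models).
    """
    hh_cols = ["household_id", "farm_type", "head_age", "head_gender",
               "education", "labour", "income", "livestock",
               "group_membership", "transport_access", "communication_access"]
    ctx = plots.merge(households[hh_cols], on="household_id", how="left",
                      validate="many_to_one")
    if ctx["farm_type"].isna().any():
        orphans = plots.loc[ctx["farm_type"].isna(), "plot_id"].tolist()
        raise ValueError(f"plots reference unknown households: {orphans}")
    ctx = ctx.copy()
    ctx["const"] = 1.0
    ctx["subsidy"] = float(s_t)
    ctx["farm_type2"] = (ctx["farm_type"] == 2).astype(float)
    ctx["farm_type3"] = (ctx["farm_type"] == 3).astype(float)
    ctx["log_income"] = np.log1p(ctx["income"].astype(float))
    for col in ("group_membership", "transport_access", "communication_access",
                "swc_flag", "head_gender"):
        if col in ctx:
            ctx[col] = ctx[col].astype(float)
    ctx["legume_planted"] = (np.zeros(len(ctx)) if legume_planted is None
                             else np.asarray(legume_planted, dtype=float))
    ctx.index = plots.index
    return ctx


def hurdle_decision(ctx: pd.DataFrame, adopt_table: CoefficientTable,
                    qty_table: CoefficientTable, rng: np.random.Generator,
                    adopt_coefs: pd.Series | None = None,
                    qty_coefs: pd.Series | None = None):
    """Two-hurdle decision over the rows of a context frame.

    First hurdle: adoption probability p = logistic(beta1' x), realised by a
    Bernoulli draw so that population adoption rates match the predicted
    probabilities in expectation.  Second hurdle: amount = inverse-link of
    beta2' x, clamped to the quantity model's bounds.  Non-adopters get 0.

    Returns ``(amount, adopted, p)`` arrays.
    """
    p = expit(adopt_table.linear_predictor(ctx, adopt_coefs))
    adopted = rng.random(len(ctx)) < p
    amount = qty_table.predict(ctx, qty_coefs)
    amount = np.where(adopted, amount, 0.0)
    return amount, adopted, p


def decide_all(households: pd.DataFrame, plots: pd.DataFrame, s_t: float,
               tables: Mapping[str, CoefficientTable], rng: np.random.Generator,
               realised: Mapping[str, pd.Series] | None = None) -> pd.DataFrame:
    """All soil-fertility-management decisions for every plot, one year.

    Evaluation order is legume -> fertilizer -> manure -> conservation, so
    the legume linkage flag exists when the fertilizer models need it.
    Returns a frame aligned with ``plots``: fert_kg_ha, subsidised_share,
    manure_kg_ha, legume_fraction, residue_retained_fraction, swc_flag.
    """
    realised = realised or {}

    def coefs(name):
        return realised.get(name)

    ctx = assemble_context(households, plots, s_t)

    legume_frac = np.zeros(len(plots))
    if "adopt_legume" in tables:
        share, planted, _ = hurdle_decision(
            ctx, tables["adopt_legume"], tables["share_legume"], rng,
            coefs("adopt_legume"), coefs("share_legume"))
        legume_frac = np.clip(share, 0.0, 1.0)
        ctx["legume_planted"] = planted.astype(float)

    fert = np.zeros(len(plots))
    if "adopt_fert" in tables:
        fert, _, _ = hurdle_decision(
            ctx, tables["adopt_fert"], tables["qty_fert"], rng,
            coefs("adopt_fert"), coefs("qty_fert"))

    manure = np.zeros(len(plots))
    if "adopt_manure" in tables:
        manure, _, _ = hurdle_decision(
            ctx, tables["adopt_manure"], tables["qty_manure"], rng,
            coefs("adopt_manure"), coefs("qty_manure"))

    if "adopt_swc" in tables:
        p_swc = expit(tables["adopt_swc"].linear_predictor(ctx, coefs("adopt_swc")))
        new_swc = rng.random(len(plots)) < p_swc
        swc = plots["swc_flag"].to_numpy(dtype=bool) | new_swc  # structures persist
    else:
        swc = plots["swc_flag"].to_numpy(dtype=bool)

    return pd.DataFrame({
        "fert_kg_ha": fert,
        "subsidised_share": np.where(fert > 0, float(s_t), 0.0),
        "manure_kg_ha": manure,
        "legume_fraction": legume_frac,
        "residue_retained_fraction": plots["residue_retained_fraction"].to_numpy(dtype=float),
        "swc_flag": swc,
    }, index=plots.index)


def predict_yield(ctx: pd.DataFrame, table: CoefficientTable,
                  coefs: pd.Series | None = None):
    """Bounded GLM yield prediction (kg ha-1) over the context rows."""
    return table.predict(ctx, coefs)


def winsorise_drift_adjust(predictions, baseline, limits=(1.0, 99.0),
                           predictions_t0=None):
    """Pull model predictions back to baseline real-farm conditions.

    Values are clipped to the [p_lo, p_hi] percentiles of the baseline
    (winsorisation), then rescaled by the model-drift coefficient
    mean(baseline) / mean(first-year predictions).  ``predictions_t0``
    defaults to ``predictions`` itself (the usual case of adjusting the
    first simulated year, then reusing the same drift for later years).

    Returns ``(adjusted, drift)``.
    """
    pred = np.asarray(predictions, dtype=float)
    base = np.asarray(baseline, dtype=float)
    lo, hi = np.percentile(base, limits)
    clipped = np.clip(pred, lo, hi)
    t0 = pred if predictions_t0 is None else np.asarray(predictions_t0, dtype=float)
    m = np.mean(t0)
    drift = float(np.mean(base) / m) if m != 0 else 1.0
    return clipped * drift, drift


def _wald_params(params: pd.Series, conf: pd.DataFrame) -> dict:
    out = {}
    for name in params.index:
        lo, hi = float(conf.loc[name, 0]), float(conf.loc[name, 1])
        out[name] = Param(float(params[name]), min(lo, float(params[name])),
                          max(hi, float(params[name])))
    return out


def fit_double_hurdle(data: pd.DataFrame, predictors: Sequence[str],
                      amount_col: str = "amount", name: str = "fert",
                      min_obs: int = 50):
    """Estimate a double-hurdle pair from observed plot-year decisions.

    First hurdle: logit of the adoption indicator (amount > 0) on the
    predictors.  Second hurdle: linear model on log(amount) over adopters
    (the log-link intensity GLM under log-normal errors).  Both return Wald
    95 % confidence bounds in the coefficient tables.

    Raises ``ValueError`` on too few observations or perfect separation.
    """
    if len(data) < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {len(data)}")
    missing = [p for p in predictors if p not in data.columns]
    if missing:
        raise KeyError(f"data is missing predictor(s) {missing}")
    X = data[list(predictors)].to_numpy(dtype=float)
    amount = data[amount_col].to_numpy(dtype=float)
    adopted = (amount > 0).astype(float)
    if adopted.all() or not adopted.any():
        raise ValueError("adoption indicator is constant; cannot fit the first hurdle")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            logit_res = sm.Logit(adopted, X).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ValueError(f"perfect separation in adoption model: {exc}") from exc
    fitted = logit_res.predict(X)
    if np.all(np.abs(fitted - adopted) < 1e-6) or np.any(np.abs(logit_res.params) > 50):
        raise ValueError("perfect separation in adoption model: the predictors "
                         "classify adoption exactly")
    conf1 = pd.DataFrame(logit_res.conf_int(),
                         index=list(predictors))
    adopt_table = CoefficientTable(
        f"adopt_{name}",
        _wald_params(pd.Series(logit_res.params, index=list(predictors)), conf1),
        link="logit", bounds=(0.0, 1.0))

    pos = amount > 0
    if pos.sum() < len(predictors) + 2:
        raise ValueError("too few adopters to fit the intensity model")
    ols_res = sm.OLS(np.log(amount[pos]), X[pos]).fit()
    conf2 = pd.DataFrame(ols_res.conf_int(), index=list(predictors))
    qty_table = CoefficientTable(
        f"qty_{name}",
        _wald_params(pd.Series(ols_res.params, index=list(predictors)), conf2),
        link="log", bounds=(0.0, float(np.inf)))
    return adopt_table, qty_table
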