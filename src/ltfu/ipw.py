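"""Inverse-probability-of-follow-up weighting.

Responders are weighted by the reciprocal of their modeled probability of
returning the 2-year questionnaire, creating a pseudo-population that stands
for the full surviving cohort.  The pipeline is: (1) screen candidate
predictors by their region-adjusted bivariate association with follow-up at a
liberal threshold (p <= 0.2 by default, so variables associated with follow-up
only conditionally on others still get a chance to enter); (2) fit a
multivariable logistic response model on the retained predictors; (3) estimate
the weighted prevalence with a robust variance that treats the weights as
fixed.  A second variant imputes missing predictor values first (the outcome
stays out of that imputation entirely) and pools the per-imputation weighted
estimates by Rubin's rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .attrition import association_scan
from .mice import ImputedDatasets
from .pooling import PooledEstimate, rubin_pool
from .simulate import CohortTable

__all__ = [
    "IpwConfig",
    "WeightSet",
    "screen_predictors",
    "fit_weights",
    "weighted_prevalence",
    "ipw_complete_case",
    "ipw_on_imputed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IpwConfig:
    """Screening threshold, optional weight truncation, variance estimator."""

    screening_alpha: float = 0.2
    weight_truncation: float | None = None   # percentile in (50, 100]
    variance_method: str = "sandwich"        # or "bootstrap"
    n_boot: int = 200
    seed: int | None = None
    stabilized: bool = False                 # marginal-probability numerator

    def __post_init__(self):
        if not 0.0 < self.screening_alpha <= 1.0:
            raise ValueError("screening_alpha must be in (0, 1]")
        if self.weight_truncation is not None and not 50.0 < self.weight_truncation <= 100.0:
            raise ValueError("weight_truncation percentile must be in (50, 100]")
        if self.variance_method not in ("sandwich", "bootstrap"):
            raise ValueError("variance_method must be 'sandwich' or 'bootstrap'")


@dataclass
class WeightSet:
    """Per-responder inverse-probability weights plus the fitted model."""

    weights: pd.Series                 # indexed by cohort row label, responders only
    fitted_probs: pd.Series            # P(follow-up) for all rows used in the fit
    retained: list[str]
    params: np.ndarray
    param_names: list[str]
    diagnostics: dict = field(default_factory=dict)

    @property
    def effective_sample_size(self) -> float:
        w = self.weights.to_numpy()
        return float(w.sum() ** 2 / (w ** 2).sum())


def screen_predictors(table: CohortTable, candidates: list[str] | None = None,
                      alpha: float = 0.2) -> list[str]:
    """Candidates whose region-adjusted association with follow-up has p <= alpha.

    Region itself is always retained.  An empty retained set falls back to a
    region-only response model with a warning.
    """
    candidates = candidates if candidates is not None else table.covariate_names
    rows = association_scan(table, target="followup", factors=candidates)
    retained = [r.factor for r in rows if np.isfinite(r.p_value) and r.p_value <= alpha]
    if not retained:
        warnings.warn("no predictor passed screening: falling back to a region-only response model")
    return retained


def _design(df: pd.DataFrame, retained: list[str], covariates: dict, regions) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["const"]
    reg = pd.get_dummies(pd.Categorical(df["region"], categories=list(regions)),
                         drop_first=True, dtype=float)
    for c in reg.columns:
        if reg[c].std() > 0:
            cols.append(reg[c].to_numpy())
            names.append(f"region[{c}]")
    for name in retained:
        levels = [lv for lv in covariates[name] if (df[name] == lv).any()]
        dum = pd.get_dummies(pd.Categorical(df[name], categories=levels),
                             drop_first=True, dtype=float)
        for c in dum.columns:
            cols.append(dum[c].to_numpy())
            names.append(f"{name}[{c}]")
    return np.column_stack(cols), names


def fit_weights(table: CohortTable, retained: list[str],
                config: IpwConfig = IpwConfig()) -> WeightSet:
    """ML logistic response model on complete rows; responder weights 1/p-hat."""
    df = table.df
    complete = df[retained].notna().all(axis=1) if retained else pd.Series(True, index=df.index)
    sub = df.loc[complete]
    X, names = _design(sub, retained, table.covariates, table.regions)
    y = sub["followed_up"].to_numpy(dtype=float)
    if y.min() == y.max():
        # degenerate cohort (e.g. full response): probability 1, unit weights
        probs = pd.Series(1.0, index=sub.index)
        resp_idx = sub.index[sub["followed_up"] == 1]
        w = pd.Series(1.0, index=resp_idx)
        diagnostics = {"n_fit": int(len(sub)), "n_responders": int(len(w)),
                       "min_weight": 1.0, "max_weight": 1.0,
                       "sum_weights": float(len(w)),
                       "effective_sample_size": float(len(w)), "converged": True}
        return WeightSet(weights=w, fitted_probs=probs, retained=retained,
                         params=np.zeros(X.shape[1]), param_names=names,
                         diagnostics=diagnostics)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"response model did not converge: {res.mle_retvals}")
    probs = pd.Series(res.predict(X), index=sub.index)
    resp_idx = sub.index[sub["followed_up"] == 1]
    p_resp = probs.loc[resp_idx]
    if (p_resp < 1e-6).any():
        logger.warning("fitted follow-up probabilities below 1e-6: very large weights")
    w = 1.0 / p_resp
    if config.stabilized:
        w = w * y.mean()
    if config.weight_truncation is not None:
        cap = np.percentile(w.to_numpy(), config.weight_truncation)
        w = w.clip(upper=cap)
    diagnostics = {
        "n_fit": int(len(sub)),
        "n_responders": int(len(w)),
        "min_weight": float(w.min()),
        "max_weight": float(w.max()),
        "sum_weights": float(w.sum()),
        "effective_sample_size": float(w.sum() ** 2 / (w ** 2).sum()),
        "converged": True,
    }
    return WeightSet(weights=w, fitted_probs=probs, retained=retained,
                     params=np.asarray(res.params), param_names=names,
                     diagnostics=diagnostics)


def weighted_prevalence(table: CohortTable, weights: WeightSet,
                        config: IpwConfig = IpwConfig(), *,
                        region: str | None = None,
                        method: str = "IPW") -> PooledEstimate:
    """Hajek-weighted prevalence among responders with an observed outcome.

    Responders whose outcome is missing are excluded from the weighted mean:
    their weight corrects for non-response, not for item missingness.  The
    robust (sandwich) variance treats weights as fixed; CI on the logit scale.
    """
    df = table.df
    if "impaired_observed" not in df.columns:
        raise ValueError("derive outcomes before the weighted prevalence")
    rows = df.index.intersection(weights.weights.index)
    mask = df.loc[rows, "impaired_observed"].notna()
    if region is not None:
        mask &= df.loc[rows, "region"] == region
    rows = rows[mask]
    if len(rows) == 0:
        raise ValueError("zero effective sample for the weighted prevalence")
    w = weights.weights.loc[rows].to_numpy()
    y = df.loc[rows, "impaired_observed"].to_numpy(dtype=float)
    p = float(np.sum(w * y) / np.sum(w))
    var = float(np.sum(w ** 2 * (y - p) ** 2) / np.sum(w) ** 2)
    if config.variance_method == "bootstrap":
        var = _bootstrap_variance(table, weights.retained, config, region)
    z = float(stats.norm.ppf(0.975))
    if 0.0 < p < 1.0:
        se_l = np.sqrt(var) / (p * (1 - p))
        lo, hi = float(expit(logit(p) - z * se_l)), float(expit(logit(p) + z * se_l))
    else:
        lo, hi = p, p
    return PooledEstimate(p, lo, hi, float(np.sqrt(var)), var, np.nan, var, np.inf, 1,
                          method=method, subgroup=region or "total", n=int(len(rows)))


def _bootstrap_variance(table, retained, config, region):
    rng = np.random.default_rng(config.seed)
    ests = []
    base_cfg = IpwConfig(screening_alpha=config.screening_alpha,
                         weight_truncation=config.weight_truncation,
                         variance_method="sandwich", stabilized=config.stabilized)
    for _ in range(config.n_boot):
        idx = rng.integers(0, table.n, size=table.n)
        bt = CohortTable(table.df.iloc[idx].reset_index(drop=True),
                         dict(table.covariates), tuple(table.regions))
        try:
            ws = fit_weights(bt, retained, base_cfg)
            ests.append(weighted_prevalence(bt, ws, base_cfg, region=region).estimate)
        except (RuntimeError, ValueError):
            continue
    return float(np.var(ests, ddof=1)) if len(ests) > 1 else float("nan")


def ipw_complete_case(table: CohortTable, config: IpwConfig = IpwConfig(),
                      candidates: list[str] | None = None) -> tuple[PooledEstimate, WeightSet]:
    """Screen → fit → weighted prevalence on the complete-case dataset."""
    retained = screen_predictors(table, candidates, config.screening_alpha)
    ws = fit_weights(table, retained, config)
    est = weighted_prevalence(table, ws, config, method="IPW complete cases")
    return est, ws


def ipw_on_imputed(imputed: ImputedDatasets, table: CohortTable,
                   config: IpwConfig = IpwConfig(),
                   candidates: list[str] | None = None, *,
                   region: str | None = None) -> PooledEstimate:
    """IPW with imputed predictors: screen/fit/estimate per completed dataset,
    then pool the m estimates and variances by Rubin's rules.

    ``imputed`` must come from a run with the outcome excluded from the
    imputation (``MiceConfig(include_outcome=False)``): the outcome column is
    carried through observed-or-missing exactly as in the input cohort.
    """
    if imputed.config.include_outcome:
        raise ValueError("ipw_on_imputed expects an imputation run with include_outcome=False")
    ests, variances = [], []
    n_used = None
    for df in imputed.datasets:
        work = table.copy()
        for name in table.covariate_names:
            work.df[name] = df[name].to_numpy()
        sub_est, _ = ipw_complete_case_on(work, config, candidates, region=region)
        ests.append(sub_est.estimate)
        variances.append(sub_est.T)
        n_used = sub_est.n
    return rubin_pool(ests, variances, df_com=(n_used - 1 if n_used else None), n=n_used,
                      method="IPW imputed", subgroup=region or "total")


def ipw_complete_case_on(table, config, candidates, region=None):
    retained = screen_predictors(table, candidates, config.screening_alpha)
    ws = fit_weights(table, retained, config)
    return weighted_prevalence(table, ws, config, region=region), ws
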