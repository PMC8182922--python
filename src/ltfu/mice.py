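"""Multiple imputation by chained equations with a delta (MNAR) offset.

Each incomplete variable is imputed from a conditional model given all other
analysis variables.  Binary variables use Bayesian logistic regression
imputation: the model is fitted by maximum likelihood on the observed rows, a
coefficient vector is drawn from the large-sample normal approximation of its
posterior (mean = MLE, covariance = inverse observed information), and each
missing value is drawn Bernoulli(logistic(x'b)).  Multi-level categoricals use
the analogous posterior-draw multinomial logit; continuous variables (a
compatibility feature — the cohort's variables are all categorical) use
predictive mean matching with 5 donors.

The MNAR sensitivity handle: a fixed offset ``delta`` is added to the linear
predictor of the *outcome's* imputation model before drawing, so with
delta = log(k) the imputation-model odds of impairment for children with a
missing outcome are k times the MAR odds.  delta = 0 reproduces the plain MAR
analysis bit-for-bit under the same seed.

Chains are initialised by random draws from the observed margins and visit
variables in order of increasing missingness; the m imputations run on
independent RNG streams spawned from a single seed, so results are
reproducible and adding imputations never perturbs earlier ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import (GlmFit, fit_linear, fit_logistic, fit_multinomial,
                   multinomial_probs, prune_constant_columns)
from .simulate import CohortTable, ConfigError

__all__ = [
    "MiceConfig",
    "ImputedDatasets",
    "impute_binary_logit",
    "impute_multinomial",
    "impute_pmm",
    "run_mice",
    "chain_slopes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiceConfig:
    """Chained-equations settings.

    ``delta`` is the log-odds offset applied to the outcome's imputation model
    (0 = MAR).  ``method_map`` and ``predictor_matrix`` override the automatic
    choices (binary logit for 2-level variables, multinomial for more levels,
    PMM for continuous; every variable predicted by all others).
    """

    m: int = 100
    n_iterations: int = 15
    seed: int = 0
    delta: float = 0.0
    outcome_var: str = "impaired_observed"
    include_outcome: bool = True
    method_map: dict[str, str] | None = None
    predictor_matrix: dict[str, list[str]] | None = None

    def validate(self) -> None:
        if self.m < 2:
            raise ConfigError("m must be >= 2")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not np.isfinite(self.delta):
            raise ConfigError("delta must be finite")
        if self.predictor_matrix is not None:
            for var, preds in self.predictor_matrix.items():
                if var in preds:
                    raise ConfigError(f"predictor matrix has non-zero diagonal for {var!r}")

    def with_delta(self, delta: float) -> "MiceConfig":
        return replace(self, delta=float(delta))


@dataclass
class ImputedDatasets:
    """m completed copies of the analysis columns plus diagnostics.

    ``datasets`` hold child_id, region, the covariates, followed_up and (when
    modeled) the outcome, fully observed.  ``chain_means`` maps each imputed
    variable to an (m, n_iterations) array of the mean imputed value per
    chain and iteration.
    """

    datasets: list[pd.DataFrame]
    chain_means: dict[str, np.ndarray]
    config: MiceConfig
    outcome_var: str
    imputed_vars: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets):
            df.to_csv(path / f"imputation_{i+1:03d}.csv", index=False)
        manifest = {
            "m": self.m,
            "outcome_var": self.outcome_var,
            "imputed_vars": self.imputed_vars,
            "seed": self.config.seed,
            "delta": self.config.delta,
            "n_iterations": self.config.n_iterations,
            "chain_means": {k: v.tolist() for k, v in self.chain_means.items()},
            "diagnostics": self.diagnostics,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# elementary imputation steps
# ---------------------------------------------------------------------------

def impute_binary_logit(y_obs, X_obs, X_mis, delta: float = 0.0,
                        rng: np.random.Generator | None = None,
                        start: np.ndarray | None = None) -> tuple[np.ndarray, GlmFit | None]:
    """Posterior-draw logistic imputation of a binary variable.

    Fits y ~ X on the observed rows by ML (ridge-stabilised on separation),
    draws a coefficient vector from N(MLE, inverse information), adds ``delta``
    to the linear predictor of the missing rows, and draws Bernoulli values.
    With delta = log(k) the imputation odds are k-fold the MAR odds.

    Returns (imputed 0/1 array, fit); fit is None when only one class was
    observed, in which case the constant class is imputed with a warning
    (delta = +inf/-inf surrogates still saturate via the linear predictor when
    a fit exists).
    """
    rng = rng or np.random.default_rng()
    y_obs = np.asarray(y_obs, dtype=float)
    X_obs = np.asarray(X_obs, dtype=float)
    X_mis = np.asarray(X_mis, dtype=float)
    classes = np.unique(y_obs)
    if len(classes) < 2:
        logger.warning("single observed class %s: imputing the constant", classes)
        return np.full(len(X_mis), int(classes[0])), None
    keep = prune_constant_columns(X_obs)
    fit = fit_logistic(X_obs[:, keep], y_obs, start=start)
    fit.kept_columns = keep
    beta = fit.draw(rng)
    lp = X_mis[:, keep] @ beta + delta
    p = expit(lp)
    return (rng.random(len(X_mis)) < p).astype(np.int64), fit


def impute_multinomial(y_obs, X_obs, X_mis, n_levels: int,
                       rng: np.random.Generator | None = None,
                       start: np.ndarray | None = None) -> tuple[np.ndarray, GlmFit | None]:
    """Posterior-draw multinomial-logit imputation of integer codes 0..n_levels-1.

    Levels unobserved in the fitting rows are dropped from the model and never
    imputed (with a warning).  No delta offset applies to covariates.
    """
    rng = rng or np.random.default_rng()
    y_obs = np.asarray(y_obs, dtype=np.intp)
    X_obs = np.asarray(X_obs, dtype=float)
    X_mis = np.asarray(X_mis, dtype=float)
    present = np.unique(y_obs)
    if len(present) < 2:
        logger.warning("single observed level %s: imputing the constant", present)
        return np.full(len(X_mis), int(present[0])), None
    if len(present) < n_levels:
        logger.warning("levels %s unobserved: dropped from the imputation model",
                       sorted(set(range(n_levels)) - set(present.tolist())))
    # re-code onto the observed levels
    code_of = {lev: i for i, lev in enumerate(present.tolist())}
    y_re = np.asarray([code_of[v] for v in y_obs.tolist()], dtype=np.intp)
    keep = prune_constant_columns(X_obs)
    if len(present) == 2:
        imputed01, fit = impute_binary_logit(y_re, X_obs[:, keep], X_mis[:, keep], 0.0, rng,
                                             start=start)
        return present[imputed01], fit
    fit = fit_multinomial(X_obs[:, keep], y_re, len(present), start=start)
    fit.kept_columns = keep
    params = fit.draw(rng)
    probs = multinomial_probs(X_mis[:, keep], params, len(present))
    cum = probs.cumsum(axis=1)
    u = rng.random(len(X_mis))[:, None]
    drawn = (u > cum).sum(axis=1)
    return present[drawn], fit


def impute_pmm(y_obs, X_obs, X_mis, rng: np.random.Generator | None = None,
               donors: int = 5) -> np.ndarray:
    """Predictive-mean-matching imputation of a continuous variable.

    Bayesian linear regression draw (scaled inverse-chi-square sigma^2, normal
    coefficients), type-1 matching: each missing row's drawn prediction is
    matched to the ``donors`` observed rows with closest ML predictions and one
    donor's observed value is imputed.
    """
    rng = rng or np.random.default_rng()
    y_obs = np.asarray(y_obs, dtype=float)
    X_obs = np.asarray(X_obs, dtype=float)
    X_mis = np.asarray(X_mis, dtype=float)
    keep = prune_constant_columns(X_obs)
    beta, XtX_inv, sigma2, df = fit_linear(X_obs[:, keep], y_obs)
    sigma2_draw = sigma2 * df / rng.chisquare(df)
    chol = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(len(beta)))
    beta_draw = beta + np.sqrt(sigma2_draw) * chol @ rng.standard_normal(len(beta))
    yhat_obs = X_obs[:, keep] @ beta
    yhat_mis = X_mis[:, keep] @ beta_draw
    k = min(donors, len(y_obs))
    out = np.empty(len(X_mis))
    for i, pred in enumerate(yhat_mis):
        idx = np.argpartition(np.abs(yhat_obs - pred), k - 1)[:k]
        out[i] = y_obs[idx[rng.integers(0, k)]]
    return out


# ---------------------------------------------------------------------------
# the chained-equations driver
# ---------------------------------------------------------------------------

class _Var:
    """Internal per-variable bookkeeping: integer codes with -1 for missing."""

    __slots__ = ("name", "levels", "codes", "obs_mask", "method", "is_outcome")

    def __init__(self, name, levels, codes, method, is_outcome=False):
        self.name = name
        self.levels = levels            # None for binary 0/1 or continuous
        self.codes = codes
        self.obs_mask = codes >= 0 if codes.dtype.kind in "iu" else ~np.isnan(codes)
        self.method = method
        self.is_outcome = is_outcome

    @property
    def n_levels(self):
        return len(self.levels) if self.levels is not None else 2

    def dummies(self, current: np.ndarray) -> np.ndarray:
        k = self.n_levels
        if k == 2:
            return current.reshape(-1, 1).astype(float)
        out = np.zeros((len(current), k - 1))
        for lev in range(1, k):
            out[:, lev - 1] = current == lev
        return out


def _encode(table: CohortTable, config: MiceConfig):
    """Integer-code the analysis columns; decide methods and predictors."""
    df = table.df
    method_map = dict(config.method_map or {})
    variables: dict[str, _Var] = {}

    region_codes = pd.Categorical(df["region"], categories=list(table.regions)).codes.astype(np.int64)
    variables["region"] = _Var("region", tuple(table.regions), region_codes, None)
    fu = df["followed_up"].to_numpy(dtype=np.int64)
    variables["followed_up"] = _Var("followed_up", None, fu, None)

    for name, levels in table.covariates.items():
        col = pd.Categorical(df[name], categories=list(levels)).codes.astype(np.int64)
        method = method_map.get(name, "binary-logit" if len(levels) == 2 else "multinomial-logit")
        variables[name] = _Var(name, tuple(levels), col, method)

    if config.include_outcome:
        if config.outcome_var not in df.columns:
            raise ConfigError(f"outcome column {config.outcome_var!r} not present; derive outcomes first")
        y = df[config.outcome_var]
        codes = y.fillna(-1).to_numpy(dtype=np.int64)
        variables[config.outcome_var] = _Var(config.outcome_var, None, codes,
                                             method_map.get(config.outcome_var, "binary-logit"),
                                             is_outcome=True)

    modeled = [v for v in variables.values()
               if v.method is not None and (~v.obs_mask).any()]
    for v in modeled:
        if not v.obs_mask.any():
            raise ConfigError(f"variable {v.name!r} is 100% missing and cannot be imputed")
    # visit order: increasing fraction missing
    modeled.sort(key=lambda v: ((~v.obs_mask).mean(), v.name))

    all_names = list(variables)
    predictors = {}
    for v in modeled:
        if config.predictor_matrix is not None and v.name in config.predictor_matrix:
            predictors[v.name] = list(config.predictor_matrix[v.name])
        else:
            predictors[v.name] = [nm for nm in all_names if nm != v.name]
    return variables, modeled, predictors


def _design(variables, names, current, rows=None):
    cols = [np.ones((len(current[names[0]]) if rows is None else int(rows.sum()), 1))]
    for nm in names:
        cur = current[nm] if rows is None else current[nm][rows]
        cols.append(variables[nm].dummies(cur))
    return np.concatenate(cols, axis=1)


def run_mice(table: CohortTable, config: MiceConfig) -> ImputedDatasets:
    """Run the chained-equations sampler and return m completed datasets.

    The outcome's imputation model receives ``config.delta``; every other
    variable is imputed at delta = 0.  Observed cells are never modified.
    """
    config.validate()
    variables, modeled, predictors = _encode(table, config)
    if not modeled:
        # nothing to impute: m identical copies of the input
        base = _completed_frame(table, variables, {v.name: v.codes for v in variables.values()}, config)
        return ImputedDatasets([base.copy() for _ in range(config.m)], {}, config,
                               config.outcome_var, [])

    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(config.m)]
    chain_means = {v.name: np.zeros((config.m, config.n_iterations)) for v in modeled}
    datasets = []
    n_separation = 0

    for i, rng in enumerate(streams):
        warm: dict[str, tuple[tuple, np.ndarray]] = {}
        current = {v.name: v.codes.copy() for v in variables.values()}
        # initialise missing cells by draws from the observed margin
        for v in modeled:
            obs_vals = v.codes[v.obs_mask]
            mis = ~v.obs_mask
            current[v.name][mis] = rng.choice(obs_vals, size=int(mis.sum()), replace=True)
        for it in range(config.n_iterations):
            for v in modeled:
                mis = ~v.obs_mask
                X_full = _design(variables, predictors[v.name], current)
                X_obs, X_mis = X_full[v.obs_mask], X_full[mis]
                y_obs = current[v.name][v.obs_mask]
                delta = config.delta if v.is_outcome else 0.0
                start = warm.get(v.name)
                if v.method == "binary-logit":
                    imputed, fit = impute_binary_logit(y_obs, X_obs, X_mis, delta, rng,
                                                       start=None if start is None else start[1])
                elif v.method == "multinomial-logit":
                    imputed, fit = impute_multinomial(y_obs, X_obs, X_mis, v.n_levels, rng,
                                                      start=None if start is None else start[1])
                elif v.method == "pmm":
                    imputed, fit = impute_pmm(y_obs, X_obs, X_mis, rng), None
                else:
                    raise ConfigError(f"unknown imputation method {v.method!r} for {v.name!r}")
                if fit is not None and fit.separation:
                    n_separation += 1
                if fit is not None and fit.kept_columns is not None:
                    kc = tuple(fit.kept_columns.tolist())
                    if start is None or start[0] == kc:
                        warm[v.name] = (kc, fit.params)
                    else:
                        warm.pop(v.name, None)
                current[v.name][mis] = imputed
                chain_means[v.name][i, it] = float(np.mean(imputed))
        datasets.append(_completed_frame(table, variables, current, config))

    diagnostics = {"n_ridge_stabilised_fits": n_separation}
    if n_separation:
        logger.info("%d imputation fits required ridge stabilisation", n_separation)
    return ImputedDatasets(datasets, chain_means, config, config.outcome_var,
                           [v.name for v in modeled], diagnostics)


def _completed_frame(table: CohortTable, variables, current, config) -> pd.DataFrame:
    df = table.df
    out = {"child_id": df["child_id"].to_numpy()}
    out["region"] = df["region"].to_numpy()
    for name, levels in table.covariates.items():
        codes = current[name]
        out[name] = np.asarray(levels, dtype=object)[codes]
    out["followed_up"] = df["followed_up"].to_numpy(dtype=np.int64)
    if config.include_outcome:
        out[config.outcome_var] = current[config.outcome_var].astype(np.int64)
    elif config.outcome_var in df.columns:
        out[config.outcome_var] = df[config.outcome_var].to_numpy()
    frame = pd.DataFrame(out)
    for name in table.covariates:
        frame[name] = frame[name].astype("string")
    frame["region"] = frame["region"].astype("string")
    return frame


def chain_slopes(imputed: ImputedDatasets, last: int = 10) -> dict[str, float]:
    """Linear-trend slope of each variable's chain-mean trace over the last
    ``last`` iterations, averaged across chains — a convergence diagnostic
    (values near 0 indicate stationarity)."""
    out = {}
    for name, traces in imputed.chain_means.items():
        tail = traces[:, -min(last, traces.shape[1]):]
        xs = np.arange(tail.shape[1])
        mean_trace = tail.mean(axis=0)
        if len(xs) < 2:
            out[name] = 0.0
        else:
            out[name] = float(np.polyfit(xs, mean_trace, 1)[0])
    return out
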