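"""Simulation studies of the attrition-correction estimators.

Repeated-cohort experiments on the calibrated synthetic generator, used both
by the test-suite and the reproduction script:

* :func:`mar_recovery_study` — under MAR attrition driven by social covariates,
  multiple imputation and inverse-probability weighting should recover the
  latent impairment prevalence while the complete-case (crude) estimate is
  biased downward;
* :func:`mnar_recovery_study` — under an MNAR mechanism with a known log-odds
  shift, the delta-adjusted imputation at the true delta should remove the
  bias that the MAR analysis leaves behind;
* :func:`delta_grid_study` — the scenario grid should be monotone in delta;
* :func:`null_calibration_study` — on null data the association scan's type-I
  error and the screening retention rate should sit at their nominal levels.

All functions are deterministic given their seed; per-cohort seeds are spawned
from it.  Biases are reported in percentage points against the cohort's
realised latent prevalence.
"""

from __future__ import annotations

import numpy as np

from .attrition import association_scan
from .delta import DEFAULT_DELTA_GRID, run_delta_grid
from .ipw import IpwConfig, ipw_complete_case, screen_predictors
from .mice import MiceConfig, run_mice
from .outcome import derive_outcomes
from .pooling import crude_prevalence, prevalence_from_imputed
from .simulate import CohortTable, default_epice_like_config, generate_cohort

__all__ = [
    "mar_recovery_study",
    "mnar_recovery_study",
    "delta_grid_study",
    "null_calibration_study",
]


def _cohort_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _study_cohort(seed: int, n_children: int, delta_true: float):
    cfg = default_epice_like_config(n_children=n_children, seed=int(seed),
                                    delta_true=delta_true)
    table = derive_outcomes(generate_cohort(cfg))
    latent = float(table.df["latent_impaired"].mean())
    return table, latent


def mar_recovery_study(n_seeds: int = 50, n_children: int = 3000, m: int = 20,
                       n_iterations: int = 5, seed: int = 0) -> dict:
    """Mean bias (pp) of MI, IPW and the crude estimate under MAR attrition."""
    seeds = _cohort_seeds(seed, n_seeds)
    mi_b, ipw_b, cc_b = [], [], []
    for i, s in enumerate(seeds):
        table, latent = _study_cohort(s, n_children, delta_true=0.0)
        cc_b.append(crude_prevalence(table).estimate - latent)
        imp = run_mice(table, MiceConfig(m=m, n_iterations=n_iterations, seed=int(s)))
        mi_b.append(prevalence_from_imputed(imp).estimate - latent)
        est, _ = ipw_complete_case(table, IpwConfig())
        ipw_b.append(est.estimate - latent)
    return {
        "n_seeds": n_seeds,
        "mi_bias_pp": 100 * float(np.mean(mi_b)),
        "ipw_bias_pp": 100 * float(np.mean(ipw_b)),
        "complete_case_bias_pp": 100 * float(np.mean(cc_b)),
        "mi_bias_sd_pp": 100 * float(np.std(mi_b)),
        "ipw_bias_sd_pp": 100 * float(np.std(ipw_b)),
        "complete_case_bias_sd_pp": 100 * float(np.std(cc_b)),
    }


def mnar_recovery_study(n_seeds: int = 50, n_children: int = 3000, m: int = 20,
                        n_iterations: int = 5, delta_true: float = 0.4,
                        seed: int = 0) -> dict:
    """Mean bias (pp) of MAR-MI versus delta-adjusted MI under MNAR attrition.

    The generator makes impaired children exp(delta_true)-fold less likely to
    respond; the adjusted analysis re-imputes with delta = delta_true.
    """
    seeds = _cohort_seeds(seed + 1, n_seeds)
    mar_b, adj_b = [], []
    for s in seeds:
        table, latent = _study_cohort(s, n_children, delta_true=delta_true)
        base = MiceConfig(m=m, n_iterations=n_iterations, seed=int(s))
        mar_b.append(prevalence_from_imputed(run_mice(table, base)).estimate - latent)
        adj = run_mice(table, base.with_delta(delta_true))
        adj_b.append(prevalence_from_imputed(adj).estimate - latent)
    return {
        "n_seeds": n_seeds,
        "delta_true": delta_true,
        "mar_mi_bias_pp": 100 * float(np.mean(mar_b)),
        "delta_adjusted_bias_pp": 100 * float(np.mean(adj_b)),
    }


def delta_grid_study(n_seeds: int = 3, n_children: int = 1500, m: int = 10,
                     n_iterations: int = 4, seed: int = 0,
                     deltas=DEFAULT_DELTA_GRID) -> dict:
    """Fraction of seeds with a monotone grid, and the MAR/delta-0 identity."""
    seeds = _cohort_seeds(seed + 2, n_seeds)
    monotone = 0
    zero_identical = True
    exp_err = 0.0
    for s in seeds:
        table, _ = _study_cohort(s, n_children, delta_true=0.0)
        res = run_delta_grid(table, MiceConfig(m=m, n_iterations=n_iterations, seed=int(s)),
                             deltas=tuple(deltas) + (0.0,), include_crude=False)
        pairs = sorted((r.delta, r.estimates["total"].estimate)
                       for r in res.rows if r.delta is not None and r.label == "MNAR")
        vals = [v for _, v in pairs]
        monotone += all(vals[i] <= vals[i + 1] + 1e-12 for i in range(len(vals) - 1))
        mar = res.mar_row.estimates["total"]
        zero = res.row_for_delta(0.0).estimates["total"]
        zero_identical &= (mar.estimate == zero.estimate and mar.T == zero.T)
        exp_err = max(exp_err, max(abs(r.exp_delta - np.exp(r.delta))
                                   for r in res.rows if r.delta is not None))
    return {
        "n_seeds": n_seeds,
        "monotone_fraction": monotone / n_seeds,
        "delta_zero_equals_mar": float(zero_identical),
        "exp_column_max_abs_err": float(exp_err),
    }


def _null_table(rng: np.random.Generator, n: int) -> CohortTable:
    """A cohort where the candidate factor is independent of follow-up."""
    import pandas as pd

    from .simulate import ITEM_COLUMNS

    df = pd.DataFrame({
        "child_id": pd.array(np.arange(1, n + 1), dtype="Int64"),
        "region": pd.array(rng.choice(["PT", "UK"], n), dtype="string"),
        "x": pd.array(rng.choice(["a", "b"], n), dtype="string"),
        "latent_impaired": pd.array(np.zeros(n, dtype=int), dtype="Int64"),
        "followed_up": pd.array(rng.integers(0, 2, n), dtype="Int64"),
    })
    for col in ITEM_COLUMNS:
        df[col] = pd.array([pd.NA] * n, dtype="Int64")
    return CohortTable(df=df, covariates={"x": ("a", "b")}, regions=("PT", "UK"))


def null_calibration_study(n_replicates: int = 200, n_children: int = 400,
                           alpha_screen: float = 0.2, seed: int = 0) -> dict:
    """Type-I error of the association scan and screening retention on null data."""
    rng = np.random.default_rng(np.random.SeedSequence(seed + 3))
    type1 = 0
    retained = 0
    pvals = []
    for _ in range(n_replicates):
        table = _null_table(rng, n_children)
        p = association_scan(table, target="followup", factors=["x"])[0].p_value
        pvals.append(p)
        type1 += bool(np.isfinite(p) and p < 0.05)
        retained += "x" in screen_predictors(table, ["x"], alpha_screen)
    return {
        "n_replicates": n_replicates,
        "type1_error_rate": type1 / n_replicates,
        "screening_retention_rate": retained / n_replicates,
        "p_values": np.asarray(pvals),
    }
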