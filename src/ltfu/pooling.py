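"""Rubin's-rules pooling and the prevalence arithmetic shared by all estimators.

Per-imputation prevalence estimates are combined on the logit scale: each
proportion and its variance are transformed (delta method), the pooled mean,
within-imputation variance W, between-imputation variance B and total variance
T = W + (1 + 1/m)B are formed, a t-interval with Barnard–Rubin degrees of
freedom is built, and everything is back-transformed.  The logit scale keeps
confidence intervals inside [0, 1]; a raw proportion-scale option is available
for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from scipy import stats
from scipy.special import expit, logit

from ._util import round_half_up

__all__ = [
    "PooledEstimate",
    "rubin_pool",
    "crude_prevalence",
    "percent_change",
    "prevalence_from_imputed",
    "subgroup_estimates",
]

logger = logging.getLogger(__name__)


@dataclass
class PooledEstimate:
    """A prevalence estimate with its pooling bookkeeping.

    ``estimate`` and CI bounds are proportions; ``W``, ``B``, ``T`` are on the
    pooling scale (logit by default).  For single-dataset estimators (crude,
    complete-case IPW) ``m`` is 1 and ``B`` is NaN.
    """

    estimate: float
    ci_low: float
    ci_high: float
    se: float
    W: float
    B: float
    T: float
    df: float
    m: int
    method: str = ""
    subgroup: str = "total"
    scale: str = "logit"
    delta: float | None = None
    n: int | None = None

    @property
    def estimate_pct(self) -> float:
        return round_half_up(100.0 * self.estimate, 1)

    @property
    def ci_pct(self) -> tuple[float, float]:
        return (round_half_up(100.0 * self.ci_low, 1), round_half_up(100.0 * self.ci_high, 1))

    def __str__(self) -> str:  # "18.4 [15.9;21.2]"
        lo, hi = self.ci_pct
        return f"{self.estimate_pct:.1f} [{lo:.1f};{hi:.1f}]"


def _barnard_rubin_df(m: int, B: float, T: float, df_com: float | None) -> float:
    if B <= 0 or T <= 0:
        return np.inf
    lam = (1.0 + 1.0 / m) * B / T
    df_old = (m - 1) / lam**2
    if df_com is None or not np.isfinite(df_com):
        return df_old
    df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
    return df_old * df_obs / (df_old + df_obs)


def _t_quantile(df: float, alpha: float) -> float:
    if not np.isfinite(df):
        return float(stats.norm.ppf(1 - alpha / 2))
    return float(stats.t.ppf(1 - alpha / 2, df))


def rubin_pool(estimates, variances, *, df_com: float | None = None,
               scale: str = "logit", alpha: float = 0.05, n: int | None = None,
               method: str = "MI", subgroup: str = "total",
               delta: float | None = None) -> PooledEstimate:
    """Combine m per-imputation proportions and their variances.

    ``estimates`` are proportions in [0, 1]; ``variances`` their sampling
    variances on the proportion scale.  With ``scale="logit"`` (default) both
    are delta-method transformed before pooling.  Estimates of exactly 0 or 1
    receive a continuity adjustment of 0.5 successes on a denominator of ``n``
    (required in that case) before the logit transform.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("rubin_pool needs m >= 2 estimates")
    if len(u) != m or (u < 0).any():
        raise ValueError("variances must align with estimates and be non-negative")
    if scale == "logit":
        boundary = (q <= 0) | (q >= 1)
        if boundary.any():
            if n is None:
                raise ValueError("estimate of exactly 0 or 1: pass n for the continuity adjustment")
            logger.warning("continuity adjustment applied to %d boundary estimate(s)", int(boundary.sum()))
            q = (q * n + 0.5) / (n + 1.0)
            u = np.maximum(u, q * (1 - q) / n)
        ell = logit(q)
        v = u / (q * (1 - q)) ** 2
    elif scale == "proportion":
        ell, v = q, u
    else:
        raise ValueError(f"unknown pooling scale {scale!r}")

    qbar = float(ell.mean())
    W = float(v.mean())
    B = float(ell.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    df = _barnard_rubin_df(m, B, T, df_com)
    tq = _t_quantile(df, alpha)
    half = tq * np.sqrt(T)
    lo, hi = qbar - half, qbar + half
    if scale == "logit":
        est, lo, hi = float(expit(qbar)), float(expit(lo)), float(expit(hi))
    else:
        est = qbar
    return PooledEstimate(est, lo, hi, float(np.sqrt(T)), W, B, T, df, m,
                          method=method, subgroup=subgroup, scale=scale,
                          delta=delta, n=n)


def crude_prevalence(table, subgroup: str = "total", region: str | None = None) -> PooledEstimate:
    """Observed prevalence among responders with an observed outcome.

    Uses a logit-scale Wald interval, se = sqrt(1/x + 1/(n-x)), which keeps the
    CI in [0, 1] and matches the pooled machinery's scale.
    """
    df = table.df
    if "impaired_observed" not in df.columns:
        raise ValueError("derive outcomes before computing the crude prevalence")
    mask = (df["followed_up"] == 1) & df["impaired_observed"].notna()
    if region is not None:
        mask &= df["region"] == region
        subgroup = region
    y = df.loc[mask, "impaired_observed"].astype(float)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no responders with observed outcome")
    x = int(y.sum())
    z = float(stats.norm.ppf(0.975))
    if x == 0 or x == n:
        p = x / n
        # one-sided boundary: clip with a continuity-adjusted logit interval
        pa = (x + 0.5) / (n + 1.0)
        se_l = np.sqrt(1.0 / (x + 0.5) + 1.0 / (n - x + 0.5))
        lo = 0.0 if x == 0 else float(expit(logit(pa) - z * se_l))
        hi = float(expit(logit(pa) + z * se_l)) if x == 0 else 1.0
        var_p = pa * (1 - pa) / n
        return PooledEstimate(p, lo, hi, float(np.sqrt(var_p)), var_p, np.nan, var_p,
                              np.inf, 1, method="Crude", subgroup=subgroup, n=n)
    p = x / n
    se_l = np.sqrt(1.0 / x + 1.0 / (n - x))
    lo = float(expit(logit(p) - z * se_l))
    hi = float(expit(logit(p) + z * se_l))
    var_p = p * (1 - p) / n
    return PooledEstimate(p, lo, hi, float(np.sqrt(var_p)), var_p, np.nan, var_p,
                          np.inf, 1, method="Crude", subgroup=subgroup, n=n)


def percent_change(corrected_pct: float, crude_pct: float) -> float:
    """Relative change (%) of a corrected prevalence over the crude one.

    Both arguments are percentages (e.g. 20.4 and 18.4); the result is the
    unrounded relative increase in percent — render with 1 decimal.
    """
    if crude_pct == 0:
        raise ValueError("percent change undefined for a crude prevalence of 0")
    return (corrected_pct - crude_pct) / crude_pct * 100.0


def _prevalence_and_variance(y: np.ndarray) -> tuple[float, float, int]:
    n = len(y)
    p = float(np.mean(y))
    return p, p * (1 - p) / n if n else np.nan, n


def prevalence_from_imputed(imputed, mask_fn=None, *, method: str = "MI",
                            subgroup: str = "total", delta: float | None = None) -> PooledEstimate:
    """Rubin-pooled outcome prevalence over the completed datasets.

    ``mask_fn`` maps a completed DataFrame to a boolean row mask (default: all
    rows).  Per-dataset variance is binomial, p(1-p)/n.
    """
    ests, variances = [], []
    n_rows = None
    for df in imputed.datasets:
        mask = np.ones(len(df), dtype=bool) if mask_fn is None else np.asarray(mask_fn(df))
        y = df.loc[mask, imputed.outcome_var].to_numpy(dtype=float)
        p, v, n_rows = _prevalence_and_variance(y)
        ests.append(p)
        variances.append(v)
    return rubin_pool(ests, variances, df_com=(n_rows - 1 if n_rows else None),
                      n=n_rows, method=method, subgroup=subgroup, delta=delta)


def subgroup_estimates(imputed, *, method: str = "MI") -> dict[str, PooledEstimate]:
    """Pooled prevalence among responders and among non-responders.

    The non-responder estimate rests entirely on imputed outcome values; under
    an MNAR generating mechanism imputed under MAR it is biased toward the
    responder prevalence — the package's motivating diagnostic.
    """
    out: dict[str, PooledEstimate] = {}
    for label, flag in (("responders", 1), ("non_responders", 0)):
        any_rows = any((df["followed_up"] == flag).any() for df in imputed.datasets)
        if not any_rows:
            logger.warning("empty stratum %s: no pooled estimate", label)
            continue
        out[label] = prevalence_from_imputed(
            imputed, lambda df, f=flag: (df["followed_up"] == f).to_numpy(),
            method=f"{method} ({label})", subgroup=label)
    return out
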