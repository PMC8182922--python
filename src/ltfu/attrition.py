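"""Descriptive attrition analysis.

Two pieces: (1) the loss-to-follow-up accounting table — responders and
non-responders overall and per region, rows with at least one missing baseline
covariate, and outcome missingness among responders; (2) a factor-by-factor
association scan, fitting for each baseline factor a logistic regression of a
binary target (follow-up, or the observed outcome) on the factor's dummies
adjusted for region of birth, and reporting a Wald block test of the factor.
Rows missing the factor are dropped per factor; the missing category never
enters the test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import pct
from .simulate import CohortTable, PARCA_ITEMS

__all__ = ["AttritionReport", "AssociationRow", "attrition_table", "association_scan"]

logger = logging.getLogger(__name__)


@dataclass
class AttritionReport:
    """Counts (and 1-decimal percentages recomputable from them) per stratum."""

    rows: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def row(self, stratum: str) -> dict:
        for r in self.rows:
            if r["stratum"] == stratum:
                return r
        raise KeyError(stratum)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)


def _outcome_missing_mask(df: pd.DataFrame) -> pd.Series:
    if "impaired_observed" in df.columns:
        return df["impaired_observed"].isna()
    return df[list(PARCA_ITEMS)].isna().all(axis=1)


def _stratum_counts(df: pd.DataFrame, covariate_names: list[str], stratum: str) -> dict:
    n = len(df)
    resp = df["followed_up"] == 1
    n_resp = int(resp.sum())
    n_nonresp = n - n_resp
    miss_cov = df[covariate_names].isna().any(axis=1)
    out_miss = _outcome_missing_mask(df) & resp
    row = {
        "stratum": stratum,
        "n_total": n,
        "n_responders": n_resp,
        "pct_responders": pct(n_resp, n),
        "n_non_responders": n_nonresp,
        "pct_non_responders": pct(n_nonresp, n),
        "n_missing_covariate": int(miss_cov.sum()),
        "pct_missing_covariate": pct(int(miss_cov.sum()), n),
        "n_missing_covariate_responders": int((miss_cov & resp).sum()),
        "n_missing_covariate_non_responders": int((miss_cov & ~resp).sum()),
        "n_outcome_missing_responders": int(out_miss.sum()),
    }
    row["pct_missing_covariate_responders"] = pct(row["n_missing_covariate_responders"], n_resp) if n_resp else float("nan")
    row["pct_missing_covariate_non_responders"] = pct(row["n_missing_covariate_non_responders"], n_nonresp) if n_nonresp else float("nan")
    row["pct_outcome_missing_responders"] = pct(row["n_outcome_missing_responders"], n_resp) if n_resp else float("nan")
    row["n_analyzed"] = n_resp - row["n_outcome_missing_responders"]
    row["pct_analyzed"] = pct(row["n_analyzed"], n) if n else float("nan")
    row["n_complete_case"] = n - row["n_missing_covariate"]
    row["pct_complete_case"] = pct(row["n_complete_case"], n) if n else float("nan")
    return row


def attrition_table(table: CohortTable) -> AttritionReport:
    """Loss-to-follow-up and missing-data accounting, overall and per region."""
    report = AttritionReport()
    names = table.covariate_names
    report.rows.append(_stratum_counts(table.df, names, "total"))
    for region in table.regions:
        sub = table.df[table.df["region"] == region]
        if len(sub):
            report.rows.append(_stratum_counts(sub, names, region))
    return report


@dataclass
class AssociationRow:
    """One factor's region-adjusted association with a binary target."""

    factor: str
    p_value: float          # NaN when the fit separated
    statistic: float
    df: int
    n: int
    separation: bool
    test: str
    level_table: pd.DataFrame = field(repr=False, default=None)


def _level_table(sub: pd.DataFrame, factor: str, y: pd.Series) -> pd.DataFrame:
    rows = []
    for level, grp in sub.groupby(factor, observed=True):
        yy = y.loc[grp.index]
        n1 = int((yy == 1).sum())
        n0 = int((yy == 0).sum())
        rows.append({"level": level,
                     "n_target1": n1, "pct_target1": pct(n1, max(int((y == 1).sum()), 1)),
                     "n_target0": n0, "pct_target0": pct(n0, max(int((y == 0).sum()), 1))})
    return pd.DataFrame(rows)


def association_scan(table: CohortTable, target: str = "followup",
                     factors: list[str] | None = None, adjust_region: bool = True,
                     test: str = "wald") -> list[AssociationRow]:
    """Region-adjusted logistic association of each factor with the target.

    ``target`` is ``"followup"`` (response indicator, all rows) or
    ``"outcome"`` (observed impairment, responders with observed outcome only).
    ``test`` is a Wald block test of the factor's dummy coefficients (default)
    or ``"lr"`` for a likelihood-ratio test against the region-only model.
    """
    df = table.df
    if target in ("followup", "followed_up"):
        y_all = df["followed_up"].astype("Int64")
    elif target in ("outcome", "impaired_observed"):
        if "impaired_observed" not in df.columns:
            raise ValueError("derive outcomes before scanning the outcome target")
        y_all = df["impaired_observed"].astype("Int64")
    else:
        raise ValueError(f"unknown target {target!r}")

    factors = factors if factors is not None else table.covariate_names
    n_regions_present = df["region"].nunique()
    if adjust_region and n_regions_present < 2:
        warnings.warn("fewer than 2 regions present: region adjustment skipped")
        adjust_region = False

    results = []
    for factor in factors:
        mask = y_all.notna() & df[factor].notna()
        sub = df.loc[mask]
        y = y_all.loc[mask].astype(int)
        levels = [lv for lv in table.covariates[factor] if (sub[factor] == lv).any()]
        fac_dum = pd.get_dummies(pd.Categorical(sub[factor], categories=levels),
                                 drop_first=True, dtype=float)
        fac_dum.index = sub.index
        X = pd.DataFrame({"const": 1.0}, index=sub.index)
        X = pd.concat([X, fac_dum], axis=1)
        k = fac_dum.shape[1]
        if adjust_region:
            reg_dum = pd.get_dummies(pd.Categorical(sub["region"], categories=list(table.regions)),
                                     drop_first=True, dtype=float)
            reg_dum.index = sub.index
            reg_dum = reg_dum.loc[:, reg_dum.std() > 0]
            X = pd.concat([X, reg_dum], axis=1)
        row = AssociationRow(factor=factor, p_value=np.nan, statistic=np.nan, df=k,
                             n=len(sub), separation=False, test=test,
                             level_table=_level_table(sub, factor, y))
        if k == 0 or y.nunique() < 2:
            row.separation = True
            results.append(row)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y.to_numpy(), X.to_numpy()).fit(disp=0, maxiter=200)
            if (not res.mle_retvals.get("converged", False)) or np.abs(res.params).max() > 15:
                raise _SeparationSignal()
            if test == "lr":
                X0 = X.drop(columns=fac_dum.columns)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res0 = sm.Logit(y.to_numpy(), X0.to_numpy()).fit(disp=0, maxiter=200)
                stat = 2.0 * (res.llf - res0.llf)
                row.statistic = float(stat)
                row.p_value = float(stats.chi2.sf(stat, k))
            else:
                R = np.zeros((k, X.shape[1]))
                for j in range(k):
                    R[j, 1 + j] = 1.0
                wt = res.wald_test(R, scalar=False)
                row.statistic = float(np.squeeze(wt.statistic))
                row.p_value = float(np.squeeze(wt.pvalue))
        except _SeparationSignal:
            row.separation = True
            row.p_value = np.nan
            logger.warning("separation / non-convergence for factor %r: p reported as missing", factor)
        except Exception as exc:  # statsmodels raises several flavours on degenerate fits
            logger.warning("fit failure for factor %r (%s): p reported as missing", factor, exc)
            row.separation = True
            row.p_value = np.nan
        results.append(row)
    return results


class _SeparationSignal(Exception):
    pass


def scan_frame(rows: list[AssociationRow]) -> pd.DataFrame:
    """Flatten an association scan into a report DataFrame."""
    return pd.DataFrame([
        {"factor": r.factor, "p_value": r.p_value, "statistic": r.statistic,
         "df": r.df, "n": r.n, "separation": r.separation, "test": r.test}
        for r in rows
    ])
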