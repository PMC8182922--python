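"""Derivation of the binary neurodevelopmental-impairment outcome.

The composite "moderate to severe neurodevelopmental impairment" at 2 years of
corrected age combines (a) gross motor impairment — any of three parent-report
flags (unable to walk without assistance, unable to sit without support,
unable to hold the head up) — and/or (b) non-verbal cognitive (NVC)
impairment, defined as a PARCA-R NVC score (sum of 34 binary items) strictly
below 22.

Missing components propagate with three-valued (Kleene) logic: the composite
is 1 as soon as any observed component is 1, 0 only when every component is
observed 0, and missing otherwise.  No partial / pro-rated scoring of the 34
items is attempted — any missing item makes the score missing; item-level
missingness is left to the downstream imputation machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (CohortTable, MOTOR_ITEMS,
                       N_PARCA_ITEMS, PARCA_ITEMS)

__all__ = [
    "OutcomeConfig",
    "EligibilityFlags",
    "score_parca",
    "classify_nvc",
    "derive_impairment",
    "derive_outcomes",
    "apply_eligibility",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutcomeConfig:
    """Scoring parameters: score < ``nvc_threshold`` flags NVC impairment."""

    nvc_threshold: int = 22
    n_parca_items: int = N_PARCA_ITEMS
    motor_item_names: tuple[str, ...] = MOTOR_ITEMS

    def __post_init__(self):
        if not 0 < self.nvc_threshold <= self.n_parca_items:
            raise ValueError("nvc_threshold must lie in (0, n_parca_items]")


@dataclass
class EligibilityFlags:
    """Per-child exclusion flags, aligned with the cohort rows."""

    died_before_2y: np.ndarray
    severe_congenital_anomaly: np.ndarray
    deaf_or_blind: np.ndarray

    def __post_init__(self):
        for name in ("died_before_2y", "severe_congenital_anomaly", "deaf_or_blind"):
            arr = np.asarray(getattr(self, name)).astype(np.int64)
            if not np.isin(arr, [0, 1]).all():
                raise ValueError(f"{name} must be binary")
            setattr(self, name, arr)


def _as_frame(items, columns) -> pd.DataFrame:
    if isinstance(items, pd.DataFrame):
        return items
    arr = pd.array(list(items), dtype="Int64")
    return pd.DataFrame([arr], columns=columns)


def score_parca(items) -> "pd.Series | object":
    """Sum the 34 binary PARCA-R items; missing if any item is missing.

    Accepts a DataFrame of the 34 item columns (returns an Int64 Series) or a
    single 34-long sequence (returns an int or ``pd.NA``).
    """
    single = not isinstance(items, pd.DataFrame)
    frame = _as_frame(items, list(PARCA_ITEMS) if single else None)
    if frame.shape[1] != N_PARCA_ITEMS:
        raise ValueError(f"expected {N_PARCA_ITEMS} items, got {frame.shape[1]}")
    score = frame.sum(axis=1).astype("Int64")
    score[frame.isna().any(axis=1)] = pd.NA
    if single:
        return score.iloc[0]
    return score


def classify_nvc(score, config: OutcomeConfig = OutcomeConfig()):
    """1 iff score < threshold; missing propagates."""
    if np.isscalar(score) or score is pd.NA:
        if score is pd.NA or (isinstance(score, float) and np.isnan(score)):
            return pd.NA
        return int(score < config.nvc_threshold)
    s = pd.Series(score).astype("Int64")
    return (s < config.nvc_threshold).astype("Int64").where(s.notna(), pd.NA)


def _kleene_any(frame: pd.DataFrame) -> pd.Series:
    """Three-valued OR across columns: 1 if any 1, 0 if all observed 0, else NA."""
    any_one = (frame == 1).any(axis=1)
    all_zero = frame.notna().all(axis=1) & (frame == 0).all(axis=1)
    out = pd.Series(pd.NA, index=frame.index, dtype="Int64")
    out[all_zero] = 0
    out[any_one] = 1
    return out


def derive_impairment(motor_items, nvc_flag):
    """Composite impairment = gross-motor OR NVC flag, with Kleene logic.

    ``motor_items`` may be a DataFrame (rows) or a 3-long sequence;
    ``nvc_flag`` a Series or scalar (0/1/NA).
    """
    single = not isinstance(motor_items, pd.DataFrame)
    motor = _as_frame(motor_items, list(MOTOR_ITEMS) if single else None)
    if motor.shape[1] != len(MOTOR_ITEMS):
        raise ValueError("expected 3 gross-motor items")
    if single:
        nvc = pd.Series([nvc_flag], dtype="Int64", index=motor.index)
    else:
        nvc = pd.Series(nvc_flag, index=motor.index).astype("Int64")
    combined = motor.copy()
    combined["nvc"] = nvc
    out = _kleene_any(combined)
    return out.iloc[0] if single else out


def derive_outcomes(table: CohortTable, config: OutcomeConfig = OutcomeConfig()) -> CohortTable:
    """Add ``nvc_score`` and ``impaired_observed`` columns to a cohort copy."""
    out = table.copy()
    score = score_parca(out.df[list(PARCA_ITEMS)])
    nvc = classify_nvc(score, config)
    out.df["nvc_score"] = score
    out.df["impaired_observed"] = derive_impairment(out.df[list(config.motor_item_names)], nvc)
    return out


def apply_eligibility(table: CohortTable, flags: EligibilityFlags) -> tuple[CohortTable, dict]:
    """Remove excluded children, sequentially per reason; return the counts.

    Exclusions are applied in order — deaths, then severe congenital anomalies
    among the remainder, then deaf/blind children among what remains — so each
    child is counted once under the first applicable reason.
    """
    if any(len(getattr(flags, f)) != table.n for f in
           ("died_before_2y", "severe_congenital_anomaly", "deaf_or_blind")):
        raise ValueError("eligibility flags do not align with the cohort rows")
    keep = np.ones(table.n, dtype=bool)
    log: dict[str, int] = {}
    for reason, arr in (("died_before_2y", flags.died_before_2y),
                        ("severe_congenital_anomaly", flags.severe_congenital_anomaly),
                        ("deaf_or_blind", flags.deaf_or_blind)):
        removed = keep & (arr == 1)
        log[reason] = int(removed.sum())
        keep &= arr == 0
    log["remaining"] = int(keep.sum())
    logger.info("eligibility exclusions: %s", log)
    if log["remaining"] == 0:
        logger.warning("all children excluded: resulting table is empty")
    out = CohortTable(table.df.loc[keep].reset_index(drop=True),
                      dict(table.covariates), tuple(table.regions))
    return out, log
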