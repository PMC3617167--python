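"""Participant exclusion rules applied before the cohort analyses.

Two screens: a univariate z-score screen on the experimental measures
(reading speed, VA span, C, K by default) excluding any child whose
absolute z on one of them exceeds 2.5, and a model fit-quality screen
excluding children whose empirical-vs-fitted condition-mean correlation
is not strictly above 0.75.  The z screen is a single pass: means and SDs
come from the full input sample, including each candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreeningConfig", "ExclusionRecord", "zscore_outlier_screen", "fit_quality_screen"]

DEFAULT_VARIABLES = ("reading_speed", "va_span", "C", "K")


@dataclass(frozen=True)
class ScreeningConfig:
    z_threshold: float = 2.5
    fit_quality_threshold: float = 0.75
    variables: tuple[str, ...] = DEFAULT_VARIABLES

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.fit_quality_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ExclusionRecord:
    child_id: str
    rule: str  # "zscore" or "fit_quality"
    variable: str
    value: float
    statistic: float  # the z score or the fit-quality r


def zscore_outlier_screen(
    cohort: pd.DataFrame, config: ScreeningConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[ExclusionRecord]]:
    """Single-pass univariate outlier screen.

    Returns (kept, excluded, report).  z-scores use the sample mean and
    SD of the full input, candidate included.  Zero-variance variables
    are skipped with a warning rather than excluding everyone.
    """
    if config is None:
        config = ScreeningConfig()
    if len(cohort) < 3:
        raise ValueError("need at least 3 children to screen")
    present = [v for v in config.variables if v in cohort.columns]
    missing = set(config.variables) - set(present)
    if missing:
        raise ValueError(f"screened variables missing from cohort: {sorted(missing)}")

    report: list[ExclusionRecord] = []
    flagged = np.zeros(len(cohort), dtype=bool)
    for var in present:
        x = cohort[var].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"variable {var!r} has zero variance; skipped in z screen")
            continue
        z = (x - x.mean()) / sd
        bad = np.abs(z) > config.z_threshold
        flagged |= bad
        for i in np.nonzero(bad)[0]:
            report.append(
                ExclusionRecord(
                    child_id=str(cohort.iloc[i]["child_id"]),
                    rule="zscore",
                    variable=var,
                    value=float(x[i]),
                    statistic=float(z[i]),
                )
            )
    kept = cohort.loc[~flagged].reset_index(drop=True)
    excluded = cohort.loc[flagged].reset_index(drop=True)
    return kept, excluded, report


def fit_quality_screen(
    fit_qualities: pd.Series | dict[str, float],
    config: ScreeningConfig | None = None,
) -> tuple[list[str], list[ExclusionRecord]]:
    """Keep children whose fit-quality r is strictly above the threshold.

    ``fit_qualities`` maps child_id -> Pearson r between empirical and
    fitted condition means.  A child exactly at the threshold is excluded
    (the rule is "above", not "at or above").
    """
    if config is None:
        config = ScreeningConfig()
    if isinstance(fit_qualities, dict):
        fit_qualities = pd.Series(fit_qualities)
    kept: list[str] = []
    report: list[ExclusionRecord] = []
    for child_id, r in fit_qualities.items():
        if np.isfinite(r) and r > config.fit_quality_threshold:
            kept.append(str(child_id))
        else:
            report.append(
                ExclusionRecord(
                    child_id=str(child_id),
                    rule="fit_quality",
                    variable="fit_quality_r",
                    value=float(r),
                    statistic=float(r),
                )
            )
    return kept, report
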