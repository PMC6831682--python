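"""Outlier-exclusion rules for participants and trials.

Participant screening: a participant is excluded when their total nonword
count or their total repetition count lies more than ``sd_multiplier``
(default 2.5) sample standard deviations above the cohort mean of that
count.  Trial screening applies, per variable, one of three one-pass rules:

* ``"above"``  -- exclude values > mean + k*SD (used for WE and SN),
* ``"below"``  -- exclude values < mean - k*SD (used for RE),
* ``"boxplot"`` -- exclude values outside the Tukey fences
  [Q1 - c*IQR, Q3 + c*IQR] (used for M; c defaults to 1.5).

Thresholds are computed once on the full pre-exclusion distribution (no
re-iteration), so the pass is idempotent.  A covariate-sparsity filter
drops participants who are (nearly) alone in a covariate level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionRecord",
    "trial_rule_bounds",
    "apply_trial_rule",
    "participant_error_bounds",
    "DEFAULT_TRIAL_RULES",
]

#: Variable -> rule name, matching the study design.
DEFAULT_TRIAL_RULES: Dict[str, str] = {
    "WE": "above",
    "SN": "above",
    "RE": "below",
    "M": "boxplot",
}

_RULES = ("above", "below", "boxplot")


@dataclass(frozen=True)
class ExclusionRecord:
    """One excluded unit: who, which variable/rule, the value and threshold."""

    unit_id: str
    variable: str
    rule: str
    value: float
    threshold: float


def trial_rule_bounds(
    values: pd.Series, rule: str, sd_multiplier: float = 2.5, iqr_coef: float = 1.5
) -> Tuple[float, float]:
    """(lower, upper) keep-bounds for one variable; infinities where one-sided."""
    if rule not in _RULES:
        raise ValueError(f"unknown exclusion rule {rule!r}; expected one of {_RULES}")
    v = values.dropna().to_numpy(float)
    if rule == "boxplot":
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        return float(q1 - iqr_coef * iqr), float(q3 + iqr_coef * iqr)
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    if rule == "above":
        return -np.inf, mean + sd_multiplier * sd
    return mean - sd_multiplier * sd, np.inf


def apply_trial_rule(
    values: pd.Series, rule: str, sd_multiplier: float = 2.5, iqr_coef: float = 1.5
) -> pd.Series:
    """Boolean keep-mask (NaN values are kept: the rule cannot judge them)."""
    lo, hi = trial_rule_bounds(values, rule, sd_multiplier, iqr_coef)
    return values.isna() | ((values >= lo) & (values <= hi))


def participant_error_bounds(
    totals: pd.DataFrame, sd_multiplier: float = 2.5
) -> Dict[str, float]:
    """Upper keep-thresholds for per-participant nonword/repetition totals.

    ``totals`` must have columns ``n_nonword`` and ``n_repetition``, one row
    per participant.  With fewer than 3 participants the SD is meaningless
    and thresholds are +inf (nobody excluded).
    """
    out: Dict[str, float] = {}
    for col in ("n_nonword", "n_repetition"):
        v = totals[col].to_numpy(float)
        if v.size < 3:
            out[col] = np.inf
        else:
            out[col] = float(np.mean(v) + sd_multiplier * np.std(v, ddof=1))
    return out
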