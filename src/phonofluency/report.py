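"""Cohort-level descriptive analysis and export for external modeling.

Covers the descriptive half of the study design: per-variable summaries,
the pairwise correlation table over the seven dependent variables, the
response-type and hop breakdowns, the SN > 0.5 strategy split, and the
analysis-ready table handed to external multivariate regression (which is
deliberately not re-implemented here -- it is stock statistical software).
"""

from __future__ import annotations

import json
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .networks import DISCONNECTED

__all__ = [
    "DEPENDENT_VARIABLES",
    "descriptives",
    "correlation_table",
    "response_type_breakdown",
    "strategy_split",
    "export_model_table",
    "code_multilingual",
]

#: The seven per-trial dependent variables of the analysis.
DEPENDENT_VARIABLES = ("WE", "RE", "SN", "Error", "CC", "M", "NC")

COVARIATES = ("english", "num_chinese", "multilingual")


def descriptives(
    scores: pd.DataFrame, variables: Sequence[str] = DEPENDENT_VARIABLES
) -> pd.DataFrame:
    """Min, max, mean and (sample) SD per variable, one row each."""
    if scores.empty:
        raise ValueError("empty score table")
    rows = []
    for var in variables:
        v = scores[var].dropna().to_numpy(float)
        rows.append(
            {
                "variable": var,
                "min": float(np.min(v)),
                "max": float(np.max(v)),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def correlation_table(
    scores: pd.DataFrame,
    variables: Sequence[str] = DEPENDENT_VARIABLES,
    method: str = "pearson",
    level: str = "trial",
) -> pd.DataFrame:
    """Pairwise-complete correlation matrix of the dependent variables.

    ``level="participant"`` averages each variable within participant first
    (both readings of a trial-level design are defensible; the default is
    trial-level).  Zero-variance variables get NaN correlations.
    """
    if level not in ("trial", "participant"):
        raise ValueError(f"unknown level {level!r}")
    df = scores
    if level == "participant":
        df = scores.groupby("participant_id")[list(variables)].mean().reset_index()
    sub = df[list(variables)].astype(float)
    corr = sub.corr(method=method)  # pairwise-complete by construction
    # pandas leaves the diagonal of an all-NaN column at 1; force NaN there
    for var in variables:
        if sub[var].dropna().nunique() <= 1:
            corr.loc[var, :] = np.nan
            corr.loc[:, var] = np.nan
    return corr


def _hop_bins(scores: pd.DataFrame) -> Dict[str, int]:
    bins: Dict[str, int] = {}
    for blob in scores["hops"]:
        for key, count in json.loads(blob).items():
            bins[key] = bins.get(key, 0) + int(count)
    return bins


def response_type_breakdown(scores: pd.DataFrame) -> Dict[str, Dict[str, float]]:
    """Proportions of correct/nonword/repetition productions and hop bins.

    Hop proportions are over correct unique network nodes; hop keys are
    ``"1"``, ``"2"``, ... plus ``"disconnected"`` for nodes that share no
    path with the stimulus.  Each breakdown sums to 1.
    """
    n_by_type = {
        "correct": int(scores["n_correct"].sum()),
        "nonword": int(scores["n_nonword"].sum()),
        "repetition": int(scores["n_repetition"].sum()),
    }
    total = sum(n_by_type.values())
    type_props = {k: v / total for k, v in n_by_type.items()} if total else {}
    bins = _hop_bins(scores)
    hop_total = sum(bins.values())
    hop_props = {k: v / hop_total for k, v in bins.items()} if hop_total else {}
    return {"response_types": type_props, "hops": hop_props}


def strategy_split(scores: pd.DataFrame, threshold: float = 0.50) -> float:
    """Fraction of trials with SN strictly above the threshold.

    Trials above the split are predominantly syllable-driven (tone-family
    enumeration); the rest are predominantly segment-driven.
    """
    sn = scores["SN"].dropna()
    if sn.empty:
        return 0.0
    return float((sn > threshold).mean())


def code_multilingual(ratings: Iterable[float]) -> int:
    """1 if more than one language is self-rated 9-10, else 0."""
    return int(sum(9 <= r <= 10 for r in ratings) > 1)


def export_model_table(
    scores: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """One row per participant-trial: IDs, covariates, all dependent variables.

    Rows whose participant lacks covariates are flagged
    (``covariates_missing``), never dropped silently.  The result feeds
    external multivariate regression software unchanged.
    """
    cov = participants[["participant_id"] + [c for c in COVARIATES
                                             if c in participants.columns]]
    out = scores.merge(cov, on="participant_id", how="left")
    present = [c for c in COVARIATES if c in out.columns]
    out["covariates_missing"] = out[present].isna().any(axis=1) if present else True
    cols = (
        ["participant_id", "trial_id", "stimulus"]
        + present
        + list(DEPENDENT_VARIABLES)
        + ["covariates_missing"]
    )
    return out[cols]
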