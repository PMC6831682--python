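"""Table-level pipeline: scoring and outlier-exclusion transformers.

The steps that map tables to tables are scikit-learn estimators, so they
compose with :class:`sklearn.pipeline.Pipeline` and carry their settings
through ``get_params``/``set_params``:

* :class:`FluencyScorer` -- response table in, per-trial score table out
  (fluency scores, error counts, and the network measures).
* :class:`ParticipantErrorFilter` -- drops participants with excessive
  nonword/repetition totals (> mean + k*SD).
* :class:`TrialOutlierFilter` -- drops trial-level outliers per variable
  (one-sided SD rules for WE/SN/RE, Tukey fences for M).
* :class:`CovariateCellFilter` -- drops participants nearly alone in a
  covariate level.

The input response table has one production per row with columns
``participant_id, trial_id, stimulus, response_index, response_pinyin``.
"""

from __future__ import annotations

import json
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import networks, qc, scoring
from .syllables import (
    SyllableMapping,
    load_default_lexicon,
    load_default_mapping,
    load_lexicon,
)

__all__ = [
    "FluencyScorer",
    "TrialOutlierFilter",
    "ParticipantErrorFilter",
    "CovariateCellFilter",
    "trials_from_table",
    "score_responses",
]

RESPONSE_COLUMNS = (
    "participant_id",
    "trial_id",
    "stimulus",
    "response_index",
    "response_pinyin",
)


def _check_columns(X: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in X.columns]
    if missing:
        raise ValueError(f"input table is missing required columns {missing}")


def trials_from_table(
    X: pd.DataFrame, mapping: SyllableMapping, lexicon: Optional[Set[str]] = None
) -> List[scoring.Trial]:
    """Parse a long-format response table into (optionally classified) trials."""
    _check_columns(X, RESPONSE_COLUMNS)
    trials = []
    for (pid, tid), grp in X.groupby(["participant_id", "trial_id"], sort=True):
        grp = grp.sort_values("response_index")
        stims = grp["stimulus"].unique()
        if len(stims) != 1:
            raise ValueError(f"trial {tid!r} of participant {pid!r} has multiple stimuli")
        try:
            stimulus = mapping.parse(str(stims[0]))
            productions = [
                scoring.Production(index=int(row.response_index),
                                   syllable=mapping.parse(str(row.response_pinyin)))
                for row in grp.itertuples()
            ]
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"participant {pid!r}, trial {tid!r}: {exc}") from exc
        trial = scoring.Trial(str(pid), str(tid), stimulus, productions)
        if lexicon is not None:
            trial = scoring.classify_productions(trial, lexicon)
        trials.append(trial)
    return trials


class FluencyScorer(BaseEstimator, TransformerMixin):
    """Transform a response table into the per-trial analysis table.

    Parameters
    ----------
    mapping : SyllableMapping, path, or None
        Atonal-pinyin segmentation table; the packaged fixture by default.
    lexicon : set of tonal strings, path, or None
        Word list used to classify nonwords; the packaged toy list by default.
    include_stimulus : bool
        Include the stimulus node in the structural network measures
        (the alternative convention); hops always include it.
    """

    def __init__(self, mapping=None, lexicon=None, include_stimulus: bool = False):
        self.mapping = mapping
        self.lexicon = lexicon
        self.include_stimulus = include_stimulus

    def fit(self, X=None, y=None) -> "FluencyScorer":
        if isinstance(self.mapping, SyllableMapping):
            self.mapping_ = self.mapping
        elif self.mapping is None:
            self.mapping_ = load_default_mapping()
        else:
            self.mapping_ = SyllableMapping.from_tsv(self.mapping)
        if isinstance(self.lexicon, (set, frozenset)):
            self.lexicon_ = set(self.lexicon)
        elif self.lexicon is None:
            self.lexicon_ = load_default_lexicon()
        else:
            self.lexicon_ = load_lexicon(self.lexicon)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mapping_"):
            raise RuntimeError("FluencyScorer must be fitted before transform")
        trials = trials_from_table(X, self.mapping_, self.lexicon_)
        rows = []
        for trial in trials:
            score = scoring.score_trial(trial)
            net = networks.build_network(trial, include_stimulus=self.include_stimulus)
            hops = {str(k): v for k, v in net.hops.items()}
            rows.append(
                {
                    "participant_id": score.participant_id,
                    "trial_id": score.trial_id,
                    "stimulus": trial.stimulus.label,
                    "WE": score.WE,
                    "RE": score.RE,
                    "SN": score.SN,
                    "Error": score.Error,
                    "n_productions": score.n_productions,
                    "n_correct": score.n_correct,
                    "n_nonword": score.n_nonword,
                    "n_repetition": score.n_repetition,
                    "NC": net.NC if net.NC is not None else np.nan,
                    "CC": net.CC,
                    "M": net.M,
                    "hop1": net.hop_count(1),
                    "hop2": net.hop_count(2),
                    "n_disconnected": net.n_disconnected,
                    "hops": json.dumps(hops, sort_keys=True),
                }
            )
        return pd.DataFrame(rows)

    def networks(self, X: pd.DataFrame) -> List[networks.FluencyNetwork]:
        """The per-trial networks themselves (for export or plotting)."""
        trials = trials_from_table(X, self.mapping_, self.lexicon_)
        return [networks.build_network(t, include_stimulus=self.include_stimulus)
                for t in trials]


class ParticipantErrorFilter(BaseEstimator, TransformerMixin):
    """Drop participants whose nonword or repetition totals are extreme.

    A participant is excluded when either total lies more than
    ``sd_multiplier`` standard deviations above the cohort mean of that
    total.  Thresholds are learned in :meth:`fit` on the pre-exclusion
    cohort, in a single pass.
    """

    def __init__(self, sd_multiplier: float = 2.5):
        self.sd_multiplier = sd_multiplier

    def fit(self, X: pd.DataFrame, y=None) -> "ParticipantErrorFilter":
        _check_columns(X, ("participant_id", "n_nonword", "n_repetition"))
        totals = X.groupby("participant_id")[["n_nonword", "n_repetition"]].sum()
        if len(totals) < 3:
            import warnings

            warnings.warn("fewer than 3 participants: SD undefined, nobody excluded")
        self.thresholds_ = qc.participant_error_bounds(totals, self.sd_multiplier)
        records = []
        excluded = set()
        for col, reason in (("n_nonword", "nonwords"), ("n_repetition", "repetitions")):
            bad = totals.index[totals[col] > self.thresholds_[col]]
            for pid in bad:
                records.append(
                    qc.ExclusionRecord(str(pid), reason, "above",
                                       float(totals.loc[pid, col]),
                                       self.thresholds_[col])
                )
                excluded.add(str(pid))
        self.exclusions_ = records
        self.excluded_participants_ = sorted(excluded)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keep = ~X["participant_id"].astype(str).isin(self.excluded_participants_)
        return X.loc[keep].reset_index(drop=True)


class TrialOutlierFilter(BaseEstimator, TransformerMixin):
    """Drop trial-level outliers, one rule per score variable.

    ``rules`` maps a column name to ``"above"``, ``"below"`` or
    ``"boxplot"``; the default reproduces the study's screen (WE and SN
    above-only at 2.5 SD, RE below-only, M by Tukey fences).
    """

    def __init__(
        self,
        rules: Optional[Dict[str, str]] = None,
        sd_multiplier: float = 2.5,
        iqr_coef: float = 1.5,
    ):
        self.rules = rules
        self.sd_multiplier = sd_multiplier
        self.iqr_coef = iqr_coef

    def fit(self, X: pd.DataFrame, y=None) -> "TrialOutlierFilter":
        rules = self.rules if self.rules is not None else dict(qc.DEFAULT_TRIAL_RULES)
        _check_columns(X, list(rules))
        self.bounds_ = {
            var: qc.trial_rule_bounds(X[var], rule, self.sd_multiplier, self.iqr_coef)
            for var, rule in rules.items()
        }
        self.rules_ = dict(rules)
        # record the exclusions on the fitted table (thresholds are one-pass)
        records: List[qc.ExclusionRecord] = []
        keep = pd.Series(True, index=X.index)
        for var, rule in self.rules_.items():
            lo, hi = self.bounds_[var]
            mask = X[var].isna() | ((X[var] >= lo) & (X[var] <= hi))
            for idx in X.index[~mask]:
                unit = f"{X.at[idx, 'participant_id']}/{X.at[idx, 'trial_id']}" \
                    if "trial_id" in X.columns else str(idx)
                bound = hi if rule == "above" else lo if rule == "below" else np.nan
                records.append(
                    qc.ExclusionRecord(unit, var, rule, float(X.at[idx, var]), float(bound))
                )
            keep &= mask
        self.exclusions_ = records
        self.n_excluded_ = int((~keep).sum())
        self.exclusion_fraction_ = float((~keep).mean()) if len(X) else 0.0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keep = pd.Series(True, index=X.index)
        for var in self.rules_:
            lo, hi = self.bounds_[var]
            keep &= X[var].isna() | ((X[var] >= lo) & (X[var] <= hi))
        return X.loc[keep].reset_index(drop=True)

    def summary(self) -> Dict[str, object]:
        """Counts per variable and the overall excluded fraction."""
        per_var: Dict[str, int] = {}
        for rec in self.exclusions_:
            per_var[rec.variable] = per_var.get(rec.variable, 0) + 1
        return {
            "per_variable": per_var,
            "n_excluded": self.n_excluded_,
            "fraction_excluded": self.exclusion_fraction_,
        }


class CovariateCellFilter(BaseEstimator, TransformerMixin):
    """Drop participants who occupy a covariate level below a minimum count."""

    def __init__(self, columns: Sequence[str] = ("english", "num_chinese"),
                 min_count: int = 2):
        self.columns = columns
        self.min_count = min_count

    def fit(self, X: pd.DataFrame, y=None) -> "CovariateCellFilter":
        _check_columns(X, list(self.columns) + ["participant_id"])
        per_participant = X.drop_duplicates("participant_id")
        excluded: Set[str] = set()
        self.sparse_levels_ = {}
        for col in self.columns:
            counts = per_participant[col].value_counts()
            sparse = counts.index[counts < self.min_count]
            self.sparse_levels_[col] = sorted(sparse.tolist())
            bad = per_participant.loc[per_participant[col].isin(sparse), "participant_id"]
            excluded.update(bad.astype(str))
        self.excluded_participants_ = sorted(excluded)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keep = ~X["participant_id"].astype(str).isin(self.excluded_participants_)
        return X.loc[keep].reset_index(drop=True)


def score_responses(
    X: pd.DataFrame, mapping=None, lexicon=None, include_stimulus: bool = False
) -> pd.DataFrame:
    """One-shot convenience wrapper around :class:`FluencyScorer`."""
    return FluencyScorer(mapping, lexicon, include_stimulus).fit().transform(X)
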