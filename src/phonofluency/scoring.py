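"""Per-trial fluency scoring: WE, RE, SN, Error and response classification.

A trial is one minute of free production to a single auditory stimulus.
Each production is classified against a lexicon: a *repetition* is an exact
tonal-syllable match to any earlier production in the same trial (tone
variants of one base are distinct legitimate responses, so repetition is
tonal, not atonal); a *nonword* is a first occurrence absent from the
lexicon; everything else is a correct response.  A repeated nonword counts
once as a nonword and thereafter as repetitions, so the three categories
partition the stream.  Error is the sum of nonwords and repetitions.

The scores:

* ``WE`` (weighted edit) -- the graded fluency score: the sum over correct
  responses of the edit weight between stimulus and response.
* ``RE`` (running edit) -- the mean edit weight over consecutive production
  pairs, errors included; 1 means every production was an immediate
  neighbor of the one before it, low values mean repeated mental jumps.
* ``SN`` -- the proportion of consecutive pairs that are syllable neighbors
  (share the atonal base), errors included.  Exact repetitions share their
  own base and therefore count.

RE and SN need at least two productions and are reported missing (NaN)
otherwise, so degenerate trials do not masquerade as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Set

from .metric import edit_weight, is_syllable_neighbor
from .syllables import SegmentedSyllable

__all__ = [
    "Production",
    "Trial",
    "TrialScore",
    "classify_productions",
    "score_WE",
    "score_RE",
    "score_SN",
    "score_error",
    "score_trial",
]


@dataclass(frozen=True)
class Production:
    """One transcribed response within a trial."""

    index: int
    syllable: SegmentedSyllable
    is_word: Optional[bool] = None
    is_repetition: Optional[bool] = None

    @property
    def is_correct(self) -> bool:
        if self.is_word is None or self.is_repetition is None:
            raise ValueError("production not yet classified")
        return self.is_word and not self.is_repetition

    @property
    def category(self) -> str:
        """'correct' | 'repetition' | 'nonword' (repetition takes precedence)."""
        if self.is_repetition:
            return "repetition"
        return "correct" if self.is_word else "nonword"


@dataclass
class Trial:
    """Stimulus plus the ordered production stream of one participant-trial."""

    participant_id: str
    trial_id: str
    stimulus: SegmentedSyllable
    productions: List[Production] = field(default_factory=list)

    @property
    def is_classified(self) -> bool:
        return all(p.is_word is not None for p in self.productions)


@dataclass(frozen=True)
class TrialScore:
    """All per-trial dependent variables except the network measures."""

    participant_id: str
    trial_id: str
    WE: float
    RE: float  # NaN when fewer than two productions
    SN: float  # NaN when fewer than two productions
    Error: int
    n_productions: int
    n_correct: int
    n_nonword: int
    n_repetition: int


def classify_productions(trial: Trial, lexicon: Set[str]) -> Trial:
    """Return the trial with word/repetition flags set on every production.

    ``lexicon`` is a set of tonal pinyin strings (the word list); membership
    is tested on the production's label.
    """
    seen: set = set()
    flagged: List[Production] = []
    for p in trial.productions:
        key = p.syllable.slots
        is_rep = key in seen
        seen.add(key)
        label = p.syllable.label or str(p.syllable)
        flagged.append(replace(p, is_word=label in lexicon, is_repetition=is_rep))
    return Trial(trial.participant_id, trial.trial_id, trial.stimulus, flagged)


def _require_classified(trial: Trial) -> None:
    if not trial.is_classified:
        raise ValueError(
            f"trial {trial.trial_id!r} of participant {trial.participant_id!r} "
            "must be classified before scoring"
        )


def score_WE(trial: Trial) -> float:
    """Weighted-edit fluency: sum of stimulus-response weights over correct items."""
    _require_classified(trial)
    return float(
        sum(edit_weight(trial.stimulus, p.syllable) for p in trial.productions if p.is_correct)
    )


def score_RE(trial: Trial) -> float:
    """Running edit: mean successive weight over ALL productions; NaN if < 2."""
    syls = [p.syllable for p in trial.productions]
    if len(syls) < 2:
        return math.nan
    weights = [edit_weight(a, b) for a, b in zip(syls, syls[1:])]
    return float(sum(weights) / len(weights))


def score_SN(trial: Trial) -> float:
    """Proportion of successive syllable-neighbor pairs; NaN if < 2 productions."""
    syls = [p.syllable for p in trial.productions]
    if len(syls) < 2:
        return math.nan
    hits = sum(is_syllable_neighbor(a, b) for a, b in zip(syls, syls[1:]))
    return float(hits / (len(syls) - 1))


def score_error(trial: Trial) -> int:
    """Error = nonword productions + repetitions."""
    _require_classified(trial)
    return sum(p.category != "correct" for p in trial.productions)


def score_trial(trial: Trial) -> TrialScore:
    """All fluency scores and category counts for one classified trial."""
    _require_classified(trial)
    cats = [p.category for p in trial.productions]
    return TrialScore(
        participant_id=trial.participant_id,
        trial_id=trial.trial_id,
        WE=score_WE(trial),
        RE=score_RE(trial),
        SN=score_SN(trial),
        Error=score_error(trial),
        n_productions=len(cats),
        n_correct=cats.count("correct"),
        n_nonword=cats.count("nonword"),
        n_repetition=cats.count("repetition"),
    )
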