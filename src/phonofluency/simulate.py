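"""Synthetic lexicons and cohorts with known ground-truth search strategy.

The study's raw recordings cannot ship with a software package, so this
module generates what the scoring pipeline consumes: one-minute response
streams to monosyllabic stimuli, produced by a simple generative model of
mental search with two move types,

* **segment-driven** moves mutate a single slot (C, G, V, X or T) of the
  previous production, yielding an immediate phonological neighbor;
* **syllable-driven** moves enumerate the remaining tone variants of the
  current atonal base in sequence (a tone-family run), whether or not the
  variants are words -- the signature that drives SN upward and produces
  nonword errors;

plus long-range *jumps* that abandon successive similarity and start a new
network component.  A move is syllable-driven with probability
``p_syllable``, a jump with probability ``p_jump``; repetition errors
re-emit an earlier item at rate ``error_repetition_rate`` and
``error_nonword_rate`` is the chance a segment-driven move tolerates a
nonword outcome.

Participant covariates (self-rated English proficiency 5-8, number of
Chinese languages/dialects 1-3, multilingual status) shift these parameters
through logit-linear links; the default effect signs follow the observed
directions (higher English -> fewer errors and less syllable-driven search;
more Chinese languages -> more jumping, hence lower running-edit similarity
and less coherent networks).  Ground-truth parameters are stored per
participant so that recovery tests can close the loop.

Everything here is synthetic and is never a stand-in for the study's data;
it exists so the pipeline is testable end to end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .metric import edit_distance
from .scoring import Production, Trial
from .syllables import SegmentedSyllable, SyllableMapping

__all__ = [
    "ToyLexicon",
    "StrategyParams",
    "CohortEffects",
    "SyntheticCohort",
    "generate_lexicon",
    "generate_trial",
    "generate_cohort",
    "DEFAULT_INVENTORY",
]

log = logging.getLogger(__name__)

#: Slot alphabets of the default toy inventory.  The alphabets are pairwise
#: disjoint so that concatenating filled slots yields a unique romanization.
DEFAULT_INVENTORY: Dict[str, Sequence[Optional[str]]] = {
    "C": (None, "p", "t", "k", "m", "s", "l", "f"),
    "G": (None, "w", "j"),
    "V": ("a", "e", "i", "o", "u"),
    "X": (None, "n", "r"),
}

TONES = (1, 2, 3, 4)


@dataclass
class ToyLexicon:
    """A closed syllable inventory with a designated subset of real words."""

    mapping: SyllableMapping
    words: Set[str]  # tonal pinyin strings
    inventory: Dict[str, Sequence[Optional[str]]]
    word_probability: float

    def is_word(self, tonal: str) -> bool:
        return tonal in self.words

    def parse(self, tonal: str) -> SegmentedSyllable:
        return self.mapping.parse(tonal)

    def render(self, syl: SegmentedSyllable) -> str:
        return self.mapping.render(syl)

    @property
    def all_tonal(self) -> List[str]:
        return [f"{a}{t}" for a in self.mapping.entries for t in TONES]


def generate_lexicon(
    inventory: Optional[Dict[str, Sequence[Optional[str]]]] = None,
    word_probability: float = 0.7,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ToyLexicon:
    """Enumerate the inventory and mark each tonal syllable a word at random."""
    inventory = dict(inventory or DEFAULT_INVENTORY)
    rng = rng if rng is not None else np.random.default_rng(seed)
    combos = [
        (c, g, v, x)
        for c in inventory["C"]
        for g in inventory["G"]
        for v in inventory["V"]
        for x in inventory["X"]
    ]
    if len(combos) < 2:
        raise ValueError("degenerate inventory: fewer than two syllable combinations")
    entries = {"".join(s for s in combo if s is not None): combo for combo in combos}
    if len(entries) != len(combos):
        raise ValueError("inventory alphabets are not disjoint: romanizations collide")
    mapping = SyllableMapping(entries, provenance_note="synthetic toy inventory")
    words = {
        f"{atonal}{t}"
        for atonal in sorted(entries)
        for t in TONES
        if rng.random() < word_probability
    }
    return ToyLexicon(mapping, words, inventory, word_probability)


@dataclass(frozen=True)
class StrategyParams:
    """Generative search parameters of one participant."""

    p_syllable: float = 0.18
    p_jump: float = 0.10
    jump_home: float = 0.6  # chance a jump re-anchors near the stimulus (edit <= 2)
    p_tone_mutation: float = 0.10  # chance a segment-driven move substitutes tone
    error_nonword_rate: float = 0.15
    error_repetition_rate: float = 0.06
    trial_length_mean: float = 14.0
    trial_length_dispersion: float = 12.0  # negative-binomial size parameter
    max_length: int = 30
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("p_syllable", "p_jump", "error_nonword_rate", "error_repetition_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _draw_length(strategy: StrategyParams, rng: np.random.Generator) -> int:
    n = strategy.trial_length_dispersion
    p = n / (n + strategy.trial_length_mean)
    return int(np.clip(rng.negative_binomial(n, p), 2, strategy.max_length))


def _segment_mutations(syl: SegmentedSyllable, lexicon: ToyLexicon) -> List[SegmentedSyllable]:
    """All single-segmental-slot variants of a syllable within the inventory."""
    inv = lexicon.inventory
    out: List[SegmentedSyllable] = []
    c, g, v, x, t = syl.slots
    for cc in inv["C"]:
        if cc != c:
            out.append(SegmentedSyllable(cc, g, v, x, t))
    for gg in inv["G"]:
        if gg != g:
            out.append(SegmentedSyllable(c, gg, v, x, t))
    for vv in inv["V"]:
        if vv != v:
            out.append(SegmentedSyllable(c, g, vv, x, t))
    for xx in inv["X"]:
        if xx != x:
            out.append(SegmentedSyllable(c, g, v, xx, t))
    return out


def _tone_mutations(syl: SegmentedSyllable) -> List[SegmentedSyllable]:
    c, g, v, x, t = syl.slots
    return [SegmentedSyllable(c, g, v, x, tt) for tt in TONES if tt != t]


def _mutations(syl: SegmentedSyllable, lexicon: ToyLexicon) -> List[SegmentedSyllable]:
    """All single-slot variants (segmental slots and tone)."""
    return _segment_mutations(syl, lexicon) + _tone_mutations(syl)


def generate_trial(
    stimulus: str | SegmentedSyllable,
    strategy: StrategyParams,
    lexicon: ToyLexicon,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "sim",
    trial_id: str = "t0",
) -> Trial:
    """One simulated response stream (unclassified productions, in order)."""
    rng = rng if rng is not None else np.random.default_rng(
        seed if seed is not None else strategy.seed
    )
    stim = lexicon.parse(stimulus) if isinstance(stimulus, str) else stimulus
    target = _draw_length(strategy, rng)
    productions: List[Production] = []
    all_words = sorted(lexicon.words)
    emitted: Set[tuple] = set()
    queue: List[SegmentedSyllable] = []  # pending tone-family run
    current = stim

    def emit(s: SegmentedSyllable) -> SegmentedSyllable:
        labelled = replace(s, label=lexicon.render(s))
        productions.append(Production(index=len(productions), syllable=labelled))
        emitted.add(s.slots)
        return labelled

    while len(productions) < target:
        if queue:
            current = emit(queue.pop(0))
            continue
        if productions and rng.random() < strategy.error_repetition_rate:
            past = productions[int(rng.integers(len(productions)))].syllable
            current = emit(SegmentedSyllable(*past.slots))
            continue
        if rng.random() < strategy.p_syllable:
            family = [
                SegmentedSyllable(*current.atonal, t)
                for t in TONES
                if t != current.tone and (*current.atonal, t) not in emitted
            ]
            if family:
                queue = family  # ascending tone order, emitted successively
                continue
        if rng.random() < strategy.p_jump:
            pool = all_words
            if rng.random() < strategy.jump_home:
                near = [w for w in all_words if edit_distance(stim, lexicon.parse(w)) <= 2]
                pool = near or all_words
            choices = [w for w in pool if lexicon.parse(w).slots not in emitted]
            if choices:
                current = emit(lexicon.parse(choices[int(rng.integers(len(choices)))]))
                continue
        # segment-driven move: mutate one slot of the previous item.  Tone
        # substitution is a legitimate neighbor move but a minority habit in
        # segment-driven search (it creates a syllable neighbor, the
        # signature of the other strategy), hence its own low weight.
        if rng.random() < strategy.p_tone_mutation:
            primary = _tone_mutations(current)
            fallback = _segment_mutations(current, lexicon)
        else:
            primary = _segment_mutations(current, lexicon)
            fallback = _tone_mutations(current)
        neighbors = [m for m in primary if m.slots not in emitted] or [
            m for m in fallback if m.slots not in emitted
        ]
        if not neighbors:
            break  # search dead-end: truncate the trial (logged below)
        if rng.random() >= strategy.error_nonword_rate:
            word_neighbors = [m for m in neighbors if lexicon.is_word(lexicon.render(m))]
            if word_neighbors:
                neighbors = word_neighbors
        current = emit(neighbors[int(rng.integers(len(neighbors)))])
    if len(productions) < target:
        log.info(
            "trial %s/%s truncated at %d of %d productions (search dead-end)",
            participant_id, trial_id, len(productions), target,
        )
    return Trial(participant_id, trial_id, stim, productions)


@dataclass(frozen=True)
class CohortEffects:
    """Logit-scale covariate -> parameter links (signs follow the study)."""

    english_on_p_syllable: float = -0.35
    english_on_nonword_rate: float = -0.35
    num_chinese_on_p_jump: float = 0.55
    num_chinese_on_p_syllable: float = -0.20
    multilingual_on_error: float = -0.30
    participant_sd: float = 0.55  # participant-level logit noise

    base_p_syllable: float = 0.18
    base_p_jump: float = 0.10
    base_nonword_rate: float = 0.15
    base_repetition_rate: float = 0.06


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# Marginal distributions of the covariates (levels and probabilities chosen
# to match the published cohort means/SDs: English M 6.74, SD 0.94 on levels
# 5-8; Num_Chinese M 1.92, SD 0.66 on levels 1-3; 47/95 multilingual).
_ENGLISH_LEVELS = (5, 6, 7, 8)
_ENGLISH_PROBS = (0.12, 0.28, 0.34, 0.26)
_NUM_CHINESE_LEVELS = (1, 2, 3)
_NUM_CHINESE_PROBS = (0.27, 0.54, 0.19)
_P_MULTILINGUAL = 47 / 95


@dataclass
class SyntheticCohort:
    """Generated participants, their trials, and the ground truth behind them."""

    lexicon: ToyLexicon
    stimuli: List[str]
    participants: pd.DataFrame  # covariates + true strategy parameters
    trials: List[Trial]

    def response_table(self) -> pd.DataFrame:
        """The long-format table the scoring pipeline reads."""
        rows = []
        for trial in self.trials:
            for p in trial.productions:
                rows.append(
                    {
                        "participant_id": trial.participant_id,
                        "trial_id": trial.trial_id,
                        "stimulus": trial.stimulus.label,
                        "response_index": p.index,
                        "response_pinyin": p.syllable.label,
                    }
                )
        return pd.DataFrame(rows)

    def ground_truth(self) -> pd.DataFrame:
        return self.participants.copy()


def _pick_stimuli(lexicon: ToyLexicon, n: int = 6) -> List[str]:
    """Deterministic stimuli: words richest in edit-1 word neighbors,
    one per atonal base (mirrors the varied-structure stimulus design)."""
    counts = []
    for w in sorted(lexicon.words):
        syl = lexicon.parse(w)
        k = sum(lexicon.is_word(lexicon.render(m)) for m in _mutations(syl, lexicon))
        counts.append((k, w))
    counts.sort(key=lambda t: (-t[0], t[1]))
    chosen: List[str] = []
    bases: Set[tuple] = set()
    for _, w in counts:
        base = lexicon.parse(w).atonal
        if base in bases:
            continue
        chosen.append(w)
        bases.add(base)
        if len(chosen) == n:
            break
    return chosen


def participant_params(
    english: int,
    num_chinese: int,
    multilingual: int,
    effects: CohortEffects,
    rng: np.random.Generator,
) -> StrategyParams:
    """Draw one participant's strategy parameters from the covariate links."""
    e = english - 6.74
    c = num_chinese - 1.92
    m = multilingual - 0.5
    sd = effects.participant_sd
    p_syl = _expit(
        _logit(effects.base_p_syllable)
        + effects.english_on_p_syllable * e
        + effects.num_chinese_on_p_syllable * c
        + rng.normal(0, sd)
    )
    p_jump = _expit(
        _logit(effects.base_p_jump) + effects.num_chinese_on_p_jump * c + rng.normal(0, sd)
    )
    nonword = _expit(
        _logit(effects.base_nonword_rate)
        + effects.english_on_nonword_rate * e
        + effects.multilingual_on_error * m
        + rng.normal(0, sd)
    )
    repetition = _expit(
        _logit(effects.base_repetition_rate)
        + effects.multilingual_on_error * m
        + rng.normal(0, sd)
    )
    return StrategyParams(
        p_syllable=float(np.clip(p_syl, 0.0, 1.0)),
        p_jump=float(np.clip(p_jump, 0.0, 1.0)),
        error_nonword_rate=float(np.clip(nonword, 0.0, 1.0)),
        error_repetition_rate=float(np.clip(repetition, 0.0, 1.0)),
    )


def generate_cohort(
    n_participants: int = 95,
    effects: Optional[CohortEffects] = None,
    lexicon: Optional[ToyLexicon] = None,
    word_probability: float = 0.7,
    seed: Optional[int] = None,
) -> SyntheticCohort:
    """A full cohort on the six-stimulus design, reproducible under ``seed``."""
    effects = effects or CohortEffects()
    rng = np.random.default_rng(seed)
    lexicon = lexicon or generate_lexicon(word_probability=word_probability, rng=rng)
    stimuli = _pick_stimuli(lexicon)
    rows = []
    trials: List[Trial] = []
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        english = int(rng.choice(_ENGLISH_LEVELS, p=_ENGLISH_PROBS))
        num_chinese = int(rng.choice(_NUM_CHINESE_LEVELS, p=_NUM_CHINESE_PROBS))
        multilingual = int(rng.random() < _P_MULTILINGUAL)
        params = participant_params(english, num_chinese, multilingual, effects, rng)
        rows.append(
            {
                "participant_id": pid,
                "english": english,
                "num_chinese": num_chinese,
                "multilingual": multilingual,
                "p_syllable": params.p_syllable,
                "p_jump": params.p_jump,
                "error_nonword_rate": params.error_nonword_rate,
                "error_repetition_rate": params.error_repetition_rate,
            }
        )
        for j, stim in enumerate(stimuli):
            trials.append(
                generate_trial(
                    stim,
                    params,
                    lexicon,
                    rng=rng,
                    participant_id=pid,
                    trial_id=f"{pid}-T{j + 1}",
                )
            )
    return SyntheticCohort(lexicon, stimuli, pd.DataFrame(rows), trials)
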