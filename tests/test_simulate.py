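"""Synthetic lexicons, trials and cohorts: determinism, ground-truth links,
and recovery of the planted search strategy by the scoring measures."""

import numpy as np
import pytest
from scipy import stats

from phonofluency import (
    CohortEffects,
    StrategyParams,
    classify_productions,
    generate_cohort,
    generate_lexicon,
    generate_trial,
    score_RE,
    score_SN,
    score_trial,
)


@pytest.fixture(scope="module")
def lex():
    return generate_lexicon(seed=11)


def test_lexicon_deterministic_under_seed():
    a = generate_lexicon(seed=5)
    b = generate_lexicon(seed=5)
    assert a.words == b.words and a.mapping.entries == b.mapping.entries
    c = generate_lexicon(seed=6)
    assert c.words != a.words


def test_lexicon_word_probability_extremes():
    full = generate_lexicon(word_probability=1.0, seed=0)
    assert len(full.words) == len(full.all_tonal)
    empty = generate_lexicon(word_probability=0.0, seed=0)
    assert not empty.words


def test_lexicon_word_count_within_binomial_bounds():
    lexicon = generate_lexicon(word_probability=0.7, seed=3)
    n = len(lexicon.all_tonal)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.7)
    assert lo <= len(lexicon.words) <= hi


def test_lexicon_degenerate_inventory_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        generate_lexicon({"C": (None,), "G": (None,), "V": ("a",), "X": (None,)})


def test_every_generated_production_is_parseable(lex):
    trial = generate_trial(sorted(lex.words)[0], StrategyParams(), lex, seed=1)
    for p in trial.productions:
        parsed = lex.parse(p.syllable.label)
        assert parsed == p.syllable


def test_trial_deterministic_under_seed(lex):
    stim = sorted(lex.words)[10]
    t1 = generate_trial(stim, StrategyParams(), lex, seed=9)
    t2 = generate_trial(stim, StrategyParams(), lex, seed=9)
    assert [p.syllable for p in t1.productions] == [p.syllable for p in t2.productions]


def test_pure_segment_chain_has_re_one(lex):
    """p_syllable=0, p_jump=0, no errors: every move is a single-slot
    mutation of the previous item, so RE is exactly 1."""
    params = StrategyParams(p_syllable=0.0, p_jump=0.0,
                            error_nonword_rate=0.0, error_repetition_rate=0.0)
    for seed in range(5):
        trial = generate_trial(sorted(lex.words)[seed], params, lex, seed=seed)
        assert score_RE(trial) == 1.0


def test_pure_syllable_strategy_yields_high_sn(lex):
    params = StrategyParams(p_syllable=1.0, p_jump=0.0,
                            error_nonword_rate=0.0, error_repetition_rate=0.0)
    sns = [
        score_SN(generate_trial(sorted(lex.words)[s], params, lex, seed=s))
        for s in range(10)
    ]
    assert np.mean(sns) > 0.5


def test_probabilities_validated():
    with pytest.raises(ValueError, match="p_jump"):
        StrategyParams(p_jump=1.5)


def test_mean_sn_increases_with_p_syllable(lex):
    """Parameter recovery at small n: mean SN is monotone in p_syllable."""
    stimuli = sorted(lex.words)[:5]
    means = []
    for i, p in enumerate((0.1, 0.5, 0.9)):
        params = StrategyParams(p_syllable=p)
        sns = [
            score_SN(generate_trial(stimuli[s % 5], params, lex, seed=1000 * i + s))
            for s in range(40)
        ]
        means.append(np.nanmean(sns))
    assert means[0] < means[1] < means[2]


def test_cohort_deterministic_and_ground_truth_complete():
    a = generate_cohort(n_participants=6, seed=21)
    b = generate_cohort(n_participants=6, seed=21)
    assert a.response_table().equals(b.response_table())
    assert a.ground_truth().equals(b.ground_truth())
    gt = a.ground_truth()
    assert set(gt.columns) >= {
        "participant_id", "english", "num_chinese", "multilingual",
        "p_syllable", "p_jump", "error_nonword_rate", "error_repetition_rate",
    }
    assert gt["english"].between(5, 8).all()
    assert gt["num_chinese"].between(1, 3).all()
    assert len(a.stimuli) == 6
    assert len(a.trials) == 6 * 6  # six trials per participant


def test_zero_effects_give_identical_link_means():
    """With all covariate effects and participant noise at zero, every
    participant gets the same strategy parameters."""
    effects = CohortEffects(
        english_on_p_syllable=0, english_on_nonword_rate=0,
        num_chinese_on_p_jump=0, num_chinese_on_p_syllable=0,
        multilingual_on_error=0, participant_sd=0,
    )
    cohort = generate_cohort(n_participants=8, effects=effects, seed=3)
    gt = cohort.ground_truth()
    for col in ("p_syllable", "p_jump", "error_nonword_rate", "error_repetition_rate"):
        assert gt[col].nunique() == 1


def test_covariate_effect_directions_monte_carlo():
    """Configured signs surface in the generated data: higher English ->
    fewer errors; higher Num_Chinese -> more jumping (lower RE)."""
    cohort = generate_cohort(n_participants=60, seed=17)
    gt = cohort.ground_truth().set_index("participant_id")
    rows = []
    for trial in cohort.trials:
        t = classify_productions(trial, cohort.lexicon.words)
        s = score_trial(t)
        rows.append((trial.participant_id, s.Error, s.RE))
    import pandas as pd

    df = pd.DataFrame(rows, columns=["participant_id", "Error", "RE"])
    df = df.join(gt[["english", "num_chinese"]], on="participant_id")
    err_by_english = df.groupby("english")["Error"].mean()
    assert err_by_english.loc[5] > err_by_english.loc[8]
    re_by_chinese = df.groupby("num_chinese")["RE"].mean()
    assert re_by_chinese.loc[1] > re_by_chinese.loc[3]
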