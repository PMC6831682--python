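# phonofluency

Scoring and network analysis for **phonological verbal-fluency** tasks with
Mandarin monosyllables.

In a phonological fluency trial a participant hears a monosyllabic stimulus
(e.g. *wai4*) and produces, for one minute, as many phonological neighbors
as they can — items differing by the addition, deletion or substitution of
a single segment or lexical tone. The stream of productions carries rich
information about how the speaker searches their mental lexicon: whether
they *segment* the syllable and manipulate onsets, glides, nuclei, codas
and tones one slot at a time, or retrieve whole atonal syllables and run
through their tone families. `phonofluency` turns transcribed streams into
quantitative per-trial measures and participant-level phonological
networks, and ships a generative simulator of both search styles so the
entire pipeline can be exercised and validated without any participant
data.

## Measures

Each syllable is represented in the five-slot schema **C_G_V_X_T** (onset,
glide, nucleus, coda, tone); its *unit count* U is the number of filled
segmental slots plus one for tone (2–5). Edit distance *e* between two
syllables is the number of differing slots — a Hamming distance with empty
slots as symbols, hence a true metric.

- **WE (weighted edit)** — graded fluency. Each correct response earns
  `max(0, (U − e)/(U − 1))` with U the larger unit count of the pair, so a
  4-unit stimulus scores its responses 1, 0.75, 0.50, 0.25, 0 as *e* runs
  1–5, and a 3-unit stimulus 1, 0.50, 0. WE is the per-trial sum.
- **RE (running edit)** — mean of the same weight over consecutive
  production pairs, errors included. RE = 1 means every production was an
  immediate neighbor of the one before; low RE means frequent mental jumps.
- **SN** — proportion of consecutive pairs that are *syllable neighbors*
  (identical atonal base, e.g. *zai4 → zai1*). SN > 0.5 marks a trial as
  predominantly syllable-driven.
- **Error** — nonword productions plus within-trial repetitions.
- **Network measures** — the unique correct productions form an undirected
  graph with edges at edit distance 1. The package reports the number of
  components **NC**, and *component-weighted* mean clustering coefficient
  **CC̄** and degree assortativity (mixing by degree) **M**: each
  component's statistic is weighted by its node count and isolates (or
  components on which the statistic is undefined) contribute zero, so a
  fully clustered 9-node component plus one isolate scores CC̄ = 0.9.
  Hop distances from the stimulus are computed on the stimulus-augmented
  graph.

## Worked example

```python
import pandas as pd
from phonofluency import FluencyScorer

responses = pd.DataFrame({
    "participant_id": ["P01"] * 6,
    "trial_id": ["T1"] * 6,
    "stimulus": ["wai4"] * 6,
    "response_index": range(6),
    "response_pinyin": ["shuai4", "shuan4", "zai4", "zai1", "zai2", "zai4"],
})
scores = FluencyScorer().fit().transform(responses)
print(scores[["WE", "RE", "SN", "Error", "NC", "CC", "M"]].round(3))
```

prints

```
     WE   RE   SN  Error  NC   CC    M
0  2.75  0.9  0.6      2   2  0.0  0.0
```

Reading it: *zai2* is a nonword and the second *zai4* a repetition (Error
= 2). The four correct responses earn 1 (*shuai4*, edit 1), 0.75
(*shuan4*, edit 2 on the 5-unit schedule), 2/3 (*zai4*, edit 2 on the
4-unit schedule) and 1/3 (*zai1*, edit 3), so WE = 2.75. Four of the five
consecutive pairs are immediate neighbors and the fifth has weight 0.5,
giving RE = 0.9; three pairs stay within the *zai* tone family (SN = 0.6).
The network has two 2-node components (*shuai4–shuan4*, *zai4–zai1*), so
NC = 2 and the degree-1 nodes leave CC̄ at 0, with M = 0 because both
components have zero degree variance.

The estimators compose with scikit-learn pipelines:

```python
from sklearn.pipeline import Pipeline
from phonofluency import FluencyScorer, ParticipantErrorFilter, TrialOutlierFilter

pipe = Pipeline([
    ("score", FluencyScorer()),
    ("participants", ParticipantErrorFilter()),   # error totals > mean + 2.5 SD
    ("trials", TrialOutlierFilter()),             # WE/SN above, RE below, M boxplot
])
clean = pipe.fit_transform(responses)
```

There is also a CLI:

```bash
phonofluency simulate --seed 7 --out sim/
phonofluency score --responses sim/responses.tsv \
    --mapping sim/mapping.tsv --lexicon sim/lexicon.txt --out scored/
phonofluency report --scores scored/scores.csv \
    --ground-truth sim/ground_truth.csv --out report/
```

`simulate` generates a synthetic cohort (95 participants x 6 stimuli by
default) with known ground-truth strategy parameters and covariates;
`score` produces the per-trial table plus a QC report of exclusions;
`report` writes descriptives, the correlation table of the seven dependent
variables, the response-type and hop breakdowns, the SN > 0.5 strategy
split, and an analysis-ready table for external regression modeling.

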