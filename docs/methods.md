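# Methods

## Syllable representation

All measures operate on the five-slot schema C_G_V_X_T: onset consonant,
prevocalic glide, nucleus vowel, coda, lexical tone. The nucleus is
obligatory; the unit count U (filled segmental slots + 1 for tone) ranges
from 2 (bare tonal vowel, *wu2*) to 5 (*shuai4*). Romanization is
deliberately **not** segmented by rule: orthographic *w*/*y* are ambiguous
(*wu2* is a bare vowel /u/, *ye1* a glide–vowel /iɛ/), so parsing goes
through a mapping table from atonal pinyin to slot assignments, the same
division of labor used by lexical databases of Mandarin neighborhood
statistics. The packaged table covers only the syllables used in the
documentation and tests; users supply a full table for real transcripts.
Neutral tone is representable (category 5) but absent from the fixtures.

## Edit distance and the weight schedule

Distance is slot-wise Hamming distance over (C, G, V, X, T) with "empty"
as a comparable symbol, so additions, deletions, substitutions and tone
changes are all single edits. This is a deliberate choice over sequence
alignment: the published weighting schedules are defined per slot (e.g.
*wai4 → shuan4* = 2: onset added, coda substituted), and slot-wise
comparison makes the distance a true metric (property-tested).

The graded weight is `w = min(1, max(0, (U − e)/(U − 1)))` with U the unit
count of the longer item of the pair. This single formula reproduces both
printed schedules (U = 5: 1, 0.75, 0.50, 0.25, 0; U = 3: 1, 0.50, 0) and
is the unique linear interpolation of them; edits at or beyond U are
impossible combinations and score 0, and identical items (e = 0, only
possible for repetitions inside RE) cap at 1.

## Trial scoring

Classification is deterministic given lexicon and order: a repetition is
an exact tonal-syllable match to any earlier production in the same trial
(tone variants are distinct legitimate responses, so repetition is tonal,
not atonal); a first-occurrence non-lexicon item is a nonword; the rest
are correct. A repeated nonword counts once as a nonword and subsequently
as a repetition, so categories partition the stream and
Error = nonwords + repetitions. A production identical to the stimulus is
treated as an ordinary response on first occurrence (the stimulus itself
is not a production).

WE sums stimulus–response weights over correct productions only; RE and SN
are means over consecutive pairs of **all** productions, errors included
(exact repetitions share their own atonal base and therefore count toward
SN). RE and SN are undefined below two productions and reported as
missing, not zero, so the exclusion screens are not distorted by
degenerate trials. Weight-0 correct responses still count as correct and
appear as network nodes.

## Networks

Nodes are the unique correct productions; edges connect pairs at edit
distance 1. The stimulus is excluded from the structural measures by
default (the graphs are built from correct lexical items) and included
only when hop distances are computed on the stimulus-augmented graph; an
`include_stimulus` switch provides the alternative convention.

Because these small graphs are routinely fragmented — fragmentation *is*
the behaviour of interest — the usual giant-component convention is
replaced by component weighting: per-component statistics averaged with
weights proportional to component size, isolates contributing zero.

- Local clustering is triangles over possible neighbor pairs, with
  degree < 2 nodes set to 0 rather than excluded; this makes the
  component-weighted mean well defined and equal to the plain mean of
  local clustering over all nodes (both routes are tested).
- Per-component assortativity is the Pearson correlation of endpoint
  degrees over edges, each edge taken in both orientations so the value is
  orientation-independent. Components with zero degree variance (single
  edges, regular cycles) have an undefined correlation and contribute 0,
  symmetrically with isolates.
- Unreachable response nodes are binned as "disconnected" in the hop
  histogram (exported GraphML marks them hop = −1).

Implementation equivalences are guarded by brute-force oracles (union-find
components, neighbor-pair triangle counting, endpoint-degree correlation)
over the complete ≤ 7-node graph atlas — exhaustive up to isomorphism,
which suffices because all three statistics are isomorphism invariants —
plus random 8- and 12-node graphs, and against networkx's assortativity on
connected graphs where it is defined.

## Outlier screens

Participant level: excluded if the total nonword count **or** total
repetition count exceeds mean + 2.5 sample SD of that count's cohort
distribution; with fewer than 3 participants the SD is meaningless and
nothing is excluded (warned). Trial level, per variable: WE and SN
above-only at 2.5 SD, RE below-only, M by Tukey fences (quartile ± 1.5
IQR; the fence coefficient is configurable since conventions differ). All
thresholds are computed once on the pre-exclusion table — a single pass,
so filtering is idempotent. A covariate-sparsity filter drops participants
alone (below a configurable minimum, default 2) in a covariate level.

## Synthetic cohorts

The generator emulates the two search styles the measures are designed to
separate. A trial is a random walk over the toy inventory: with
probability `p_syllable` a move enumerates the remaining tone variants of
the current atonal base in ascending order (nonwords included — tone
families are enumerated blindly, which is exactly why syllable-driven
search produces more errors); with probability `p_jump` it jumps to a
random word (re-anchoring within edit 2 of the stimulus with probability
`jump_home`, reflecting that the task instructs production of stimulus
neighbors); otherwise it mutates a single slot of the previous item. Tone
substitution inside a segment-driven move is given its own low weight
(`p_tone_mutation` = 0.1): it creates a syllable neighbor — the signature
of the *other* strategy — and observed segment-driven searchers manipulate
onsets and rimes predominantly, keeping their SN below ~0.2. Repetition
errors re-emit an earlier item at `error_repetition_rate`;
`error_nonword_rate` is the chance a mutation tolerates a nonword outcome.
A search dead-end truncates the trial with a log entry, which also
guarantees that the pure segment regime (`p_syllable = p_jump = 0`, error
rates 0) emits chains whose RE is exactly 1.

Defaults were fixed once to sit on the scale of the study conditions:
trial length negative-binomial (mean 14 productions, dispersion 12,
bounded 2–30, giving a correct-response mean near 12 and maxima in the
low 20s), base move mixture `p_syllable` 0.18 / `p_jump` 0.10 (roughly a
third of trials end up above the SN > 0.5 split), error rates 0.15/0.06
(Error ≈ 2 per trial, reaching double digits in the tail). Covariates
follow the published marginals (English levels 5–8, mean 6.74, SD 0.94;
1–3 Chinese languages/dialects, mean 1.92, SD 0.66; ~half multilingual)
and shift the parameters through logit-linear links whose default signs
follow the reported directions: higher English lowers `p_syllable` and
the nonword rate; more Chinese languages raise `p_jump` (hence lower RE
and more components) and slightly lower `p_syllable`; multilingual status
lowers the error rates. Only directions are emulated — the links' functional
form and magnitudes are package choices, since no generative model of the
real behaviour exists.

What the generator does **not** emulate: response timing, frequency and
neighborhood-density effects on retrieval order, homophone/orthographic
(radical) knowledge, fatigue within the minute, and the real Mandarin
inventory (the toy inventory has disjoint slot alphabets so romanization
is trivially invertible). Passing recovery tests therefore show that the
measures separate the two search regimes *as modeled* and that the
pipeline is numerically correct; they are not evidence about real
speakers.

## Numerical and design notes

- Correlations are product–moment by default (rank correlation available);
  pairwise-complete over missing RE/SN; zero-variance variables report
  missing correlations. Trial-level and participant-averaged modes are
  both provided.
- The strategy split uses strict inequality (SN > 0.50).
- The multivariate regression stage (multiple dependent variables with
  tweedie-family variance functions) is intentionally not reimplemented:
  the package exports a documented analysis-ready table
  (`export_model_table`) for external statistical software.
- Problem sizes in the validation suite — 100 trials per mixture level
  across nine levels for strategy recovery, a 95 × 6 default cohort for
  the correlation-sign checks, the ≤ 7-node atlas plus 300 + 500 random
  graphs for the oracle sweeps — were chosen as the smallest scales at
  which the Monte-Carlo properties are stable.
- Determinism: every stochastic component takes a seed or a numpy
  Generator; a fixed seed makes `simulate → score → report` byte-identical
  across runs.

## Known limitations

- The slot-wise metric cannot express resyllabification or cross-slot
  segment identity (e.g. a glide moving between G and V readings is two
  edits); it follows the segmentation table's slot assignments.
- With user-supplied mapping tables whose slot tuples are not unique,
  rendering falls back to the stored label; round-tripping is only
  guaranteed for injective tables (the packaged fixtures are).
- The participant screen treats nonword and repetition totals as
  independent criteria; participants extreme in a combination but not in
  either margin are retained.
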