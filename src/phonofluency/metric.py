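"""Slot-wise phonological edit distance and the graded fluency weighting.

Two monosyllables are at edit distance *e* if they differ in *e* of the five
slots C, G, V, X, T, where an empty slot compares against a filled one (so a
single addition or deletion of a segment is one edit, as is a substitution
or a tone change).  This is a Hamming distance over five symbols -- a true
metric -- and deliberately not a sequence-alignment distance: the weighting
schedules below are defined on slot counts.

The graded weight of a pair is the proportion of edit steps still possible
before the two items share no similarity:

    w(a, b) = max(0, (U - e) / (U - 1)),   U = max(units(a), units(b))

which reproduces the published schedules exactly -- for U = 5 the weights
run 1, 0.75, 0.50, 0.25, 0 with increasing e, and for U = 3 they run
1, 0.50, 0 (edits beyond U are impossible combinations and score 0).
"""

from __future__ import annotations

from .syllables import SegmentedSyllable, atonal_key

__all__ = [
    "edit_distance",
    "edit_weight",
    "is_immediate_neighbor",
    "is_syllable_neighbor",
]


def edit_distance(a: SegmentedSyllable, b: SegmentedSyllable) -> int:
    """Number of differing slots among {C, G, V, X, T}; 0..5."""
    return sum(x != y for x, y in zip(a.slots, b.slots))


def edit_weight(a: SegmentedSyllable, b: SegmentedSyllable) -> float:
    """Graded similarity in [0, 1]; 1 for identity, 0 once e >= U.

    The formula caps at both ends: identical items (e = 0) sit at the top
    of the scale, pairs at or beyond full dissimilarity at the bottom.
    """
    u = max(a.unit_count, b.unit_count)
    e = edit_distance(a, b)
    return min(1.0, max(0.0, (u - e) / (u - 1)))


def is_immediate_neighbor(a: SegmentedSyllable, b: SegmentedSyllable) -> bool:
    """True iff the pair is a phonological neighbor pair (edit distance 1)."""
    return edit_distance(a, b) == 1


def is_syllable_neighbor(a: SegmentedSyllable, b: SegmentedSyllable) -> bool:
    """True iff the two items share the same atonal syllable base."""
    return atonal_key(a) == atonal_key(b)
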