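"""Five-slot (C_G_V_X_T) representation of Mandarin monosyllables.

Every measure in this package is defined over a fully segmented tonal
syllable: an optional onset consonant (C), an optional prevocalic glide (G),
an obligatory nucleus vowel (V), an optional coda (X, a glide or nasal), and
a lexical tone (T, categories 1-4 plus 5 for the neutral tone).  The number
of *units* of a syllable is the number of filled segmental slots plus one
for tone, so it ranges from 2 (a bare tonal vowel such as wu2) to 5 (e.g.
shuai4).

Romanized (pinyin) strings are not segmented by rule -- orthographic ``w``
and ``y`` are ambiguous between a glide and a bare vowel -- but through a
mapping table from atonal pinyin to slot assignments, mirroring how lexical
databases of Mandarin neighborhood statistics segment the inventory.  A
small table covering the syllables used in the bundled examples ships with
the package; users supply their own table for full coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Tuple

__all__ = [
    "SegmentedSyllable",
    "SyllableMapping",
    "parse_pinyin",
    "unit_count",
    "atonal_key",
    "load_default_mapping",
    "load_default_lexicon",
]

#: Valid tone categories; 5 denotes the neutral tone.
TONES = (1, 2, 3, 4, 5)

Slots = Tuple[Optional[str], Optional[str], str, Optional[str]]


@dataclass(frozen=True)
class SegmentedSyllable:
    """One tonal syllable as five slots.

    Two syllables compare equal iff all five slots are equal; the original
    romanized string (``label``) is carried along for display only and is
    excluded from equality and hashing.
    """

    onset: Optional[str]
    glide: Optional[str]
    nucleus: str
    coda: Optional[str]
    tone: int
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.nucleus:
            raise ValueError(f"syllable {self.label!r} has an empty nucleus slot")
        if self.tone not in TONES:
            raise ValueError(f"invalid tone category {self.tone!r} in {self.label!r}")

    @property
    def slots(self) -> Tuple[Optional[str], Optional[str], str, Optional[str], int]:
        """The five compared slots (C, G, V, X, T), ``None`` for empty."""
        return (self.onset, self.glide, self.nucleus, self.coda, self.tone)

    @property
    def unit_count(self) -> int:
        """Filled segmental slots + 1 (tone); always in 2..5."""
        return sum(s is not None for s in (self.onset, self.glide, self.coda)) + 2

    @property
    def atonal(self) -> Slots:
        """Tone-independent identity: the (C, G, V, X) tuple."""
        return (self.onset, self.glide, self.nucleus, self.coda)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label or "".join(s or "" for s in self.atonal) + str(self.tone)


class PinyinLookupError(KeyError):
    """An atonal syllable is not present in the mapping table."""


class PinyinFormatError(ValueError):
    """A romanized string lacks a valid trailing tone digit."""


class SyllableMapping:
    """Atonal pinyin -> (C, G, V, X) slot assignment table.

    The on-disk format is two tab-separated columns: the atonal pinyin
    string and the slot assignment ``C|G|V|X`` with ``-`` marking an empty
    slot.  Lines starting with ``#`` are comments.
    """

    def __init__(self, entries: Mapping[str, Slots], provenance_note: str = "") -> None:
        self.entries: dict[str, Slots] = dict(entries)
        self.provenance_note = provenance_note
        # Reverse index for rendering; only well-defined if injective.
        self._reverse: dict[Slots, str] = {}
        for key, slots in self.entries.items():
            self._reverse.setdefault(slots, key)

    def __contains__(self, atonal: str) -> bool:
        return atonal in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def parse(self, s: str) -> SegmentedSyllable:
        """Parse a tonal pinyin string (e.g. ``wai4``) into slots."""
        s = s.strip()
        if not s or not s[-1].isdigit():
            raise PinyinFormatError(f"{s!r} does not end in a tone digit")
        tone = int(s[-1])
        if tone not in TONES:
            raise PinyinFormatError(f"{s!r} has invalid tone digit {tone}")
        atonal = s[:-1]
        if atonal not in self.entries:
            raise PinyinLookupError(f"unknown atonal syllable {atonal!r} (from {s!r})")
        c, g, v, x = self.entries[atonal]
        return SegmentedSyllable(c, g, v, x, tone, label=s)

    def render(self, syl: SegmentedSyllable) -> str:
        """Inverse of :meth:`parse`: slots back to a tonal pinyin string."""
        atonal = self._reverse.get(syl.atonal)
        if atonal is None:
            if syl.label:
                return syl.label
            raise PinyinLookupError(f"no mapping entry renders slots {syl.atonal!r}")
        return f"{atonal}{syl.tone}"

    @classmethod
    def from_tsv(cls, path: str | Path, provenance_note: str = "") -> "SyllableMapping":
        entries: dict[str, Slots] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                atonal, spec = line.split("\t")
                c, g, v, x = spec.split("|")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed mapping line {line!r}") from exc
            entries[atonal] = tuple(None if t == "-" else t for t in (c, g, v, x))  # type: ignore[assignment]
        return cls(entries, provenance_note or f"loaded from {path}")

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            "\t".join([atonal, "|".join(t if t is not None else "-" for t in slots)])
            for atonal, slots in sorted(self.entries.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def parse_pinyin(s: str, mapping: SyllableMapping) -> SegmentedSyllable:
    """Parse a romanized tonal syllable via a mapping table."""
    return mapping.parse(s)


def unit_count(syl: SegmentedSyllable) -> int:
    """Number of phonological units (filled segmental slots + tone)."""
    return syl.unit_count


def atonal_key(syl: SegmentedSyllable) -> Slots:
    """Tone-stripped identity; equal for any two tones of one base syllable."""
    return syl.atonal


def load_default_mapping() -> SyllableMapping:
    """The packaged mapping fixture (syllables used in docs, tests, examples)."""
    ref = resources.files("phonofluency").joinpath("data/mapping.tsv")
    with resources.as_file(ref) as path:
        return SyllableMapping.from_tsv(path, provenance_note="packaged fixture")


def load_lexicon(path: str | Path) -> set[str]:
    """Read a word list: one tonal pinyin entry per line, ``#`` comments."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return words


def load_default_lexicon() -> set[str]:
    """The packaged toy word list (tonal pinyin strings)."""
    ref = resources.files("phonofluency").joinpath("data/toy_lexicon.txt")
    with resources.as_file(ref) as path:
        return load_lexicon(path)
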