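"""BIO label semantics, entity-span decoding, counting, and CoNLL-format I/O.

The unit of supervision throughout the package is the *entity mention*: a
maximal contiguous run of tokens tagged with one entity class.  Tags follow
the IOB2 convention (``B-c`` begins a mention of class ``c``, ``I-c``
continues it, ``O`` marks non-entity tokens).  Decoding is *lenient* by
default: an ``I-c`` token without a valid predecessor opens a new mention,
mirroring the behaviour of standard sequence-labeling evaluation tools.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, NamedTuple, Sequence, Union


class InvalidTagError(ValueError):
    """A tag is unknown to the scheme, or violates strict IOB2 rules."""


class ConllParseError(ValueError):
    """A CoNLL-format line could not be parsed."""


@dataclass(frozen=True)
class LabelScheme:
    """The tag inventory for a tagging task.

    ``tags`` holds exactly one ``O`` plus ``B-c``/``I-c`` per entity class,
    in the canonical order ``O, B-c1, I-c1, B-c2, I-c2, ...`` following the
    class order.  ``tag_index`` is the induced bijection onto ``1..|A|``
    (``O`` maps to 1); the positive-integer encoding matters because one of
    the reward functions compares label sequences as integer vectors.
    """

    classes: tuple[str, ...]
    tags: tuple[str, ...] = field(init=False)
    tag_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate entity class names")
        if "O" in self.classes:
            raise ValueError("'O' is not an entity class")
        tags = ["O"]
        for cls in self.classes:
            tags.extend((f"B-{cls}", f"I-{cls}"))
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "tags", tuple(tags))
        object.__setattr__(
            self, "tag_index", {tag: i + 1 for i, tag in enumerate(tags)}
        )

    @property
    def n_actions(self) -> int:
        """Size of the action set ``|A|`` = ``2 * n_classes + 1``."""
        return len(self.tags)

    def class_of(self, tag: str) -> str | None:
        """Entity class of a tag, or ``None`` for ``O``."""
        self._check(tag, position=None)
        return None if tag == "O" else tag[2:]

    def _check(self, tag: str, position: int | None) -> None:
        if tag not in self.tag_index:
            where = "" if position is None else f" at position {position}"
            raise InvalidTagError(f"unknown tag {tag!r}{where}")


#: 4-class newswire-style scheme (order matches the count-vector convention
#: PER, LOC, ORG, MISC used in the worked reward examples).
CONLL_SCHEME = LabelScheme(("PER", "LOC", "ORG", "MISC"))

#: 2-class biomedical scheme: chemical and disease mentions.
BC5CDR_SCHEME = LabelScheme(("CHEM", "DISE"))


@dataclass(frozen=True)
class TaggedSequence:
    """One token sequence with gold tags — a single episode."""

    tokens: tuple[str, ...]
    gold: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "gold", tuple(self.gold))
        if len(self.tokens) != len(self.gold):
            raise ValueError(
                f"tokens/gold length mismatch: {len(self.tokens)} vs {len(self.gold)}"
            )

    def __len__(self) -> int:
        return len(self.tokens)


class EntitySpan(NamedTuple):
    """A decoded entity mention as a 0-based half-open token interval."""

    cls: str
    start: int
    end: int


@dataclass(frozen=True)
class CountVector:
    """Per-class entity counts, optionally with the O-interval count.

    ``per_class`` is aligned to the scheme's class order; ``o_intervals``
    (the number of maximal runs of ``O``) is present only when a +O count
    variant asked for it.
    """

    per_class: tuple[int, ...]
    o_intervals: int | None = None

    def as_list(self) -> list[int]:
        out = list(self.per_class)
        if self.o_intervals is not None:
            out.append(self.o_intervals)
        return out


def decode_entities(
    labels: Sequence[str], scheme: LabelScheme, strict: bool = False
) -> list[EntitySpan]:
    """Extract entity spans from a tag sequence.

    Lenient mode (default): ``B-c`` always opens a span; ``I-c`` continues a
    running span of class ``c`` and otherwise opens a new one.  A lone
    ``I-PER`` therefore decodes to the same span as ``B-PER`` — standard
    evaluation tooling treats the two identically, which is exactly why
    single-token F1 cannot separate them.  Strict mode raises on an ``I-c``
    with no valid predecessor.
    """
    spans: list[EntitySpan] = []
    cur_cls: str | None = None
    cur_start = 0
    for i, tag in enumerate(labels):
        scheme._check(tag, i)
        if tag == "O":
            if cur_cls is not None:
                spans.append(EntitySpan(cur_cls, cur_start, i))
                cur_cls = None
            continue
        prefix, cls = tag[0], tag[2:]
        if prefix == "B" or cls != cur_cls:
            if prefix == "I" and strict:
                raise InvalidTagError(
                    f"strict IOB2 violation: {tag!r} at position {i} "
                    "does not continue an open entity"
                )
            if cur_cls is not None:
                spans.append(EntitySpan(cur_cls, cur_start, i))
            cur_cls, cur_start = cls, i
    if cur_cls is not None:
        spans.append(EntitySpan(cur_cls, cur_start, len(labels)))
    return spans


def validate_iob2(labels: Sequence[str], scheme: LabelScheme) -> None:
    """Raise :class:`InvalidTagError` unless ``labels`` is well-formed IOB2."""
    decode_entities(labels, scheme, strict=True)


def count_o_intervals(labels: Sequence[str], scheme: LabelScheme | None = None) -> int:
    """Number of maximal runs of consecutive ``O`` tokens."""
    runs = 0
    prev_o = False
    for i, tag in enumerate(labels):
        if scheme is not None:
            scheme._check(tag, i)
        is_o = tag == "O"
        if is_o and not prev_o:
            runs += 1
        prev_o = is_o
    return runs


def count_entities(
    labels: Sequence[str], scheme: LabelScheme, include_o: bool = False
) -> CountVector:
    """Per-class mention counts (the aggregate label for a segment)."""
    spans = decode_entities(labels, scheme)
    counts = dict.fromkeys(scheme.classes, 0)
    for span in spans:
        counts[span.cls] += 1
    o_runs = count_o_intervals(labels) if include_o else None
    return CountVector(tuple(counts[c] for c in scheme.classes), o_runs)


def encode_labels(labels: Sequence[str], scheme: LabelScheme) -> list[int]:
    """Map tags to their canonical positive-integer codes in ``1..|A|``."""
    out = []
    for i, tag in enumerate(labels):
        scheme._check(tag, i)
        out.append(scheme.tag_index[tag])
    return out


def decode_label_indices(indices: Sequence[int], scheme: LabelScheme) -> list[str]:
    """Inverse of :func:`encode_labels`."""
    out = []
    for i, idx in enumerate(indices):
        if not 1 <= idx <= scheme.n_actions:
            raise InvalidTagError(f"label code {idx} at position {i} out of range")
        out.append(scheme.tags[idx - 1])
    return out


_PathLike = Union[str, os.PathLike]


def read_conll(source: _PathLike | IO[str] | Iterable[str]) -> list[TaggedSequence]:
    """Read a token-per-line corpus: ``token<whitespace>tag``, blank line
    between sentences, ``-DOCSTART-`` records skipped.  Only the first and
    last columns are used, so 4-column CoNLL-2003 files load unchanged.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, encoding="utf-8") as handle:
            return read_conll(handle)
    sequences: list[TaggedSequence] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if tokens:
            sequences.append(TaggedSequence(tuple(tokens), tuple(tags)))
            tokens.clear()
            tags.clear()

    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            flush()
            continue
        fields = line.split()
        if fields[0] == "-DOCSTART-":
            continue
        if len(fields) < 2:
            raise ConllParseError(
                f"line {lineno}: expected 'token tag', got {line!r}"
            )
        tokens.append(fields[0])
        tags.append(fields[-1])
    flush()
    return sequences


def write_conll(
    sequences: Iterable[TaggedSequence], target: _PathLike | IO[str] | None = None
) -> str | None:
    """Write sequences in two-column CoNLL format.

    With ``target=None`` the formatted text is returned as a string.
    """
    if target is None:
        buffer = io.StringIO()
        write_conll(sequences, buffer)
        return buffer.getvalue()
    if isinstance(target, (str, os.PathLike)):
        with open(target, "w", encoding="utf-8") as handle:
            write_conll(sequences, handle)
        return None
    for seq in sequences:
        for token, tag in zip(seq.tokens, seq.gold):
            target.write(f"{token} {tag}\n")
        target.write("\n")
    return None
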