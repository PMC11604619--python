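"""Reward schemes: partitioning an episode into aggregation segments.

A reward scheme slices a gold label sequence (or a concatenation of several
sequences) into contiguous segments; each segment later receives exactly one
aggregated reward.  Coarser schemes delay and aggregate the feedback more:

* ``by_action`` — one segment per token (dense per-prediction feedback);
* ``by_region`` — one segment per maximal homogeneous region, i.e. each
  entity mention and each maximal O-run is its own segment;
* ``by_entity`` — one segment per entity, each merged with the non-entity
  run preceding it (plus one trailing entity-free segment if any);
* ``k_grouped`` — one segment per group of ``k`` whole sequences
  (``k=1`` is sequence-level feedback).

Partitions are always computed from the *gold* labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .labels import LabelScheme, TaggedSequence, decode_entities

SCHEME_NAMES = ("by_action", "by_region", "by_entity", "k_grouped")


@dataclass(frozen=True)
class Partition:
    """Ordered, non-overlapping segments covering ``[0, n)`` exactly."""

    segments: tuple[tuple[int, int], ...]
    scheme_name: str
    k: int = 1

    def __post_init__(self) -> None:
        if self.scheme_name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.scheme_name!r}")
        pos = 0
        for start, end in self.segments:
            if start != pos or end <= start:
                raise ValueError(
                    f"segments must be contiguous non-empty intervals; got {self.segments}"
                )
            pos = end

    @property
    def n(self) -> int:
        return self.segments[-1][1] if self.segments else 0

    def boundaries(self) -> set[int]:
        """Interior cut points (excludes 0 and n)."""
        return {start for start, _ in self.segments[1:]}

    def to_json(self) -> dict:
        return {
            "scheme": self.scheme_name,
            "k": self.k,
            "segments": [list(seg) for seg in self.segments],
        }


@dataclass(frozen=True)
class GroupedEpisode:
    """``k`` whole sequences concatenated into one episode."""

    members: tuple[TaggedSequence, ...]
    offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        offsets = []
        pos = 0
        for member in self.members:
            offsets.append(pos)
            pos += len(member)
        object.__setattr__(self, "offsets", tuple(offsets))

    @property
    def total_length(self) -> int:
        return self.offsets[-1] + len(self.members[-1]) if self.members else 0

    @property
    def gold(self) -> tuple[str, ...]:
        return tuple(tag for member in self.members for tag in member.gold)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(tok for member in self.members for tok in member.tokens)


def by_action(labels: Sequence[str]) -> Partition:
    """One singleton segment per position."""
    return Partition(tuple((i, i + 1) for i in range(len(labels))), "by_action")


def by_region(labels: Sequence[str], scheme: LabelScheme) -> Partition:
    """Segments at every entity span and every maximal O-run.

    Adjacent same-class entities (``B-X B-X``) stay separate segments, so a
    segment never contains more than one mention.
    """
    n = len(labels)
    if n == 0:
        return Partition((), "by_region")
    cuts = {0, n}
    for span in decode_entities(labels, scheme):
        cuts.add(span.start)
        cuts.add(span.end)
    points = sorted(cuts)
    segments = tuple(zip(points[:-1], points[1:]))
    return Partition(segments, "by_region")


def by_entity(labels: Sequence[str], scheme: LabelScheme) -> Partition:
    """Cut after each entity: every segment holds at most one mention,
    merged with whatever non-entity run precedes it.  Entity-free labels
    form a single segment."""
    n = len(labels)
    if n == 0:
        return Partition((), "by_entity")
    cuts = {0, n}
    for span in decode_entities(labels, scheme):
        cuts.add(span.end)
    points = sorted(cuts)
    segments = tuple(zip(points[:-1], points[1:]))
    return Partition(segments, "by_entity")


def k_grouped(
    batch: Sequence[TaggedSequence], k: int
) -> list[tuple[GroupedEpisode, Partition]]:
    """Group ``k`` consecutive sequences into single-segment episodes.

    A trailing remainder (batch size not divisible by ``k``) forms a smaller
    final group rather than being discarded.
    """
    if not isinstance(k, int) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    out = []
    for i in range(0, len(batch), k):
        group = GroupedEpisode(tuple(batch[i : i + k]))
        total = group.total_length
        segments = ((0, total),) if total else ()
        out.append((group, Partition(segments, "k_grouped", k=k)))
    return out


def partition_labels(
    labels: Sequence[str], scheme_name: str, scheme: LabelScheme
) -> Partition:
    """Partition a single label sequence under a (non-grouped) scheme name.

    ``k_grouped`` here means ``k=1``: one segment over the whole sequence.
    """
    if scheme_name == "by_action":
        return by_action(labels)
    if scheme_name == "by_region":
        return by_region(labels, scheme)
    if scheme_name == "by_entity":
        return by_entity(labels, scheme)
    if scheme_name == "k_grouped":
        n = len(labels)
        return Partition(((0, n),) if n else (), "k_grouped", k=1)
    raise ValueError(f"unknown scheme {scheme_name!r}; valid: {SCHEME_NAMES}")
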