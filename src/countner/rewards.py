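"""Reward functions and the placement of aggregated rewards over an episode.

Two families of feedback are supported.  *Standard* functions (exact match,
token accuracy, entity F1, label cosine) read the token-level annotations of
a segment directly.  *Count-based* functions compare only the number of
entity mentions per class between gold and prediction — the aggregate-label
setting — via a magnitude-corrected cosine similarity

    sigma(A, B) = (A.B / (|A| |B|)) * (1 - | |A| - |B| | / (|A| + |B|))

whose correction factor ensures sigma(A, B) = 1 iff A = B on non-negative
vectors (plain cosine is blind to scale, so over-predicting every class by
the same factor would otherwise look perfect).

Count variants:

* ``counts``    — per-class entity counts only;
* ``counts_o``  — additionally appends the number of contiguous O-intervals
  to both vectors (non-entity structure);
* ``counts_p``  — *informed* counting: predicted per-class counts are capped
  at the gold counts (only true positives are enumerated), and every
  prediction of a class that does not occur in the gold segment at all
  receives a local 0-reward override at its position;
* ``counts_op`` — both of the above.

Within a segment ``[i, j)`` the aggregated reward is communicated at the
last position ``j-1``; earlier positions carry the EMPTY placeholder, which
is distinct from a numeric 0 (0 is a legal, informative reward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .labels import (
    LabelScheme,
    count_entities,
    count_o_intervals,
    decode_entities,
    encode_labels,
)
from .schemes import SCHEME_NAMES, Partition

REWARD_FUNCTIONS = (
    "exact_match",
    "accuracy",
    "f1",
    "cosine_labels",
    "counts",
    "counts_o",
    "counts_p",
    "counts_op",
)
COUNT_VARIANTS = ("counts", "counts_o", "counts_p", "counts_op")


class _EmptyReward:
    """Placeholder for positions where no reward signal is communicated."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "EMPTY"


EMPTY = _EmptyReward()


@dataclass(frozen=True)
class RewardTrace:
    """Per-position rewards: EMPTY or a float in [0, 1]."""

    values: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        for i, v in enumerate(self.values):
            if v is EMPTY:
                continue
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"reward {v!r} at position {i} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def numeric_positions(self) -> list[int]:
        return [i for i, v in enumerate(self.values) if v is not EMPTY]

    def numeric_values(self) -> list[float]:
        return [float(v) for v in self.values if v is not EMPTY]


@dataclass(frozen=True)
class RewardSpec:
    """Which reward function to use, under which aggregation scheme."""

    function: str
    scheme: str = "by_action"
    k: int = 1

    def __post_init__(self) -> None:
        if self.function not in REWARD_FUNCTIONS:
            raise ValueError(
                f"unknown reward function {self.function!r}; valid: {REWARD_FUNCTIONS}"
            )
        if self.scheme not in SCHEME_NAMES:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; valid: {SCHEME_NAMES}"
            )
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > 1 and self.scheme != "k_grouped":
            raise ValueError("k > 1 is only meaningful with the k_grouped scheme")


def _check_lengths(y_seg: Sequence[str], p_seg: Sequence[str]) -> None:
    if len(y_seg) != len(p_seg):
        raise ValueError(
            f"segment length mismatch: {len(y_seg)} vs {len(p_seg)}"
        )


def exact_match(y_seg: Sequence[str], p_seg: Sequence[str]) -> float:
    """1.0 iff the predicted segment equals the gold segment elementwise."""
    _check_lengths(y_seg, p_seg)
    return 1.0 if tuple(y_seg) == tuple(p_seg) else 0.0


def token_accuracy(y_seg: Sequence[str], p_seg: Sequence[str]) -> float:
    """Fraction of positions tagged correctly."""
    _check_lengths(y_seg, p_seg)
    if len(y_seg) == 0:
        raise ValueError("token accuracy is undefined on an empty segment")
    hits = sum(a == b for a, b in zip(y_seg, p_seg))
    return hits / len(y_seg)


def entity_f1(
    y_seg: Sequence[str], p_seg: Sequence[str], scheme: LabelScheme
) -> float:
    """Micro entity-level F1 between lenient decodings of the two segments.

    A predicted span counts as a true positive iff class, start and end all
    match a gold span.  When neither side contains any entity, the segment
    is a perfectly handled non-entity region and the reward is 1.
    """
    _check_lengths(y_seg, p_seg)
    gold = set(decode_entities(y_seg, scheme))
    pred = set(decode_entities(p_seg, scheme))
    if not gold and not pred:
        return 1.0
    tp = len(gold & pred)
    return 2.0 * tp / (len(gold) + len(pred))


def modified_cosine(a: Sequence[float], b: Sequence[float]) -> float:
    """Magnitude-corrected cosine similarity on non-negative vectors.

    Conventions for zero vectors: sigma(0, 0) = 1 (identical) and
    sigma(0, B != 0) = 0, extending the "perfect reward iff A = B" design
    goal to the degenerate case.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError(f"incompatible vector shapes {av.shape} and {bv.shape}")
    if (av < 0).any() or (bv < 0).any():
        raise ValueError("count vectors must be non-negative")
    if np.array_equal(av, bv):
        return 1.0  # exact by design: full reward iff A = B
    na = float(np.linalg.norm(av))
    nb = float(np.linalg.norm(bv))
    if na == 0.0 and nb == 0.0:
        return 1.0
    if na == 0.0 or nb == 0.0:
        return 0.0
    cos = float(av @ bv) / (na * nb)
    value = cos * (1.0 - abs(na - nb) / (na + nb))
    # guard against float drift just past the closed interval
    return min(1.0, max(0.0, value))


def cosine_labels(
    y_seg: Sequence[str], p_seg: Sequence[str], scheme: LabelScheme
) -> float:
    """Modified cosine over the canonical integer encodings of the tags."""
    _check_lengths(y_seg, p_seg)
    if len(y_seg) == 0:
        return 1.0
    return modified_cosine(encode_labels(y_seg, scheme), encode_labels(p_seg, scheme))


def _chunked(seg: Sequence[str], boundaries: Sequence[int]) -> list[Sequence[str]]:
    points = [0, *sorted(b for b in boundaries if 0 < b < len(seg)), len(seg)]
    return [seg[s:e] for s, e in zip(points[:-1], points[1:])]


def segment_count_vectors(
    seg: Sequence[str],
    scheme: LabelScheme,
    include_o: bool,
    boundaries: Sequence[int] = (),
) -> list[int]:
    """Count entities (and optionally O-intervals) over a segment.

    ``boundaries`` marks internal sequence joins inside a grouped episode:
    counting is done per chunk and summed, so neither entities nor O-runs
    merge across the join of two concatenated sequences.
    """
    per_class = np.zeros(len(scheme.classes), dtype=int)
    o_runs = 0
    for chunk in _chunked(seg, boundaries):
        cv = count_entities(chunk, scheme, include_o=False)
        per_class += np.array(cv.per_class, dtype=int)
        if include_o:
            o_runs += count_o_intervals(chunk)
    out = per_class.tolist()
    if include_o:
        out.append(o_runs)
    return out


def count_reward(
    y_seg: Sequence[str],
    p_seg: Sequence[str],
    variant: str,
    scheme: LabelScheme,
    boundaries: Sequence[int] = (),
) -> tuple[float, dict[int, float]]:
    """Aggregate count-based reward for one segment.

    Returns the global segment reward plus, for +P variants, a map of
    segment-relative positions to local 0-reward overrides (predictions of a
    class whose gold count in the segment is zero are *impossible* and are
    punished at their exact positions).
    """
    if variant not in COUNT_VARIANTS:
        raise ValueError(f"unknown count variant {variant!r}; valid: {COUNT_VARIANTS}")
    _check_lengths(y_seg, p_seg)
    include_o = variant in ("counts_o", "counts_op")
    informed = variant in ("counts_p", "counts_op")
    gold_vec = segment_count_vectors(y_seg, scheme, include_o, boundaries)
    pred_vec = segment_count_vectors(p_seg, scheme, include_o, boundaries)

    overrides: dict[int, float] = {}
    if informed:
        n_cls = len(scheme.classes)
        gold_by_class = dict(zip(scheme.classes, gold_vec[:n_cls]))
        # enumerate true positives only: cap predicted counts at gold counts
        # (O-interval entries are never capped)
        pred_vec = [
            min(p, g) for p, g in zip(pred_vec[:n_cls], gold_vec[:n_cls])
        ] + pred_vec[n_cls:]
        for t, tag in enumerate(p_seg):
            if tag != "O" and gold_by_class[tag[2:]] == 0:
                overrides[t] = 0.0
    return modified_cosine(gold_vec, pred_vec), overrides


def segment_reward(
    y_seg: Sequence[str],
    p_seg: Sequence[str],
    function: str,
    scheme: LabelScheme,
    boundaries: Sequence[int] = (),
) -> tuple[float, dict[int, float]]:
    """Dispatch a reward function on one segment; count variants may also
    return positional overrides."""
    if function == "exact_match":
        return exact_match(y_seg, p_seg), {}
    if function == "accuracy":
        return token_accuracy(y_seg, p_seg), {}
    if function == "f1":
        return entity_f1(y_seg, p_seg, scheme), {}
    if function == "cosine_labels":
        return cosine_labels(y_seg, p_seg, scheme), {}
    if function in COUNT_VARIANTS:
        return count_reward(y_seg, p_seg, function, scheme, boundaries)
    raise ValueError(
        f"unknown reward function {function!r}; valid: {REWARD_FUNCTIONS}"
    )


def assign_rewards(
    y: Sequence[str],
    y_hat: Sequence[str],
    partition: Partition,
    spec: RewardSpec,
    scheme: LabelScheme,
    member_offsets: Sequence[int] = (),
) -> RewardTrace:
    """Place one aggregated reward per segment (at its last position) and
    apply any +P positional overrides.

    ``member_offsets`` lists the start offsets of the member sequences of a
    grouped episode (offset 0 may be omitted); they are forwarded to the
    count functions so counting respects sequence joins.
    """
    n = len(y)
    if len(y_hat) != n:
        raise ValueError(f"gold/prediction length mismatch: {n} vs {len(y_hat)}")
    if partition.n != n or (n > 0 and not partition.segments):
        raise ValueError(
            f"partition covers [0, {partition.n}) but sequence has length {n}"
        )
    values: list = [EMPTY] * n
    for start, end in partition.segments:
        boundaries = [o - start for o in member_offsets if start < o < end]
        reward, overrides = segment_reward(
            y[start:end], y_hat[start:end], spec.function, scheme, boundaries
        )
        values[end - 1] = reward
        for t, v in overrides.items():
            values[start + t] = v
    return RewardTrace(tuple(values))
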