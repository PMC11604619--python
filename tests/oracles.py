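"""Independent brute-force reference implementations used as test oracles.

Deliberately written with different formulations than the package (boundary
scans, pure-python arithmetic, precision/recall composition) so agreement is
evidence, not tautology.
"""

from __future__ import annotations

import math
from typing import Sequence


def oracle_spans(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    """Lenient span extraction by boundary scan: a span starts wherever a
    non-O position is not a same-class I-continuation of its neighbour."""
    n = len(labels)
    cls = [None if t == "O" else t[2:] for t in labels]
    spans = []
    for i in range(n):
        if cls[i] is None:
            continue
        starts_here = (
            labels[i].startswith("B")
            or i == 0
            or cls[i - 1] != cls[i]
        )
        if not starts_here:
            continue
        end = i + 1
        while end < n and labels[end] == f"I-{cls[i]}":
            end += 1
        spans.append((cls[i], i, end))
    return spans


def oracle_counts(
    labels: Sequence[str], classes: Sequence[str], include_o: bool = False
) -> list[int]:
    """Entity counts per class (and O-runs) from the boundary-scan spans."""
    spans = oracle_spans(labels)
    out = [sum(1 for c, _, _ in spans if c == cls) for cls in classes]
    if include_o:
        runs = 0
        for i, tag in enumerate(labels):
            if tag == "O" and (i == 0 or labels[i - 1] != "O"):
                runs += 1
        out.append(runs)
    return out


def oracle_f1(gold: Sequence[str], pred: Sequence[str]) -> float:
    """Micro entity F1 via explicit precision/recall composition."""
    g = set(oracle_spans(gold))
    p = set(oracle_spans(pred))
    if not g and not p:
        return 1.0
    tp = len(g & p)
    precision = tp / len(p) if p else 0.0
    recall = tp / len(g) if g else 0.0
    if precision + recall == 0.0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def oracle_sigma(a: Sequence[float], b: Sequence[float]) -> float:
    """Magnitude-corrected cosine in pure-python scalar arithmetic."""
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(x * x for x in b))
    if na == 0.0 and nb == 0.0:
        return 1.0
    if na == 0.0 or nb == 0.0:
        return 0.0
    dot = sum(x * y for x, y in zip(a, b))
    return (dot / (na * nb)) * (1.0 - abs(na - nb) / (na + nb))


def random_tags(rng, scheme, n: int) -> list[str]:
    """Arbitrary (not necessarily well-formed IOB2) tag sequence."""
    return [scheme.tags[i] for i in rng.integers(0, scheme.n_actions, size=n)]


def random_iob2(rng, scheme, n: int) -> list[str]:
    """Well-formed IOB2 sequence built left to right."""
    out: list[str] = []
    open_cls = None
    for _ in range(n):
        roll = rng.random()
        if open_cls is not None and roll < 0.4:
            out.append(f"I-{open_cls}")
            continue
        if roll < 0.65:
            open_cls = scheme.classes[rng.integers(len(scheme.classes))]
            out.append(f"B-{open_cls}")
        else:
            open_cls = None
            out.append("O")
    return out
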