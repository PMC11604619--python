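"""Seeded synthetic BIO corpora for desk-scale experiments.

The generator emulates the *structure* of annotated NER data — short
sentence-like token sequences in which entity mentions of a few classes are
embedded in non-entity filler — without any natural-language realism.  Each
entity class has its own lexicon of pseudo-words (chemical-like names ending
in "-ol"/"-ine"/"-azole", disease-like names ending in "-itis"/"-oma", and
so on) disjoint from the background pool, so at zero label noise the token
identity determines the class and a per-token classifier can in principle
reach near-perfect entity F1.  This separability is deliberate: it turns
learning smoke tests into assertions about the training machinery, not
about linguistic difficulty.

Two presets mirror the shape of common benchmarks: ``bc5cdr-like`` (two
balanced biomedical classes, chemical and disease) and ``conll-like`` (four
newswire classes with the characteristic mild imbalance, MISC rarest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .labels import LabelScheme, TaggedSequence, count_entities

# ---------------------------------------------------------------------------
# lexicons (deterministic pseudo-words, pools pairwise disjoint)


def _combine(stems: Sequence[str], suffixes: Sequence[str]) -> tuple[str, ...]:
    return tuple(stem + suffix for stem in stems for suffix in suffixes)


LEXICONS: dict[str, tuple[str, ...]] = {
    "CHEM": _combine(
        ("natr", "chlor", "metf", "keto", "sulf", "benz", "carbi", "oxa"),
        ("ol", "ine", "ide", "azole", "ate"),
    ),
    "DISE": _combine(
        ("hepat", "derm", "nephr", "card", "neur", "arthr", "gastr", "leuk"),
        ("itis", "oma", "emia", "osis", "algia"),
    ),
    "PER": _combine(
        ("Mar", "Jon", "Hel", "Kat", "Olg", "Pet", "Ann", "Vik"),
        ("a", "en", "ik", "ova", "sen"),
    ),
    "LOC": _combine(
        ("Bre", "Dan", "Kor", "Mal", "Tus", "Vel", "Nor", "Sar"),
        ("burg", "stad", "ville", "land", "mark"),
    ),
    "ORG": _combine(
        ("Gen", "Uni", "Tel", "Agri", "Med", "Fin", "Ind", "Glo"),
        ("corp", "tech", "bank", "works", "group"),
    ),
    "MISC": _combine(
        ("Olymp", "Euro", "World", "Summ", "Class", "Grand", "Open", "Winter"),
        ("iad", "cup", "fest", "prix", "bowl"),
    ),
}

BACKGROUND: tuple[str, ...] = (
    "the", "of", "in", "and", "to", "a", "was", "were", "with", "for",
    "on", "after", "before", "patients", "patient", "treated", "showed",
    "reported", "study", "dose", "effect", "observed", "during", "cases",
    "results", "increased", "reduced", "clinical", "trial", "group",
    "received", "daily", "severe", "acute", "chronic", "associated",
    "induced", "following", "therapy", "treatment", "response", "levels",
    "significant", "risk", "development", "use", "common", "known",
    "single", "first", "second", "compared", "without", "between",
    "several", "two", "three", "most", "also", "however",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Everything needed to generate a corpus reproducibly.

    ``entity_density`` is the probability of opening an entity at each
    eligible position — a position that is neither inside an entity nor
    immediately after one (a background separator token always follows a
    mention, so two mentions never touch; real mentions are almost always
    separated by at least one non-entity token, and the separator keeps the
    task solvable from local context).  Entity lengths are geometric with
    the given mean, truncated to the remaining sequence length;
    ``class_freqs`` weights the class drawn at each entity start.  ``label_noise`` is the corruption rate used by
    :func:`noisy_copy` — generated gold labels themselves are always clean
    IOB2.
    """

    classes: tuple[str, ...] = ("CHEM", "DISE")
    class_freqs: tuple[float, ...] = (0.5, 0.5)
    n_sequences: int = 500
    length_range: tuple[int, int] = (5, 12)
    entity_density: float = 0.25
    mean_entity_length: float = 1.6
    lexicons: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(LEXICONS)
    )
    background: tuple[str, ...] = BACKGROUND
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.class_freqs):
            raise ValueError("classes and class_freqs must align")
        if abs(sum(self.class_freqs) - 1.0) > 1e-9:
            raise ValueError("class_freqs must sum to 1")
        if not 0.0 <= self.entity_density <= 1.0:
            raise ValueError("entity_density must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if self.mean_entity_length < 1.0:
            raise ValueError("mean_entity_length must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"impossible length range {self.length_range}")
        for cls in self.classes:
            if not self.lexicons.get(cls):
                raise ValueError(f"empty or missing lexicon for class {cls!r}")
        if not self.background:
            raise ValueError("empty background pool")

    @property
    def scheme(self) -> LabelScheme:
        return LabelScheme(self.classes)

    def to_json(self) -> dict:
        return {
            "classes": list(self.classes),
            "class_freqs": list(self.class_freqs),
            "n_sequences": self.n_sequences,
            "length_range": list(self.length_range),
            "entity_density": self.entity_density,
            "mean_entity_length": self.mean_entity_length,
            "label_noise": self.label_noise,
            "seed": self.seed,
        }


def bc5cdr_like(**overrides) -> CorpusSpec:
    """Two balanced biomedical classes (chemical/disease mentions)."""
    return replace(CorpusSpec(), **overrides) if overrides else CorpusSpec()


def conll_like(**overrides) -> CorpusSpec:
    """Four newswire classes with mild imbalance (PER/LOC/ORG ~ 28/30/27%,
    MISC ~ 15% of mentions)."""
    spec = CorpusSpec(
        classes=("PER", "LOC", "ORG", "MISC"),
        class_freqs=(0.28, 0.30, 0.27, 0.15),
    )
    return replace(spec, **overrides) if overrides else spec


PRESETS = {"bc5cdr-like": bc5cdr_like, "conll-like": conll_like}


def generate_corpus(
    spec: CorpusSpec, rng: np.random.Generator | None = None
) -> list[TaggedSequence]:
    """Generate ``spec.n_sequences`` tagged sequences, deterministically for
    a fixed seed.  Gold labels are well-formed IOB2 and entity tokens are
    drawn only from their class lexicon."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    geo_p = 1.0 / spec.mean_entity_length
    lo, hi = spec.length_range
    class_freqs = np.asarray(spec.class_freqs)
    corpus: list[TaggedSequence] = []
    for _ in range(spec.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        tokens: list[str] = []
        tags: list[str] = []
        pos = 0
        after_entity = False  # force a separator so mentions never touch
        while pos < length:
            if (
                not after_entity
                and spec.entity_density > 0
                and rng.random() < spec.entity_density
            ):
                cls = spec.classes[rng.choice(len(spec.classes), p=class_freqs)]
                span_len = min(int(rng.geometric(geo_p)), length - pos)
                pool = spec.lexicons[cls]
                for j in range(span_len):
                    tokens.append(pool[rng.integers(len(pool))])
                    tags.append(f"B-{cls}" if j == 0 else f"I-{cls}")
                pos += span_len
                after_entity = True
            else:
                tokens.append(spec.background[rng.integers(len(spec.background))])
                tags.append("O")
                pos += 1
                after_entity = False
        corpus.append(TaggedSequence(tuple(tokens), tuple(tags)))
    return corpus


def noisy_copy(
    corpus: Sequence[TaggedSequence],
    rate: float,
    rng: np.random.Generator | int = 0,
    scheme: LabelScheme | None = None,
) -> list[TaggedSequence]:
    """Return a copy of the corpus in which each gold tag is independently
    replaced by a different uniformly-drawn tag with probability ``rate``.
    The result may violate IOB2 (that is the point of noise)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if scheme is None:
        classes = sorted(
            {tag[2:] for seq in corpus for tag in seq.gold if tag != "O"}
        )
        scheme = LabelScheme(tuple(classes))
    tags = scheme.tags
    noisy = []
    for seq in corpus:
        new = list(seq.gold)
        for i, tag in enumerate(new):
            if rate > 0 and rng.random() < rate:
                others = [t for t in tags if t != tag]
                new[i] = others[rng.integers(len(others))]
        noisy.append(TaggedSequence(seq.tokens, tuple(new)))
    return noisy


def corpus_stats(
    corpus: Sequence[TaggedSequence], scheme: LabelScheme
) -> dict[str, dict[str, float]]:
    """Absolute and relative entity-mention counts per class."""
    totals = dict.fromkeys(scheme.classes, 0)
    for seq in corpus:
        cv = count_entities(seq.gold, scheme)
        for cls, c in zip(scheme.classes, cv.per_class):
            totals[cls] += c
    grand = sum(totals.values())
    return {
        cls: {
            "count": totals[cls],
            "relative": totals[cls] / grand if grand else 0.0,
        }
        for cls in scheme.classes
    }


def train_val_test(
    spec: CorpusSpec, n_val: int, n_test: int
) -> tuple[list[TaggedSequence], list[TaggedSequence], list[TaggedSequence]]:
    """Generate disjoint splits from independent child streams of the seed."""
    root = np.random.SeedSequence(spec.seed)
    train_seq, val_seq, test_seq = root.spawn(3)
    train = generate_corpus(spec, np.random.default_rng(train_seq))
    val = generate_corpus(
        replace(spec, n_sequences=n_val), np.random.default_rng(val_seq)
    )
    test = generate_corpus(
        replace(spec, n_sequences=n_test), np.random.default_rng(test_seq)
    )
    return train, val, test
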