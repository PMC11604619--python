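# Methods

This note documents the model, the numerical and design choices, and what
the desk-scale experiments do and do not demonstrate.

## The decision process

An episode is one token sequence; states are positions `(x, t)`, actions
are the BIO tags, transitions advance `t` deterministically regardless of
the chosen tag. Because the state carries no history of earlier actions,
the policy is memoryless and all per-token action values for one sequence
can be produced from a single encoder pass. Tags are also given a fixed
positive-integer code (`O = 1`, then `B-c, I-c` in class order) because the
label-cosine reward operates on tag sequences *as integer vectors*; the
code assignment is part of the model definition and is documented in
`LabelScheme` (any fixed bijection would do, but results depend on it, so
it must not silently change).

## Span semantics

Decoding is lenient by default: `B-c` always opens a mention, `I-c`
continues a same-class mention and otherwise opens one. This matches the
behaviour of the standard sequence-evaluation tooling and has a real
consequence for reward design: on a single-token segment, gold `I-PER`
versus predicted `B-PER` scores entity F1 = 1.0, so per-action F1 feedback
cannot teach the B/I distinction at all (token accuracy can). Strict IOB2
validation is available behind a flag and is used to check generated gold
labels, never predictions.

## Reward placement

A scheme partitions the gold labels into contiguous segments; each segment
communicates exactly one aggregated reward, at its last position, with the
EMPTY sentinel everywhere else. EMPTY is deliberately not the number 0: a
numeric 0 is informative feedback, while EMPTY means "no signal yet", and
the two behave differently in the value recursion (a numeric reward also
zeroes the gate `γ_t`). The `+P` variants may additionally overwrite
interior positions (or the terminal value) with local 0-rewards.

Two readings of the published count arithmetic had to be fixed:

* Plain `counts` compares per-class entity counts *without* the O-interval
  entries — the printed worked example (σ ≈ 0.76 for counts vs ≈ 0.89 for
  +O on the same pair) is only consistent with that reading.
* `+P` punishes *impossible* predictions: a predicted class whose gold
  count in the segment is zero. Surplus predictions of a class that does
  occur (predicted count > gold count > 0) are handled solely by capping
  the predicted count at the gold count ("true positives only") before the
  similarity; they receive no local punishment, since nothing marks any
  particular occurrence as the surplus one.

For k-grouped episodes, counting is performed per member sequence and
summed, so neither entities nor O-runs merge across the join of two
concatenated sequences.

Zero-vector conventions for the magnitude-corrected cosine extend the
"full reward iff equal" design goal: σ(0, 0) = 1 and σ(0, B≠0) = 0. Exact
equality short-circuits to 1.0 to keep the iff sharp under floating point.

## Value targets and loss

Targets are computed backward over the reward trace, `q_t = r_t + γ_t
q_{t+1}`, with `q_{n+1} = 0` (episodes end with no future reward), EMPTY
contributing 0 to `r_t`, and `γ_t = 0` at numeric rewards (gated
discounting). Within a segment ending at `j` this reduces to `q_t =
γ^(j−t) r_j`; with the default `γ = 1` every position in a segment
regresses to the segment's reward. The loss is the MSE between these
targets and the Q-estimate *of the action actually taken* — the published
loss leaves the vector/scalar question open, and regressing only the taken
action is the standard value-regression reading (regressing all `|A|`
outputs to one scalar would destroy the untaken actions' estimates).

Exploration follows `ε = max(0.005, 0.5^(round−1))` with 1-based rounds,
i.e. a fully random first round; the alternative reading (first-round
ε = 0.5) only shifts the schedule by one round. Exploration draws
uniformly over the full action set, greedy action included; argmax ties
break to the lowest tag index.

## Training protocol and defaults

`TrainConfig` defaults reproduce the published protocol: γ = 1, learning
rate 1e-5, AdamW with standard moments and decoupled weight decay 0.01,
batches of 8 sampled uniformly with replacement, 400 rounds × 250 updates.
Those optimizer settings are calibrated for fine-tuning a large pretrained
transformer. The desk-scale runs in this package use `desk_config`:
30 rounds × 50 updates and learning rate 3e-3, chosen once for the small
randomly-initialized reference encoder (a 1e-5 rate cannot move a fresh
~34k-parameter network measurably inside 1,500 updates). The head is
initialized uniformly on ±1/√d as published.

The reference encoder (`WindowQModel`) is a token embedding (d = 64), a
±1-token context window concatenation, one tanh layer (d = 128), and the
linear Q-head; gradients are analytic and verified against finite
differences in the tests. It is a *contract*, not the contribution: any
encoder exposing `qhat`/`backward`/`params` can replace it (e.g. a
transformer adapter), and nothing in the learning algorithm depends on its
internals. One RNG seeds the run, with independent spawned streams for
batch sampling and exploration, so histories are bit-reproducible.

## Synthetic corpora

The generator emulates the structure, not the language, of NER data:
sequences of 5–12 tokens; entities opened at eligible positions with
probability `entity_density` (default 0.25); geometric mention lengths
with mean 1.6 tokens (short chemical/disease-style mentions, enough
multi-token spans to exercise boundaries); per-class pseudo-word lexicons
disjoint from the background pool; presets with two balanced biomedical
classes (`bc5cdr-like`) or four mildly imbalanced newswire classes
(`conll-like`, MISC rarest at 15%).

A background separator token always follows a mention, so two mentions
never touch. Real mentions are rarely adjacent, and the separator is what
makes the default corpus *certifiably* separable: a majority-class
per-token vote (with class runs encoded as B/I) attains entity F1 ≥ 0.99
at zero noise, a property the test suite checks. Without it, adjacent
same-class mentions are indistinguishable from continuations for any local
model and impose an F1 ceiling unrelated to the learning algorithm.
`label_noise` corrupts tags only in an explicitly requested noisy copy;
generated gold labels always pass strict IOB2 validation.

Consequently, passing the learning smoke tests shows that the training
machinery — reward placement, gated targets, optimization — can extract a
tagging policy from aggregate feedback under favourable, fully separable
conditions. It does not show robustness to ambiguous tokens, out-of-lexicon
mentions, or realistic class imbalance, and desk-scale scores are not
comparable to benchmark results obtained with pretrained encoders.

## Desk-scale study conditions

The smoke experiments (in `tests/test_acceptance.py`) use a 500-sequence
training split, 100 validation sequences, three seeds (0, 1, 2), the
reference encoder, and 30 × 50 updates; reported per-configuration scores
are the maximum validation entity F1 over rounds, mirroring how
max-over-validation results are conventionally reported. Under these
conditions: dense by-action accuracy feedback and the supervised baseline
both reach F1 = 1.0, and sequence-level Counts+OP reaches ≈ 0.6 from an
untrained ≈ 0.1 — the qualitative ordering (supervised ≥ dense RL ≥
sequence-level count RL ≫ untrained) expected of the framework.

## Known limitations

* The confusion matrix is class-level by default (prefix-collapsed);
  B-versus-I confusions are only visible with `tag_level=True`.
* `entity_f1` returns 1.0 when neither segment contains a mention
  (perfect abstention); the undefined 0/0 case must be fixed by convention
  and this choice avoids punishing correct all-O segments.
* Zero-support classes report precision/recall/F1 = 0 with a warning
  rather than NaN.
* The per-class reward decomposition (one reward signal per entity class)
  is out of scope, as are experience replay, target networks and
  policy-gradient learners.
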