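"""countner: sequence labeling trained from aggregate entity-count rewards.

A value-based reinforcement-learning framework for BIO sequence labeling in
which the supervision signal can be as weak as "how many mentions of each
class does this sequence contain".  The package provides BIO/CoNLL
machinery, the reward schemes (by-action / by-region / by-entity /
k-grouped) and reward functions (token-level and count-based with a
magnitude-corrected cosine), a replay-free Q-learner with gated discounting
and ground-truth Q-targets, entity-level evaluation, and a seeded synthetic
corpus generator.
"""

__version__ = "0.1.0"

from .labels import (
    BC5CDR_SCHEME,
    CONLL_SCHEME,
    CountVector,
    EntitySpan,
    LabelScheme,
    TaggedSequence,
    count_entities,
    count_o_intervals,
    decode_entities,
    encode_labels,
    read_conll,
    write_conll,
)
from .schemes import (
    GroupedEpisode,
    Partition,
    by_action,
    by_entity,
    by_region,
    k_grouped,
    partition_labels,
)
from .rewards import (
    EMPTY,
    RewardSpec,
    RewardTrace,
    assign_rewards,
    cosine_labels,
    count_reward,
    entity_f1,
    exact_match,
    modified_cosine,
    token_accuracy,
)
from .engine import (
    AdamW,
    TrainConfig,
    UpdateResult,
    WindowQModel,
    build_vocab,
    desk_config,
    epsilon_greedy,
    epsilon_schedule,
    gated_discounts,
    mse_loss,
    predict,
    q_targets,
    train,
    train_supervised_baseline,
    update_step,
)
from .evaluation import ConfusionMatrix, EvalReport, entity_prf, token_confusion
from .synth import (
    CorpusSpec,
    bc5cdr_like,
    conll_like,
    corpus_stats,
    generate_corpus,
    noisy_copy,
    train_val_test,
)

__all__ = [
    "BC5CDR_SCHEME",
    "CONLL_SCHEME",
    "AdamW",
    "ConfusionMatrix",
    "CorpusSpec",
    "CountVector",
    "EMPTY",
    "EntitySpan",
    "EvalReport",
    "GroupedEpisode",
    "LabelScheme",
    "Partition",
    "RewardSpec",
    "RewardTrace",
    "TaggedSequence",
    "TrainConfig",
    "UpdateResult",
    "WindowQModel",
    "assign_rewards",
    "bc5cdr_like",
    "build_vocab",
    "by_action",
    "by_entity",
    "by_region",
    "conll_like",
    "corpus_stats",
    "cosine_labels",
    "count_entities",
    "count_o_intervals",
    "count_reward",
    "decode_entities",
    "desk_config",
    "encode_labels",
    "entity_f1",
    "entity_prf",
    "epsilon_greedy",
    "epsilon_schedule",
    "exact_match",
    "gated_discounts",
    "generate_corpus",
    "k_grouped",
    "modified_cosine",
    "mse_loss",
    "noisy_copy",
    "partition_labels",
    "predict",
    "q_targets",
    "read_conll",
    "token_accuracy",
    "token_confusion",
    "train",
    "train_supervised_baseline",
    "train_val_test",
    "update_step",
    "write_conll",
]
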