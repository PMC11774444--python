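"""Seeded synthetic datasets with known ground truth.

Everything downstream (encoding, divergence, discovery, model comparison)
is exercised on data produced here, so the generator plants the structure
those stages are supposed to find:

* responses are a linear map of context-dependent embeddings plus Gaussian
  noise (the forward model the ridge encoder should recover);
* a "planted" word category carries structured residual variance that is
  unpredictable from the embeddings (the ground-truth divergence);
* sentences of planted words contain a marker keyword, so a corpus-difference
  discovery run has a recoverable hypothesis;
* a toy multiple-choice dataset whose correct option is decidable from token
  statistics (the correct option reuses context tokens).

All randomness flows from one seed through named per-stream generators
(tokens, weights, noise, ...), so enlarging one sub-stream does not perturb
the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "GroundTruth",
    "WordEvent",
    "MCItem",
    "generate_word_stream",
    "generate_embeddings",
    "generate_responses",
    "average_repetitions",
    "generate_mc_dataset",
    "generate_dataset",
]

PLANTED_FLAG = "planted"
#: categories assigned at the vocabulary level (a token always carries its
#: category), mirroring word-level semantic annotations of a stimulus text
VOCAB_CATEGORIES = ("social", "physical")


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one synthetic recording session.

    The epoch is 0-500 ms after word onset in 25 ms bins (20 bins); each
    word's embedding mixes its own token vector with a decaying sum over the
    preceding ``context_len`` tokens (19, the context length used when
    extracting LM embeddings for a word).
    """

    n_words: int = 2000
    n_sentences: int = 400
    n_channels: int = 40
    n_timebins: int = 20
    embed_dim: int = 32
    context_len: int = 19
    #: weight of the decaying context sum relative to the word's own token
    context_mix: float = 0.5
    #: geometric decay of context token contributions with distance
    context_decay: float = 0.8
    noise_sd: float = 1.0
    planted_effect: float = 3.0
    planted_fraction: float = 0.3
    n_repetitions: int = 1
    vocab_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sentences < 1 or self.n_words < self.n_sentences:
            raise ValueError(
                f"need n_words >= n_sentences >= 1, got "
                f"n_words={self.n_words}, n_sentences={self.n_sentences}"
            )
        for name in ("n_channels", "n_timebins", "embed_dim", "n_repetitions",
                     "vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.context_len < 0:
            raise ValueError("context_len must be >= 0")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.planted_effect < 0:
            raise ValueError("noise_sd and planted_effect must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent generator for one randomness sub-stream."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_STREAMS = {
    "tokens": 0,
    "sentences": 1,
    "token_vectors": 2,
    "weights": 3,
    "noise": 4,
    "planted": 5,
    "mc": 6,
    "categories": 7,
    "layers": 8,
}


@dataclass(frozen=True)
class WordEvent:
    """One stimulus word: its token, sentence membership and annotations."""

    word_id: int
    token: str
    sentence_id: int
    position_in_sentence: int
    category_flags: frozenset = field(default_factory=frozenset)


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    true_weights: np.ndarray  # embed_dim x (n_channels * n_timebins)
    true_bias: np.ndarray  # (n_channels * n_timebins,)
    planted_word_ids: frozenset
    planted_keyword: str
    noise_sd: float
    #: per-word amplitudes of the planted low-rank residual, zero off-category;
    #: (n_words, rank) — appending these columns to the embeddings makes the
    #: planted residual linearly predictable (the "fine-tuned" representation)
    planted_amplitudes: np.ndarray | None = None
    #: spatial patterns of the planted residual, (rank, n_channels*n_timebins)
    planted_patterns: np.ndarray | None = None

    def to_jsonable(self) -> dict:
        return {
            "planted_word_ids": sorted(self.planted_word_ids),
            "planted_keyword": self.planted_keyword,
            "noise_sd": self.noise_sd,
        }


@dataclass(frozen=True)
class MCItem:
    """A multiple-choice item: context x, options y1..yN, one correct."""

    context: tuple
    options: tuple  # tuple of tuples of tokens
    correct_index: int

    def __post_init__(self) -> None:
        if len(self.options) < 2:
            raise ValueError("need at least 2 options")
        if not 0 <= self.correct_index < len(self.options):
            raise ValueError("correct_index out of range")
        if any(len(o) == 0 for o in self.options):
            raise ValueError("options must be non-empty token sequences")


def _token_name(i: int) -> str:
    return f"tok{i:04d}"


def token_categories(config: SimConfig) -> dict:
    """Map token -> category flags, fixed at the vocabulary level.

    A disjoint slice of the vocabulary is assigned to each category so that
    word-level annotations exist for the category-improvement analysis.
    """
    rng = config.rng("categories")
    perm = rng.permutation(config.vocab_size)
    per_cat = max(1, config.vocab_size // (2 * len(VOCAB_CATEGORIES)))
    out: dict = {}
    for ci, cat in enumerate(VOCAB_CATEGORIES):
        for idx in perm[ci * per_cat:(ci + 1) * per_cat]:
            out[_token_name(int(idx))] = frozenset({cat})
    return out


def generate_word_stream(config: SimConfig) -> list[WordEvent]:
    """Word events in presentation order, partitioned into contiguous
    sentences; ``floor(planted_fraction * n_sentences)`` sentences contain the
    planted keyword and their words carry the "planted" flag."""
    rng_tok = config.rng("tokens")
    rng_sent = config.rng("sentences")
    rng_planted = config.rng("planted")

    # contiguous sentence lengths, as even as n_words allows
    base, rem = divmod(config.n_words, config.n_sentences)
    lengths = [base + 1 if s < rem else base for s in range(config.n_sentences)]

    n_planted = int(np.floor(config.planted_fraction * config.n_sentences))
    planted_sents = set(
        rng_planted.choice(config.n_sentences, size=n_planted, replace=False).tolist()
    )
    keyword = "kw_storm"  # marker token, outside the numeric vocabulary
    cats = token_categories(config)

    events: list[WordEvent] = []
    wid = 0
    for sid, length in enumerate(lengths):
        tokens = [
            _token_name(int(t))
            for t in rng_tok.integers(0, config.vocab_size, size=length)
        ]
        if sid in planted_sents:
            pos = int(rng_sent.integers(0, length))
            tokens[pos] = keyword
        for pos, tok in enumerate(tokens):
            flags = set(cats.get(tok, frozenset()))
            if sid in planted_sents:
                flags.add(PLANTED_FLAG)
            events.append(
                WordEvent(wid, tok, sid, pos, frozenset(flags))
            )
            wid += 1
    return events


def _token_vectors(config: SimConfig) -> dict:
    rng = config.rng("token_vectors")
    vocab = [_token_name(i) for i in range(config.vocab_size)]
    vocab.append("kw_storm")
    vecs = rng.standard_normal((len(vocab), config.embed_dim))
    return dict(zip(vocab, vecs))


def generate_embeddings(
    events: list[WordEvent], config: SimConfig
) -> np.ndarray:
    """Context-dependent embedding matrix (n_words x embed_dim).

    Row ``w`` is the word's own token vector plus ``context_mix`` times a
    geometrically decaying sum over the preceding ``context_len`` token
    vectors — a linear stand-in for contextual LM hidden states: the same
    token in different contexts gets different rows.
    """
    if not events:
        raise ValueError("events must be non-empty")
    vecs = _token_vectors(config)
    tok_mat = np.stack([vecs[e.token] for e in events])
    n = len(events)
    out = tok_mat.copy()
    if config.context_mix != 0.0 and config.context_len > 0:
        decay = config.context_decay ** np.arange(1, config.context_len + 1)
        for lag, d in enumerate(decay, start=1):
            out[lag:] += config.context_mix * d * tok_mat[:-lag]
    return out


def generate_layer_stack(
    events: list[WordEvent],
    config: SimConfig,
    n_layers: int = 3,
    true_layer: int | None = None,
) -> tuple[list[np.ndarray], int]:
    """A stack of candidate embedding layers, one of which generated the data.

    Layer ``true_layer`` (middle layer by default, as intermediate layers
    tend to predict brain responses best) is the generating embedding; the
    others are progressively noise-degraded copies, mixing weight
    ``0.5 ** |j - true_layer|``. Returns ``(layers, true_layer)``.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if true_layer is None:
        true_layer = n_layers // 2
    if not 0 <= true_layer < n_layers:
        raise ValueError("true_layer out of range")
    L = generate_embeddings(events, config)
    rng = config.rng("layers")
    scale = float(np.std(L))
    layers = []
    for j in range(n_layers):
        if j == true_layer:
            layers.append(L)
        else:
            w = 0.5 ** abs(j - true_layer)
            noise = rng.standard_normal(L.shape) * scale
            layers.append(w * L + (1 - w) * noise)
    return layers, true_layer


def make_ground_truth(events: list[WordEvent], config: SimConfig) -> GroundTruth:
    """Draw the linear forward model and the planted low-rank residual."""
    rng = config.rng("weights")
    n_targets = config.n_channels * config.n_timebins
    W = rng.standard_normal((config.embed_dim, n_targets)) / np.sqrt(
        config.embed_dim
    )
    b = rng.standard_normal(n_targets)

    planted_ids = frozenset(
        e.word_id for e in events if PLANTED_FLAG in e.category_flags
    )
    rank = 2
    # spatial patterns scaled to unit mean square so that the per-element
    # residual power of a planted word is planted_effect**2 on average
    U = rng.standard_normal((rank, n_targets))
    U /= np.sqrt(np.mean(U**2, axis=1, keepdims=True))
    amps = np.zeros((len(events), rank))
    if planted_ids:
        idx = sorted(planted_ids)
        amps[idx] = rng.standard_normal((len(idx), rank))
    return GroundTruth(
        true_weights=W,
        true_bias=b,
        planted_word_ids=planted_ids,
        planted_keyword="kw_storm",
        noise_sd=config.noise_sd,
        planted_amplitudes=amps,
        planted_patterns=U,
    )


def generate_responses(
    embeddings: np.ndarray,
    truth: GroundTruth,
    config: SimConfig,
    repetition: int = 0,
) -> np.ndarray:
    """Response tensor ``M`` (n_words x n_channels x n_timebins).

    ``M[w] = L[w] @ W + b + planted residual + noise``; the planted residual
    is a fixed low-rank spatial pattern times word-specific Gaussian
    amplitude, independent of the embeddings. Distinct ``repetition`` indices
    redraw only the noise (the signal is trial-invariant).
    """
    n_words = embeddings.shape[0]
    n_targets = config.n_channels * config.n_timebins
    if embeddings.shape[1] != truth.true_weights.shape[0]:
        raise ValueError(
            f"embedding dim {embeddings.shape[1]} does not match weights "
            f"{truth.true_weights.shape[0]}"
        )
    if truth.true_weights.shape[1] != n_targets:
        raise ValueError("weight target dim does not match channels*timebins")
    signal = embeddings @ truth.true_weights + truth.true_bias
    if truth.planted_amplitudes is not None and config.planted_effect > 0:
        rank = truth.planted_amplitudes.shape[1]
        signal = signal + (
            config.planted_effect / np.sqrt(rank)
        ) * truth.planted_amplitudes @ truth.planted_patterns
    rng = np.random.default_rng(
        np.random.SeedSequence(
            config.seed, spawn_key=(_STREAMS["noise"], repetition)
        )
    )
    noise = rng.standard_normal((n_words, n_targets)) * config.noise_sd
    M = signal + noise
    return M.reshape(n_words, config.n_channels, config.n_timebins)


def average_repetitions(tensors: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean across repetitions; noise variance drops as 1/n."""
    if not tensors:
        raise ValueError("no repetitions to average")
    shape = tensors[0].shape
    for t in tensors[1:]:
        if t.shape != shape:
            raise ValueError(f"shape mismatch: {t.shape} vs {shape}")
    return np.mean(np.stack(tensors), axis=0)


def generate_mc_dataset(
    n_items: int, n_options: int, seed: int, vocab_size: int = 200,
    context_len: int = 8, option_len: int = 2,
) -> list[MCItem]:
    """Toy multiple-choice items whose correct option reuses context tokens.

    The planted rule — the correct option's tokens all occur in the context,
    distractor tokens never do — is decidable from token statistics alone, so
    a scorer that learns to up-weight recently seen tokens solves the task.
    """
    if n_options < 2:
        raise ValueError("need at least 2 options")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["mc"],)))
    half = vocab_size // 2
    items = []
    for _ in range(n_items):
        ctx = rng.integers(0, half, size=context_len)
        correct = tuple(
            _token_name(int(t))
            for t in rng.choice(ctx, size=option_len, replace=True)
        )
        options = []
        for _j in range(n_options - 1):
            distract = rng.integers(half, vocab_size, size=option_len)
            options.append(tuple(_token_name(int(t)) for t in distract))
        correct_index = int(rng.integers(0, n_options))
        options.insert(correct_index, correct)
        items.append(
            MCItem(
                context=tuple(_token_name(int(t)) for t in ctx),
                options=tuple(options),
                correct_index=correct_index,
            )
        )
    return items


def generate_dataset(config: SimConfig):
    """One full session: events, embeddings, ground truth, averaged responses.

    Returns ``(events, L, truth, M)`` with ``M`` averaged over
    ``config.n_repetitions`` independent-noise repetitions.
    """
    events = generate_word_stream(config)
    L = generate_embeddings(events, config)
    truth = make_ground_truth(events, config)
    reps = [
        generate_responses(L, truth, config, repetition=r)
        for r in range(config.n_repetitions)
    ]
    M = average_repetitions(reps)
    return events, L, truth, M


def finetuned_embeddings(L: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Representation that additionally encodes the planted category.

    Appends the planted residual amplitudes as extra embedding coordinates,
    emulating a model fine-tuned on the planted domain: the structured
    residual becomes linearly predictable, so encoding improves specifically
    on planted words.
    """
    if truth.planted_amplitudes is None:
        raise ValueError("ground truth carries no planted amplitudes")
    return np.hstack([L, truth.planted_amplitudes])


def events_to_records(events: list[WordEvent]) -> list[dict]:
    return [
        {
            "word_id": e.word_id,
            "token": e.token,
            "sentence_id": e.sentence_id,
            "position": e.position_in_sentence,
            "categories": ",".join(sorted(e.category_flags)),
        }
        for e in events
    ]


def mc_items_to_json(items: list[MCItem]) -> str:
    return json.dumps(
        [
            {
                "context": list(it.context),
                "options": [list(o) for o in it.options],
                "correct_index": it.correct_index,
            }
            for it in items
        ],
        indent=1,
    )


def mc_items_from_json(text: str) -> list[MCItem]:
    return [
        MCItem(
            context=tuple(d["context"]),
            options=tuple(tuple(o) for o in d["options"]),
            correct_index=d["correct_index"],
        )
        for d in json.loads(text)
    ]
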