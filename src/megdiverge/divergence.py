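"""Per-word divergence statistic and contrast-corpus construction.

After encoding, the cells of the sensor x time grid whose held-out
correlation passes a one-sided significance test (p < 0.001 by default) form
the significant set S. For each word w the divergence statistic is the mean
squared prediction error over S,

    MSE_w = 1/|S| * sum_{i in S} (Mhat_wi - M_wi)^2 ,

large where the brain response carries structure the embeddings cannot
predict. Words aggregate to sentences by an unweighted mean, sentences are
ranked by descending score, and the top/bottom ``top_n`` sentences become
the contrast corpora D0 (least predicted) and D1 (best predicted) handed to
the hypothesis-discovery stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import WordEvent

__all__ = [
    "ChannelSet",
    "DivergenceTable",
    "ContrastCorpora",
    "significant_channels",
    "word_mse",
    "sentence_scores",
    "build_contrast",
    "sentences_from_events",
]


@dataclass
class ChannelSet:
    """Significance-gated (channel, timebin) cells.

    ``members`` is a boolean mask (n_channels x n_timebins); ``pool`` records
    whether gating was cell-wise over the full spatio-temporal grid
    ("cells", default) or channel-wise with a channel kept at every timebin
    if it is significant in any ("channels").
    """

    members: np.ndarray
    alpha: float
    n_words: int
    pool: str = "cells"

    @property
    def size(self) -> int:
        return int(self.members.sum())

    def pairs(self) -> list[tuple[int, int]]:
        return [tuple(p) for p in np.argwhere(self.members)]


@dataclass
class DivergenceTable:
    word_mse: np.ndarray  # (n_words,)
    sentence_mse: pd.Series  # index: sentence_id
    ranking: np.ndarray  # sentence ids, descending mean MSE


@dataclass
class ContrastCorpora:
    """D0 = least-predicted sentences, D1 = best-predicted; disjoint."""

    d0_ids: np.ndarray
    d1_ids: np.ndarray
    d0_sentences: list[str]
    d1_sentences: list[str]
    top_n: int


def significant_channels(
    correlations: np.ndarray,
    n_words: int,
    alpha: float = 0.001,
    pool: str = "cells",
) -> ChannelSet:
    """Cells whose Pearson r is significantly positive.

    One-sided test of r > 0 via the exact t transform
    t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 degrees of freedom; no
    multiple-comparison correction at this gating step (a raw p threshold).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_words < 3:
        raise ValueError("need n_words >= 3 for the correlation test")
    r = np.asarray(correlations, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n_words - 2) / np.sqrt(1.0 - r**2)
    p = stats.t.sf(t, df=n_words - 2)
    mask = np.where(np.isnan(r), False, p < alpha)
    # r == 1 exactly: t is +inf, sf gives 0 -> included, as it should be
    if pool == "channels":
        mask = np.repeat(
            mask.any(axis=1, keepdims=True), mask.shape[1], axis=1
        )
    elif pool != "cells":
        raise ValueError(f"unknown pooling variant {pool!r}")
    return ChannelSet(members=mask, alpha=alpha, n_words=n_words, pool=pool)


def word_mse(M: np.ndarray, M_hat: np.ndarray, S: ChannelSet) -> np.ndarray:
    """Mean squared actual-vs-predicted difference over the cells of S,
    one value per word; channels outside S never enter the statistic."""
    if M.shape != M_hat.shape:
        raise ValueError(f"shape mismatch {M.shape} vs {M_hat.shape}")
    if S.members.shape != M.shape[1:]:
        raise ValueError("channel set grid does not match response grid")
    if S.size == 0:
        raise ValueError("empty significant set: MSE_w undefined")
    diff2 = (M_hat - M) ** 2
    return diff2[:, S.members].mean(axis=1)


def word_mse_per_bin(
    M: np.ndarray, M_hat: np.ndarray, S: ChannelSet
) -> np.ndarray:
    """Per-word, per-timebin MSE over the significant channels of each bin.

    Returns (n_words, n_timebins); bins with no significant channel are NaN
    (the statistic is undefined there). Feeds the time-resolved
    category-improvement analysis.
    """
    if M.shape != M_hat.shape:
        raise ValueError(f"shape mismatch {M.shape} vs {M_hat.shape}")
    if S.members.shape != M.shape[1:]:
        raise ValueError("channel set grid does not match response grid")
    diff2 = (M_hat - M) ** 2
    n_sig = S.members.sum(axis=0)  # per timebin
    masked = diff2 * S.members[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = masked.sum(axis=1) / n_sig
    out[:, n_sig == 0] = np.nan
    return out


def sentence_scores(
    word_mse_values: np.ndarray, events: list[WordEvent]
) -> DivergenceTable:
    """Unweighted per-sentence mean of member words' MSE_w, ranked
    descending; ties keep the lower sentence_id first."""
    mse = np.asarray(word_mse_values, dtype=float)
    if len(mse) != len(events):
        raise ValueError("word_mse length does not match events")
    sid = np.array([e.sentence_id for e in events])
    s = pd.Series(mse).groupby(sid).mean()
    s.index.name = "sentence_id"
    order = sorted(s.index, key=lambda i: (-s.loc[i], i))
    return DivergenceTable(
        word_mse=mse, sentence_mse=s, ranking=np.array(order)
    )


def sentences_from_events(events: list[WordEvent]) -> dict[int, str]:
    """Reassemble sentence text (space-joined tokens) keyed by sentence_id."""
    out: dict[int, list[str]] = {}
    for e in events:
        out.setdefault(e.sentence_id, []).append(e.token)
    return {k: " ".join(v) for k, v in out.items()}


def build_contrast(
    table: DivergenceTable,
    sentences: dict[int, str],
    top_n: int = 100,
) -> ContrastCorpora:
    """Top ``top_n`` highest-MSE sentences as D0, lowest as D1.

    When fewer than ``2*top_n`` sentences are available, ``top_n`` is
    reduced symmetrically so the corpora stay disjoint.
    """
    n = len(table.ranking)
    if n == 0:
        raise ValueError("empty divergence table")
    if n < 2 * top_n:
        import warnings

        top_n = n // 2
        warnings.warn(
            f"fewer than 2*top_n sentences; reducing top_n to {top_n}",
            stacklevel=2,
        )
        if top_n == 0:
            raise ValueError("not enough sentences to build both corpora")
    d0 = table.ranking[:top_n]
    d1 = table.ranking[-top_n:][::-1]  # best-predicted first
    return ContrastCorpora(
        d0_ids=d0,
        d1_ids=d1,
        d0_sentences=[sentences[i] for i in d0],
        d1_sentences=[sentences[i] for i in d1],
        top_n=top_n,
    )


def length_bias_diagnostic(
    table: DivergenceTable, events: list[WordEvent]
) -> float:
    """Pearson r between sentence score and sentence length (a length
    confound check on the unweighted-mean aggregation)."""
    sid = np.array([e.sentence_id for e in events])
    lengths = pd.Series(np.ones_like(sid)).groupby(sid).sum()
    common = table.sentence_mse.index
    if table.sentence_mse.std() == 0 or lengths.loc[common].std() == 0:
        return float("nan")
    return float(np.corrcoef(table.sentence_mse, lengths.loc[common])[0, 1])
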