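"""A tiny trainable next-token scorer over the synthetic vocabulary.

The scorer assigns, at every position of a token sequence, a logit vector
over the vocabulary predicting the token at that position from the tokens
before it:

    logit[t, v] = bias[v] + copy_weight * freq(v in tokens[:t])

i.e. a unigram bias plus a "copy" term that up-weights tokens already seen
in the context; ``freq`` is the relative frequency of ``v`` among the
preceding tokens (bounded in [0, 1], which keeps gradient descent well
conditioned on long streams). Both parameters are trained by full-batch gradient descent;
the objective is convex in (bias, copy_weight) because the logits are
linear in them. The copy term is exactly the statistic that solves the
planted multiple-choice task (correct options reuse context tokens), so the
scorer can learn that task from cross-entropy on option scores, and it also
supports a plain next-token language-modeling objective.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import softmax

__all__ = ["ToyScorer"]


class ToyScorer:
    def __init__(self, vocab: Sequence[str], copy_weight: float = 0.0,
                 bias: np.ndarray | None = None):
        self.vocab = list(vocab)
        self.index = {t: i for i, t in enumerate(self.vocab)}
        self.copy_weight = float(copy_weight)
        self.bias = (
            np.zeros(len(self.vocab)) if bias is None else np.asarray(bias, float).copy()
        )
        if self.bias.shape != (len(self.vocab),):
            raise ValueError("bias length must equal vocabulary size")
        self.loss_curve: list[float] = []

    def clone(self) -> "ToyScorer":
        c = ToyScorer(self.vocab, self.copy_weight, self.bias)
        return c

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.index[t] for t in tokens], dtype=int)
        except KeyError as e:
            raise ValueError(f"token {e.args[0]!r} not in vocabulary") from None

    def _counts_before(self, ids: np.ndarray) -> np.ndarray:
        """freq[t, v] = relative frequency of v among ids[:t]; shape (T, V).

        Row 0 is all zeros (no context yet)."""
        T, V = len(ids), len(self.vocab)
        onehot = np.zeros((T, V))
        onehot[np.arange(T), ids] = 1.0
        counts = np.zeros((T, V))
        if T > 1:
            counts[1:] = np.cumsum(onehot[:-1], axis=0)
            counts[1:] /= np.arange(1, T)[:, None]
        return counts

    def token_logits(self, tokens: Sequence[str]) -> np.ndarray:
        """(len(tokens), V) logits; row t predicts tokens[t] from tokens[:t]."""
        ids = self.encode(tokens)
        return self.bias + self.copy_weight * self._counts_before(ids)

    # ------------------------------------------------------------------
    # language-modeling objective

    def lm_loss(self, tokens: Sequence[str]) -> float:
        """Mean next-token cross-entropy over the stream."""
        ids = self.encode(tokens)
        logits = self.token_logits(tokens)
        logp = logits - _logsumexp_rows(logits)
        return float(-logp[np.arange(len(ids)), ids].mean())

    def _lm_grad(self, ids: np.ndarray):
        counts = self._counts_before(ids)
        logits = self.bias + self.copy_weight * counts
        probs = softmax(logits, axis=1)
        dlogits = probs.copy()
        dlogits[np.arange(len(ids)), ids] -= 1.0
        dlogits /= len(ids)
        db = dlogits.sum(axis=0)
        dc = float((dlogits * counts).sum())
        loss = float(
            -np.log(probs[np.arange(len(ids)), ids] + 1e-300).mean()
        )
        return loss, db, dc

    def train_lm(self, tokens: Sequence[str], epochs: int = 50,
                 lr: float = 1.0) -> "ToyScorer":
        """Full-batch gradient descent on the LM objective (in place)."""
        ids = self.encode(tokens)
        for _ in range(epochs):
            loss, db, dc = self._lm_grad(ids)
            self.bias -= lr * db
            self.copy_weight -= lr * dc
            self.loss_curve.append(loss)
        return self


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1, keepdims=True)
    return m + np.log(np.exp(a - m).sum(axis=1, keepdims=True))
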