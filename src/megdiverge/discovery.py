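"""Data-driven discovery of differences between two sentence corpora.

Given the contrast corpora D0 (poorly predicted) and D1 (well predicted), a
*proposer* generates candidate natural-language hypotheses about how D0
differs from D1 and a *verifier* judges each hypothesis sentence by
sentence. A hypothesis's validity is the held-out difference in verified
fractions, D0 minus D1, in [-1, 1]: +1 for a perfect separator, 0 for an
uninformative statement. Proposal and verification are repeated over 3
cross-validation folds, and significance is assessed by permuting corpus
labels over the pooled held-out sentences (add-one empirical p-value).

The backends are pluggable; the shipped implementations are deterministic
token-frequency mocks that make the whole loop testable at desk scale.
A remote LLM proposer/verifier can be plugged in by implementing the same
two methods.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "Hypothesis",
    "ProposerBackend",
    "VerifierBackend",
    "KeywordProposer",
    "KeywordVerifier",
    "RandomVerifier",
    "compute_validity",
    "validity_pvalue",
    "cross_validated_discovery",
]


@dataclass
class Hypothesis:
    text: str
    validity: float
    p_value: float
    fold_validities: list = field(default_factory=list)


class ProposerBackend(Protocol):
    def propose(
        self,
        samples_d0: Sequence[str],
        samples_d1: Sequence[str],
        n_hypotheses: int,
    ) -> list[str]: ...


class VerifierBackend(Protocol):
    def verify(self, hypothesis_text: str, sentence: str) -> bool: ...


_HYP_TEMPLATE = "contain the word '{tok}'"
_HYP_RE = re.compile(r"contain the word '([^']+)'")


class KeywordProposer:
    """Hypotheses naming the tokens most over-represented in D0 vs D1.

    Over-representation is measured by document frequency difference (the
    fraction of D0 sample sentences containing the token minus the fraction
    of D1 samples); ties break lexicographically for determinism.
    """

    def propose(self, samples_d0, samples_d1, n_hypotheses):
        def doc_freq(samples):
            counts: dict[str, int] = {}
            for s in samples:
                for tok in set(s.split()):
                    counts[tok] = counts.get(tok, 0) + 1
            n = max(len(samples), 1)
            return {t: c / n for t, c in counts.items()}

        f0 = doc_freq(samples_d0)
        f1 = doc_freq(samples_d1)
        tokens = sorted(set(f0) | set(f1))
        scored = sorted(
            tokens, key=lambda t: (-(f0.get(t, 0.0) - f1.get(t, 0.0)), t)
        )
        return [_HYP_TEMPLATE.format(tok=t) for t in scored[:n_hypotheses]]


class KeywordVerifier:
    """Membership test for hypotheses of the keyword-proposer form."""

    def verify(self, hypothesis_text: str, sentence: str) -> bool:
        m = _HYP_RE.search(hypothesis_text)
        if m is None:
            return False
        return m.group(1) in sentence.split()


class RandomVerifier:
    """Coin-flip verifier (null model for calibration checks).

    Deterministic given the seed: the verdict is a hash of (seed,
    hypothesis, sentence), so repeated calls agree.
    """

    def __init__(self, seed: int, p_true: float = 0.5):
        self.seed = seed
        self.p_true = p_true

    def verify(self, hypothesis_text: str, sentence: str) -> bool:
        import hashlib

        # a cryptographic hash: verdicts for different (hypothesis, sentence)
        # pairs must be independent coin flips, which linear checksums
        # (crc32, builtin hash) do not deliver
        digest = hashlib.blake2b(
            f"{self.seed}|{hypothesis_text}|{sentence}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(digest, "big") / 2**64 < self.p_true


def compute_validity(
    verifier: VerifierBackend,
    hypothesis_text: str,
    d0_held: Sequence[str],
    d1_held: Sequence[str],
) -> float:
    """Held-out validity: fraction of D0 sentences verified true minus the
    fraction of D1 sentences verified true."""
    if not d0_held or not d1_held:
        raise ValueError("held-out sets must be non-empty")
    v0 = np.mean([verifier.verify(hypothesis_text, s) for s in d0_held])
    v1 = np.mean([verifier.verify(hypothesis_text, s) for s in d1_held])
    return float(v0 - v1)


def _validity_from_verdicts(verdicts: np.ndarray, labels: np.ndarray) -> float:
    return float(verdicts[labels == 0].mean() - verdicts[labels == 1].mean())


def validity_pvalue(
    verifier: VerifierBackend,
    hypothesis_text: str,
    d0_held: Sequence[str],
    d1_held: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Add-one empirical p-value under corpus-label permutation.

    Verifier verdicts are computed once per pooled sentence; permutations
    shuffle only the D0/D1 labels, so p = (1 + #{perm >= observed}) /
    (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not d0_held or not d1_held:
        raise ValueError("held-out sets must be non-empty")
    verdicts = np.array(
        [verifier.verify(hypothesis_text, s) for s in list(d0_held) + list(d1_held)],
        dtype=float,
    )
    labels = np.array([0] * len(d0_held) + [1] * len(d1_held))
    observed = _validity_from_verdicts(verdicts, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _validity_from_verdicts(verdicts, perm) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def _contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    return [idx for idx in np.array_split(np.arange(n), k)]


def cross_validated_discovery(
    proposer: ProposerBackend,
    verifier: VerifierBackend,
    d0: Sequence[str],
    d1: Sequence[str],
    folds: int = 3,
    n_hypotheses: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    n_proposal_samples: int = 25,
) -> list[Hypothesis]:
    """Propose-and-verify over cross-validation folds.

    Per fold, one split of each corpus is held out for verification and the
    proposer sees a sample of the remaining sentences. Hypotheses are
    deduplicated by exact text; a hypothesis's validity is the mean over the
    folds where it was evaluated, and its p-value comes from label
    permutation over the pooled held-out evaluations. Ranked by descending
    validity, ties by ascending p-value then lexicographic text.

    ``folds=1`` degenerates to proposing and verifying on the full corpora
    (equivalent to a single :func:`compute_validity` call per hypothesis).
    """
    d0, d1 = list(d0), list(d1)
    if min(len(d0), len(d1)) < folds:
        raise ValueError("each corpus needs at least `folds` sentences")
    rng = np.random.default_rng(seed)

    folds0 = _contiguous_folds(len(d0), folds) if folds > 1 else [np.arange(len(d0))]
    folds1 = _contiguous_folds(len(d1), folds) if folds > 1 else [np.arange(len(d1))]

    per_hyp_folds: dict[str, list[float]] = {}
    pooled: dict[str, tuple[list[float], list[int]]] = {}
    any_proposed = False
    for fi in range(len(folds0)):
        held0 = [d0[i] for i in folds0[fi]]
        held1 = [d1[i] for i in folds1[fi]]
        if folds > 1:
            prop0 = [d0[i] for i in np.setdiff1d(np.arange(len(d0)), folds0[fi])]
            prop1 = [d1[i] for i in np.setdiff1d(np.arange(len(d1)), folds1[fi])]
        else:
            prop0, prop1 = held0, held1
        if len(prop0) > n_proposal_samples:
            prop0 = [prop0[i] for i in rng.choice(len(prop0), n_proposal_samples, replace=False)]
        if len(prop1) > n_proposal_samples:
            prop1 = [prop1[i] for i in rng.choice(len(prop1), n_proposal_samples, replace=False)]
        hyps = proposer.propose(prop0, prop1, n_hypotheses)
        if hyps:
            any_proposed = True
        for h in dict.fromkeys(hyps):  # dedupe within fold, keep order
            val = compute_validity(verifier, h, held0, held1)
            per_hyp_folds.setdefault(h, []).append(val)
            verd, labs = pooled.setdefault(h, ([], []))
            verd.extend(float(verifier.verify(h, s)) for s in held0)
            labs.extend([0] * len(held0))
            verd.extend(float(verifier.verify(h, s)) for s in held1)
            labs.extend([1] * len(held1))
    if not any_proposed:
        raise ValueError("proposer returned no hypotheses in any fold")

    results = []
    for h in sorted(per_hyp_folds):
        fold_vals = per_hyp_folds[h]
        validity = float(np.mean(fold_vals))
        verdicts = np.array(pooled[h][0])
        labels = np.array(pooled[h][1])
        observed = _validity_from_verdicts(verdicts, labels)
        p = _permutation_p(verdicts, labels, observed, n_perm,
                           np.random.default_rng(_hyp_seed(seed, h)))
        results.append(
            Hypothesis(text=h, validity=validity, p_value=p,
                       fold_validities=fold_vals)
        )
    results.sort(key=lambda h: (-h.validity, h.p_value, h.text))
    return results


def _hyp_seed(seed: int, text: str) -> int:
    import zlib

    return (seed * 1_000_003 + zlib.crc32(text.encode())) % (2**31)


def _permutation_p(verdicts, labels, observed, n_perm, rng) -> float:
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _validity_from_verdicts(verdicts, perm) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)
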