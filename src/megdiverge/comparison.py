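"""Base-vs-fine-tuned model comparison statistics.

Covers four pieces of machinery:

* multiple-choice scoring as N language-modeling tasks — each option is
  appended to the context, the scorer's logits for the realized option
  tokens are summed into one score per option, and cross-entropy over the
  score vector trains the scorer;
* a per-(channel, timebin) permutation test of the difference in encoding
  correlation between two prediction tensors, with the null built by
  permuting the word order of the measured responses (10,000 permutations
  by default, add-one two-sided empirical p);
* a category-wise MSE-improvement analysis: per timebin, a two-sample
  t-test of in-category vs out-of-category per-word improvement, corrected
  across timebins with Benjamini-Hochberg FDR;
* a language-modeling-loss control comparing two scorers under contiguous
  3-fold cross-validation on a token stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_softmax
from statsmodels.stats.multitest import multipletests

from .scorer import ToyScorer
from .simulate import MCItem, WordEvent

__all__ = [
    "OptionScores",
    "ChannelComparison",
    "score_options",
    "mc_loss",
    "mc_accuracy",
    "train_mc",
    "permutation_channel_test",
    "category_improvement",
    "bh_fdr",
    "lm_loss_control",
]


@dataclass
class OptionScores:
    scores: np.ndarray  # (N,)
    correct_index: int


@dataclass
class ChannelComparison:
    delta_r: np.ndarray  # n_channels x n_timebins, r_ft - r_base
    p_values: np.ndarray  # same shape, add-one two-sided empirical p
    labels: np.ndarray  # same shape, values in {"better","worse","ns"}
    n_perm: int
    alpha: float

    def timebin_fractions(self) -> pd.DataFrame:
        """Per-timebin fractions of channels better / worse / ns (sum to 1)."""
        rows = []
        for t in range(self.labels.shape[1]):
            col = self.labels[:, t]
            n = len(col)
            rows.append(
                {
                    "timebin": t,
                    "better": (col == "better").sum() / n,
                    "worse": (col == "worse").sum() / n,
                    "ns": (col == "ns").sum() / n,
                }
            )
        return pd.DataFrame(rows)


def score_options(
    scorer, item: MCItem, use_log_softmax: bool = False
) -> OptionScores:
    """Sum the scorer's logits over each option's token positions.

    For option ``y_j`` the sequence ``x || y_j`` is scored; position ``p``
    of the option contributes the scorer's logit for the realized token at
    ``p``, read from the prediction made after seeing all preceding tokens.
    ``use_log_softmax`` switches to summed log-probabilities (the
    normalized likelihood reading) instead of raw logits.
    """
    scores = np.empty(len(item.options))
    ctx = list(item.context)
    for j, opt in enumerate(item.options):
        if len(opt) == 0:
            raise ValueError("empty option")
        seq = ctx + list(opt)
        logits = np.asarray(scorer.token_logits(seq), dtype=float)
        if use_log_softmax:
            logits = log_softmax(logits, axis=1)
        ids = scorer.encode(seq)
        pos = np.arange(len(ctx), len(seq))
        scores[j] = logits[pos, ids[pos]].sum()
    return OptionScores(scores=scores, correct_index=item.correct_index)


def mc_loss(option_scores: OptionScores) -> float:
    """Cross-entropy of the option-score vector w.r.t. the correct option."""
    s = option_scores.scores
    return float(-log_softmax(s)[option_scores.correct_index])


def mc_accuracy(scorer, items: list[MCItem], **kw) -> float:
    if not items:
        raise ValueError("no items")
    hits = sum(
        int(np.argmax(score_options(scorer, it, **kw).scores) == it.correct_index)
        for it in items
    )
    return hits / len(items)


def train_mc(
    scorer: ToyScorer,
    items: list[MCItem],
    epochs: int = 30,
    lr: float = 0.5,
    seed: int = 0,
    use_log_softmax: bool = False,
) -> ToyScorer:
    """Gradient training of the toy scorer on mean multiple-choice loss.

    Full-batch analytic gradients through the summed-logit scores (the raw
    logit reading keeps the objective linear in the parameters before the
    softmax, so gradients are exact); the mean loss per epoch is appended
    to ``scorer.loss_curve``. ``epochs=0`` returns the scorer unchanged.
    """
    if not items:
        raise ValueError("no items to train on")
    if use_log_softmax:
        raise NotImplementedError(
            "analytic training is provided for the raw-logit reading; "
            "the log-softmax reading is evaluation-only"
        )
    rng = np.random.default_rng(seed)
    # precompute per-item per-option: token indices and copy counts
    pre = []
    for it in items:
        per_opt = []
        for opt in it.options:
            seq = list(it.context) + list(opt)
            ids = scorer.encode(seq)
            counts = scorer._counts_before(ids)
            pos = np.arange(len(it.context), len(seq))
            per_opt.append((ids[pos], counts[pos, ids[pos]].sum()))
        pre.append(per_opt)

    for _ in range(epochs):
        order = rng.permutation(len(items))  # order irrelevant full-batch; kept seeded
        db = np.zeros_like(scorer.bias)
        dc = 0.0
        total = 0.0
        for idx in order:
            it = items[idx]
            per_opt = pre[idx]
            s = np.array(
                [
                    scorer.bias[ids].sum() + scorer.copy_weight * csum
                    for ids, csum in per_opt
                ]
            )
            p = np.exp(log_softmax(s))
            total += -float(np.log(p[it.correct_index] + 1e-300))
            ds = p.copy()
            ds[it.correct_index] -= 1.0
            for j, (ids, csum) in enumerate(per_opt):
                np.add.at(db, ids, ds[j])
                dc += ds[j] * csum
        n = len(items)
        loss = total / n
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss: {loss}")
        scorer.bias -= lr * db / n
        scorer.copy_weight -= lr * dc / n
        scorer.loss_curve.append(loss)
    return scorer


def _standardize_columns(A: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=0)
    sd = np.sqrt((A**2).mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = A / sd
    Z[:, sd == 0] = 0.0
    return Z


def permutation_channel_test(
    M: np.ndarray,
    M_hat_base: np.ndarray,
    M_hat_ft: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    chunk: int = 32,
) -> ChannelComparison:
    """Permutation test of Δr = r(M, M̂_ft) − r(M, M̂_base) per cell.

    The null permutes the word order of the measured responses; each draw
    applies the same permutation to both correlations, so word-level
    structure shared by the two models cancels. Two-sided add-one p-values;
    cells with p < alpha are labeled by the sign of the observed Δr.
    """
    if not (M.shape == M_hat_base.shape == M_hat_ft.shape):
        raise ValueError("response and prediction tensors must share a shape")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    n_words, n_channels, n_timebins = M.shape
    zM = _standardize_columns(M.reshape(n_words, -1))
    zB = _standardize_columns(M_hat_base.reshape(n_words, -1))
    zF = _standardize_columns(M_hat_ft.reshape(n_words, -1))
    zD = zF - zB  # Δr = mean_w zM * zD
    observed = (zM * zD).mean(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(zM.shape[1], dtype=np.int64)
    done = 0
    abs_obs = np.abs(observed)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n_words) for _ in range(b)])
        # (b, n_words, cells) gather is the memory bound; chunked
        null = np.abs(np.einsum("bwc,wc->bc", zM[perms], zD) / n_words)
        exceed += (null >= abs_obs - 1e-15).sum(axis=0)
        done += b
    p = (1 + exceed) / (n_perm + 1)
    labels = np.full(zM.shape[1], "ns", dtype=object)
    sig = p < alpha
    labels[sig & (observed > 0)] = "better"
    labels[sig & (observed < 0)] = "worse"
    shape = (n_channels, n_timebins)
    return ChannelComparison(
        delta_r=observed.reshape(shape),
        p_values=p.reshape(shape),
        labels=labels.reshape(shape),
        n_perm=n_perm,
        alpha=alpha,
    )


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up; returns (reject mask, adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def category_improvement(
    word_mse_base: np.ndarray,
    word_mse_ft: np.ndarray,
    events: list[WordEvent],
    category: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timebin comparison of in- vs out-of-category MSE improvement.

    ``word_mse_*`` are (n_words, n_timebins) matrices (1-D vectors are
    treated as a single bin). The improvement ΔMSE_w = MSE_base − MSE_ft is
    positive where the fine-tuned model predicts better; per timebin a
    two-sample Student t-test compares in-category vs out-of-category
    words, and Benjamini-Hochberg correction runs across timebins. Bins
    whose MSE is undefined (no significant channel) are excluded.
    """
    base = np.atleast_2d(np.asarray(word_mse_base, dtype=float).T).T
    ft = np.atleast_2d(np.asarray(word_mse_ft, dtype=float).T).T
    if base.shape != ft.shape or base.shape[0] != len(events):
        raise ValueError("MSE matrices must align with each other and events")
    in_cat = np.array([category in e.category_flags for e in events])
    if in_cat.sum() < 2 or (~in_cat).sum() < 2:
        raise ValueError(
            f"category {category!r} needs >= 2 words inside and outside"
        )
    delta = base - ft
    rows = []
    for t in range(delta.shape[1]):
        d = delta[:, t]
        if np.any(np.isnan(d)):
            rows.append(
                {"timebin": t, "mean_in": np.nan, "mean_out": np.nan,
                 "se_in": np.nan, "se_out": np.nan, "t": np.nan, "p": np.nan}
            )
            continue
        din, dout = d[in_cat], d[~in_cat]
        tstat, p = stats.ttest_ind(din, dout)
        rows.append(
            {
                "timebin": t,
                "mean_in": din.mean(),
                "mean_out": dout.mean(),
                "se_in": stats.sem(din),
                "se_out": stats.sem(dout),
                "t": tstat,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    valid = df["p"].notna()
    df["p_adj"] = np.nan
    df["significant"] = False
    if valid.any():
        reject, p_adj = bh_fdr(df.loc[valid, "p"].to_numpy(), alpha=alpha)
        df.loc[valid, "p_adj"] = p_adj
        df.loc[valid, "significant"] = reject
    return df


def lm_loss_control(
    scorer_base: ToyScorer,
    scorer_ft: ToyScorer,
    text_stream,
    folds: int = 3,
    epochs: int = 50,
    lr: float = 1.0,
) -> pd.DataFrame:
    """Contiguous k-fold language-modeling control.

    Per fold, a clone of each scorer is fine-tuned with the LM objective on
    the training segments and evaluated by mean next-token loss on the held
    -out segment; the final row gives average losses and their difference
    (fine-tuned minus base). Similar averages indicate the two scorers have
    not diverged in plain language-modeling ability.
    """
    stream = list(text_stream)
    if len(stream) < folds:
        raise ValueError("stream shorter than the number of folds")
    pieces = np.array_split(np.arange(len(stream)), folds)
    rows = []
    for fi, test_idx in enumerate(pieces):
        train = [stream[i] for i in np.setdiff1d(np.arange(len(stream)), test_idx)]
        test = [stream[i] for i in test_idx]
        lb = scorer_base.clone().train_lm(train, epochs=epochs, lr=lr)
        lf = scorer_ft.clone().train_lm(train, epochs=epochs, lr=lr)
        rows.append(
            {"fold": fi, "loss_base": lb.lm_loss(test), "loss_ft": lf.lm_loss(test)}
        )
    df = pd.DataFrame(rows)
    avg = {
        "fold": "mean",
        "loss_base": df["loss_base"].mean(),
        "loss_ft": df["loss_ft"].mean(),
    }
    df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    df["difference"] = df["loss_ft"] - df["loss_base"]
    return df
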