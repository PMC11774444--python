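"""Time-resolved ridge encoding of responses from embeddings.

The encoder maps per-word embeddings L (n_words x embed_dim) to per-word
response tensors M (n_words x n_channels x n_timebins) with one ridge model
per timebin (all channels as joint targets), 10-fold contiguous
cross-validation over words — contiguous because stimulus-locked responses
are temporally autocorrelated, so shuffled folds would leak — and nested
contiguous cross-validation inside each training split to pick the
regularization strength. Held-out predictions from all folds are
concatenated back into word order, and prediction quality is summarized as
a per-channel/per-timebin Pearson correlation map across words.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoldSplit",
    "RidgeModel",
    "EncodingResult",
    "contiguous_kfold",
    "fit_ridge",
    "nested_select_lambda",
    "run_encoding",
    "select_best_layer",
    "correlation_map",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    test_start: int
    test_stop: int  # exclusive
    n_total: int

    @property
    def test_ids(self) -> np.ndarray:
        return np.arange(self.test_start, self.test_stop)

    @property
    def train_ids(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(0, self.test_start), np.arange(self.test_stop, self.n_total)]
        )


@dataclass
class RidgeModel:
    """Centered ridge solution: W minimizes ||Yc - Xc W||^2 + lam ||W||^2,
    the bias absorbs the training means (unpenalized)."""

    weights: np.ndarray  # embed_dim x n_targets
    bias: np.ndarray  # (n_targets,)
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


@dataclass
class EncodingResult:
    predicted: np.ndarray  # n_words x n_channels x n_timebins
    correlations: np.ndarray  # n_channels x n_timebins
    chosen_lambdas: np.ndarray  # n_folds x n_timebins
    layer_index: int = 0
    #: per-fold models are not retained by default (memory); mean r is cheap
    mean_r: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_r = float(np.nanmean(self.correlations))


def contiguous_kfold(n_words: int, k: int) -> list[FoldSplit]:
    """k contiguous, disjoint, exhaustive test ranges; sizes differ by at
    most one, earlier folds take the remainder."""
    if k < 2 or k > n_words:
        raise ValueError(f"need 2 <= k <= n_words, got k={k}, n_words={n_words}")
    base, rem = divmod(n_words, k)
    splits = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        splits.append(FoldSplit(i, start, start + size, n_words))
        start += size
    return splits


def _check_finite(name: str, a: np.ndarray) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")


def fit_ridge(X: np.ndarray, Y: np.ndarray, lam: float,
              allow_singular: bool = False) -> RidgeModel:
    """Ridge with unpenalized bias via the centering convention.

    With lam=0 a rank-deficient design raises unless ``allow_singular``
    (then the minimum-norm pseudo-inverse solution is returned).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0] or X.shape[0] < 2:
        raise ValueError("X and Y must share >= 2 rows")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    _check_finite("X", X)
    _check_finite("Y", Y)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if lam == 0:
        tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
        if np.any(s <= tol):
            if not allow_singular:
                raise np.linalg.LinAlgError(
                    "rank-deficient design with lambda=0; pass "
                    "allow_singular=True for the pseudo-inverse solution"
                )
            keep = s > tol
            U, s, Vt = U[:, keep], s[keep], Vt[keep]
        d = 1.0 / s
    else:
        d = s / (s**2 + lam)
    W = Vt.T @ (d[:, None] * (U.T @ Yc))
    b = y_mean - x_mean @ W
    return RidgeModel(weights=W, bias=b, lam=float(lam))


def _pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (n x m) matrices; columns with zero
    variance in either input yield NaN (undefined, excluded from averages)."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt((A**2).sum(axis=0))
    sb = np.sqrt((B**2).sum(axis=0))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return r


def correlation_map(M: np.ndarray, M_hat: np.ndarray) -> np.ndarray:
    """Per-channel/per-timebin Pearson r across words (n_channels x n_timebins)."""
    if M.shape != M_hat.shape:
        raise ValueError(f"shape mismatch {M.shape} vs {M_hat.shape}")
    n_words = M.shape[0]
    flat = _pearson_columns(M.reshape(n_words, -1), M_hat.reshape(n_words, -1))
    return flat.reshape(M.shape[1], M.shape[2])


def _grid_predictions(X_tr, Y_tr, X_va, lambdas):
    """Held-out predictions for every lambda from one SVD of the centered
    training design. Returns array (n_lambda, n_val, n_targets)."""
    x_mean = X_tr.mean(axis=0)
    y_mean = Y_tr.mean(axis=0)
    Xc = X_tr - x_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    UtY = U.T @ (Y_tr - y_mean)
    Xv = (X_va - x_mean) @ Vt.T  # n_val x rank
    preds = np.empty((len(lambdas), X_va.shape[0], Y_tr.shape[1]))
    for i, lam in enumerate(lambdas):
        d = s / (s**2 + lam) if lam > 0 else np.where(s > 0, 1.0 / s, 0.0)
        preds[i] = (Xv * d) @ UtY + y_mean
    return preds


def nested_select_lambda(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    inner_k: int = 5,
) -> float:
    """Grid value maximizing mean inner-fold held-out Pearson correlation
    (averaged over targets); inner folds are contiguous; ties break to the
    smallest lambda."""
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    if Y_train.ndim == 1:
        Y_train = Y_train[:, None]
    lambdas = list(lambda_grid)
    if not lambdas or any(l < 0 for l in lambdas):
        raise ValueError("lambda grid must be non-empty with values >= 0")
    if len(lambdas) == 1:
        return float(lambdas[0])
    if X_train.shape[0] < inner_k:
        raise ValueError("fewer training rows than inner folds")
    scores = _inner_cv_scores(X_train, Y_train, lambdas, inner_k)
    mean_scores = np.nanmean(scores, axis=(1, 2))  # over folds, targets
    best = min(
        range(len(lambdas)),
        key=lambda i: (-mean_scores[i], lambdas[i]),
    )
    return float(lambdas[best])


def _inner_cv_scores(X, Y, lambdas, inner_k):
    """r scores, shape (n_lambda, inner_k, n_targets)."""
    folds = contiguous_kfold(X.shape[0], inner_k)
    out = np.empty((len(lambdas), inner_k, Y.shape[1]))
    for f in folds:
        tr, va = f.train_ids, f.test_ids
        preds = _grid_predictions(X[tr], Y[tr], X[va], lambdas)
        for i in range(len(lambdas)):
            out[i, f.fold_index] = _pearson_columns(Y[va], preds[i])
    return out


def run_encoding(
    L: np.ndarray,
    M: np.ndarray,
    k: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    inner_k: int = 5,
    per_channel_lambda: bool = False,
    layer_index: int = 0,
) -> EncodingResult:
    """Contiguous k-fold encoding with per-fold, per-timebin nested lambda.

    One ridge model per timebin with all channels as joint targets; a single
    lambda per fold per timebin is shared across channels by default
    (``per_channel_lambda`` selects lambdas channel-wise instead). Test
    predictions are concatenated in word order; the correlation map is
    computed across words between actual and concatenated predictions.
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    _check_finite("embeddings", L)
    _check_finite("responses", M)
    if L.shape[0] != M.shape[0]:
        raise ValueError("embedding and response word counts differ")
    n_words, n_channels, n_timebins = M.shape
    lambdas = list(lambda_grid)
    if not lambdas:
        raise ValueError("empty lambda grid")

    predicted = np.empty_like(M)
    chosen = np.empty((k, n_timebins))
    for f in contiguous_kfold(n_words, k):
        tr, te = f.train_ids, f.test_ids
        X_tr, X_te = L[tr], L[te]
        # inner-CV scores for all timebins at once: targets stacked per bin
        Y_tr_all = M[tr].reshape(len(tr), -1)  # channels*timebins, bin-major last
        scores = _inner_cv_scores(X_tr, Y_tr_all, lambdas, inner_k)
        # scores targets are (channel, timebin) flattened C-order
        scores = scores.reshape(len(lambdas), inner_k, n_channels, n_timebins)
        for t in range(n_timebins):
            Y_tr = M[tr][:, :, t]
            if per_channel_lambda:
                per_ch = np.nanmean(scores[:, :, :, t], axis=1)  # lam x chan
                lam_idx = _argmax_smallest(per_ch, lambdas)
                model_preds = np.empty((len(te), n_channels))
                for li in np.unique(lam_idx):
                    cols = np.where(lam_idx == li)[0]
                    m = fit_ridge(X_tr, Y_tr[:, cols], lambdas[li])
                    model_preds[:, cols] = m.predict(X_te)
                predicted[te, :, t] = model_preds
                chosen[f.fold_index, t] = np.nan  # per-channel: no single value
            else:
                mean_s = np.nanmean(scores[:, :, :, t], axis=(1, 2))
                best = min(
                    range(len(lambdas)),
                    key=lambda i: (-mean_s[i], lambdas[i]),
                )
                lam = lambdas[best]
                model = fit_ridge(X_tr, Y_tr, lam)
                predicted[te, :, t] = model.predict(X_te)
                chosen[f.fold_index, t] = lam
    corr = correlation_map(M, predicted)
    return EncodingResult(
        predicted=predicted,
        correlations=corr,
        chosen_lambdas=chosen,
        layer_index=layer_index,
    )


def _argmax_smallest(scores: np.ndarray, lambdas) -> np.ndarray:
    """Per-column argmax over axis 0 with ties broken to smallest lambda."""
    order = np.argsort(np.asarray(lambdas), kind="stable")
    s = scores[order]
    best = np.nanargmax(s, axis=0)
    return order[best]


def select_best_layer(results_by_layer: dict) -> int:
    """Layer maximizing mean correlation over all channels and timebins;
    ties break to the lowest layer index."""
    if not results_by_layer:
        raise ValueError("no layers to select from")
    return min(
        results_by_layer,
        key=lambda k: (-float(np.nanmean(results_by_layer[k].correlations)), k),
    )
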