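"""Per-target regularized linear encoding models.

The estimator follows the statsmodels idiom: :class:`RidgeEncodingModel`
holds the design and the response, ``fit()`` performs per-target ridge
regression with cross-validated regularization and returns a
:class:`RidgeEncodingResults` carrying weights, chosen alphas, CV
diagnostics, prediction and scoring methods, and a ``summary()`` table.

Cross-validation respects temporal autocorrelation: rows are grouped into
contiguous time chunks and whole chunks are assigned to folds, never
individual (shuffled) rows.  Model selection maximizes the mean held-out
Pearson correlation per target; the weights are then refit on all training
rows at the selected alpha.  Both design columns and response columns are
z-scored with training statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "ScoreVector",
    "RidgeEncodingModel",
    "RidgeEncodingResults",
    "score_predictions",
    "relative_improvement",
    "pearson_columns",
    "DEFAULT_ALPHAS",
]

#: log-spaced regularization grid, the standard encoding-model range
DEFAULT_ALPHAS: np.ndarray = np.logspace(0, 4, 10)


@dataclass
class ScoreVector:
    """Held-out prediction correlations, one per target.

    ``valid`` is False where the correlation was undefined (constant
    prediction or constant observation); such entries carry the sentinel 0
    so downstream map arithmetic stays total.
    """

    r: np.ndarray
    n_test: int
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.valid is None:
            self.valid = np.ones_like(self.r, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.r.shape != self.valid.shape:
            raise ValueError("r and valid must have the same shape")
        if np.any(np.abs(self.r[self.valid]) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    def mean(self, mask: np.ndarray | None = None) -> float:
        r = self.r if mask is None else self.r[mask]
        return float(np.mean(r))


def pearson_columns(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r between two (T, V) arrays.

    Returns (r, valid); degenerate columns get r = 0, valid = False.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.sqrt((Ac**2).sum(axis=0))
    nb = np.sqrt((Bc**2).sum(axis=0))
    valid = (na > 0) & (nb > 0)
    denom = np.where(valid, na * nb, 1.0)
    r = (Ac * Bc).sum(axis=0) / denom
    r[~valid] = 0.0
    return np.clip(r, -1.0, 1.0), valid


def _zscore_fit(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _design_array(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def chunk_folds(n_rows: int, chunk_len: int = 20, n_folds: int = 5) -> np.ndarray:
    """Fold label per row: contiguous chunks dealt round-robin to folds."""
    chunks = np.arange(n_rows) // chunk_len
    return (chunks % n_folds).astype(int)


def _svd_ridge(Xtr: np.ndarray, Ytr: np.ndarray, alphas: np.ndarray):
    """Ridge coefficient stacks for every alpha via one thin SVD.

    Returns an array (n_alpha, F, V) of coefficients for centered/scaled
    inputs (no intercept).
    """
    U, s, Vt = np.linalg.svd(Xtr, full_matrices=False)
    UtY = U.T @ Ytr  # (k, V)
    coefs = np.empty((len(alphas), Xtr.shape[1], Ytr.shape[1]))
    for i, a in enumerate(alphas):
        d = s / (s**2 + a)
        coefs[i] = Vt.T @ (d[:, None] * UtY)
    return coefs


class RidgeEncodingModel:
    """Voxel/electrode-wise ridge encoding model.

    Parameters
    ----------
    Y : (T, V) array
        Response matrix, one column per target (voxel or electrode).
    X : FeatureMatrix or (T, F) array
        Design matrix on the same time grid.
    alphas : sequence of positive floats
        Regularization grid searched per target.
    chunk_len, n_folds : int
        Contiguous-chunk cross-validation layout.
    folds : (T,) int array, optional
        Explicit fold label per row, overriding the chunk layout (rows with
        the same label are held out together).

    Examples
    --------
    >>> model = RidgeEncodingModel(Y, X)
    >>> res = model.fit()
    >>> res.score(X_test, Y_test).r
    """

    def __init__(self, Y, X, alphas: Sequence[float] | None = None,
                 chunk_len: int = 20, n_folds: int = 5,
                 folds: np.ndarray | None = None):
        self.X = X
        self.Y = np.asarray(Y, dtype=float)
        Xv = _design_array(X)
        if Xv.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must share the time axis")
        if not (np.isfinite(Xv).all() and np.isfinite(self.Y).all()):
            raise ValueError("NaN/Inf in inputs")
        self.alphas = np.asarray(
            DEFAULT_ALPHAS if alphas is None else alphas, dtype=float
        )
        if np.any(self.alphas <= 0):
            raise ValueError("alphas must be positive")
        if folds is not None:
            folds = np.asarray(folds, dtype=int)
            if folds.shape != (Xv.shape[0],):
                raise ValueError("folds must label every row")
            self.folds = folds
        else:
            self.folds = chunk_folds(Xv.shape[0], chunk_len, n_folds)
        if Xv.shape[0] <= Xv.shape[1]:
            import warnings

            warnings.warn(
                f"T={Xv.shape[0]} <= F={Xv.shape[1]}: ridge fit is "
                "underdetermined; interpret weights with care"
            )

    def fit(self, seed: int = 0) -> "RidgeEncodingResults":
        """Select alpha per target by chunked CV, refit on all rows."""
        Xv = _design_array(self.X)
        Y = self.Y
        T, F = Xv.shape
        V = Y.shape[1]
        n_alpha = len(self.alphas)
        cv_r = np.zeros((n_alpha, V))
        cv_n = np.zeros((n_alpha, V))
        for f in np.unique(self.folds):
            tr = self.folds != f
            te = ~tr
            if tr.sum() < 2 or te.sum() < 3:
                continue
            xm, xs = _zscore_fit(Xv[tr])
            ym, ys = _zscore_fit(Y[tr])
            Xtr = (Xv[tr] - xm) / xs
            Ytr = (Y[tr] - ym) / ys
            Xte = (Xv[te] - xm) / xs
            coefs = _svd_ridge(Xtr, Ytr, self.alphas)
            for i in range(n_alpha):
                pred = Xte @ coefs[i]
                r, valid = pearson_columns(pred, Y[te])
                cv_r[i] += np.where(valid, r, 0.0)
                cv_n[i] += valid.astype(float)
        with np.errstate(invalid="ignore"):
            mean_cv = cv_r / np.maximum(cv_n, 1.0)
        best_idx = np.argmax(mean_cv, axis=0)

        # refit on all rows at each target's selected alpha
        xm, xs = _zscore_fit(Xv)
        ym, ys = _zscore_fit(Y)
        Xz = (Xv - xm) / xs
        Yz = (Y - ym) / ys
        coefs_all = _svd_ridge(Xz, Yz, self.alphas)
        weights = np.empty((F, V))
        for i in range(n_alpha):
            sel = best_idx == i
            if sel.any():
                weights[:, sel] = coefs_all[i][:, sel]
        labels = self.X.labels if isinstance(self.X, FeatureMatrix) else None
        return RidgeEncodingResults(
            weights=weights,
            alpha_per_target=self.alphas[best_idx],
            cv_corr=mean_cv[best_idx, np.arange(V)],
            x_mean=xm, x_std=xs, y_mean=ym, y_std=ys,
            labels=labels, alphas=self.alphas, model=self,
        )


@dataclass
class RidgeEncodingResults:
    """Fitted per-target encoding model.

    ``weights`` are on the standardized (z-scored X and Y) scale — the scale
    on which they are read as selectivity maps.  ``predict`` returns
    responses in original Y units.
    """

    weights: np.ndarray  # (F, V)
    alpha_per_target: np.ndarray  # (V,)
    cv_corr: np.ndarray  # (V,) mean held-out r at the chosen alpha
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    labels: list[tuple] | None = None
    alphas: np.ndarray | None = None
    model: RidgeEncodingModel | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite weights")
        if np.any(self.alpha_per_target <= 0):
            raise ValueError("alphas must be positive")

    @property
    def intercept(self) -> np.ndarray:
        """Per-target intercept in original response units."""
        return self.y_mean

    @property
    def n_targets(self) -> int:
        return self.weights.shape[1]

    def predict(self, X) -> np.ndarray:
        Xv = _design_array(X)
        Xz = (Xv - self.x_mean) / self.x_std
        return (Xz @ self.weights) * self.y_std + self.y_mean

    def score(self, X_test, Y_test) -> ScoreVector:
        return score_predictions(self, X_test, Y_test)

    def question_weights(self, combine: str = "mean") -> tuple[np.ndarray, list[str]]:
        """Collapse FIR-delay copies: one weight per (question, target).

        combine="mean" averages a question's delay weights; "sum" sums them
        (the question's total standardized effect across the FIR span).
        """
        if self.labels is None:
            raise ValueError("results carry no column labels")
        qids: list[str] = []
        for lab in self.labels:
            if lab[0] not in qids:
                qids.append(lab[0])
        out = np.zeros((len(qids), self.weights.shape[1]))
        for i, q in enumerate(qids):
            rows = [j for j, lab in enumerate(self.labels) if lab[0] == q]
            block = self.weights[rows]
            out[i] = block.mean(axis=0) if combine == "mean" else block.sum(axis=0)
        return out, qids

    def summary(self, top: int = 5) -> str:
        """Text summary: fit dimensions, alpha usage and CV performance."""
        lines = [
            "Ridge encoding model results",
            "=" * 32,
            f"targets:            {self.n_targets}",
            f"design columns:     {self.weights.shape[0]}",
            f"mean CV r:          {np.nanmean(self.cv_corr):.4f}",
            f"median CV r:        {np.nanmedian(self.cv_corr):.4f}",
            f"alpha range chosen: [{self.alpha_per_target.min():.3g}, "
            f"{self.alpha_per_target.max():.3g}]",
        ]
        if self.labels is not None:
            qw, qids = self.question_weights()
            strength = np.abs(qw).mean(axis=1)
            order = np.argsort(-strength)[:top]
            lines.append(f"top questions by mean |weight| across targets:")
            for i in order:
                lines.append(f"  {qids[i]:<8s} {strength[i]:.4f}")
        return "\n".join(lines)


def score_predictions(results: RidgeEncodingResults, X_test, Y_test) -> ScoreVector:
    """Held-out Pearson correlation per target.

    Constant predictions or observations get the sentinel 0 with
    ``valid=False``.
    """
    Y_test = np.asarray(Y_test, dtype=float)
    pred = results.predict(X_test)
    if pred.shape != Y_test.shape:
        raise ValueError(f"prediction shape {pred.shape} != Y_test {Y_test.shape}")
    r, valid = pearson_columns(pred, Y_test)
    return ScoreVector(r=r, n_test=Y_test.shape[0], valid=valid)


def relative_improvement(r_a: ScoreVector | np.ndarray,
                         r_b: ScoreVector | np.ndarray,
                         mask: np.ndarray | None = None) -> float:
    """Percent improvement of mean score a over mean score b.

    ``100 * (mean(r_a) - mean(r_b)) / mean(r_b)`` over masked targets.  The
    baseline mean must be positive for the percentage to be meaningful.
    """
    a = r_a.r if isinstance(r_a, ScoreVector) else np.asarray(r_a, dtype=float)
    b = r_b.r if isinstance(r_b, ScoreVector) else np.asarray(r_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must cover the same targets")
    if mask is not None:
        a, b = a[mask], b[mask]
    mb = float(np.mean(b))
    if mb <= 0:
        raise ValueError(
            "baseline mean correlation must be positive; restrict the mask to "
            "well-predicted targets before comparing models"
        )
    return 100.0 * (float(np.mean(a)) - mb) / mb
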