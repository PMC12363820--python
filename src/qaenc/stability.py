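"""Stability selection of questions by resampled sparse regression.

To compress a large question bank to a compact, stable subset, an
L1-regularized (lasso) regression of each target's response on the design is
fit on many chunk-respecting subsamples of the time axis across a grid of
penalties.  A question's *selection frequency* is the fraction of subsamples
in which it receives nonzero weight at the most favorable penalty; the
compact set keeps the questions with the highest frequencies.

All FIR-delay copies of one question count as a single selection unit: the
question is the scientific object, not the delay.  Following the
Meinshausen–Bühlmann prescription, a penalty only contributes to selection
frequencies while the fit stays sparse (at most ``max_active`` question
groups active); without this cap the smallest penalties select everything
and frequencies saturate at 1 for pure-noise columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import lasso_path

from .features import FeatureMatrix

__all__ = ["SelectionResult", "stability_select", "compact_design"]


@dataclass
class SelectionResult:
    """Outcome of stability selection over a question bank."""

    frequency: dict[str, float]  # qid -> selection frequency in [0, 1]
    selected_qids: list[str]  # ordered by (frequency, mean |w|, qid)
    threshold: float
    b: int
    frac: float
    seed: int
    lambdas: np.ndarray  # relative penalty grid (fractions of lambda_max)
    mean_abs_weight: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "frequency": self.frequency,
            "selected_qids": self.selected_qids,
            "threshold": self.threshold,
            "b": self.b,
            "frac": self.frac,
            "seed": self.seed,
            "lambdas": list(map(float, self.lambdas)),
            "mean_abs_weight": self.mean_abs_weight,
        }
        Path(path).write_text(json.dumps(obj, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        obj["lambdas"] = np.asarray(obj["lambdas"])
        return cls(**obj)


def _group_columns(X: FeatureMatrix) -> tuple[list[str], list[list[int]]]:
    qids = X.qids
    return qids, [X.columns_for(q) for q in qids]


def _chunk_half_subsamples(n_rows: int, chunk_len: int, frac: float, B: int,
                           rng: np.random.Generator) -> list[np.ndarray]:
    """Complementary contiguous-chunk subsamples of about frac*T rows each."""
    chunk_ids = np.arange(n_rows) // chunk_len
    uniq = np.unique(chunk_ids)
    subs: list[np.ndarray] = []
    while len(subs) < B:
        perm = rng.permutation(uniq)
        k = max(1, int(round(frac * len(uniq))))
        first, second = perm[:k], perm[k:]
        subs.append(np.flatnonzero(np.isin(chunk_ids, first)))
        if len(subs) < B and len(second):
            subs.append(np.flatnonzero(np.isin(chunk_ids, second)))
    return subs[:B]


def stability_select(X: FeatureMatrix, Y: np.ndarray, B: int = 100,
                     frac: float = 0.5,
                     lambdas: Sequence[float] | None = None,
                     target_k: int | None = None,
                     threshold: float | None = None,
                     seed: int = 0, chunk_len: int = 20,
                     targets: Sequence[int] | None = None,
                     max_active: int | None = None) -> SelectionResult:
    """Select a stable question subset by resampled lasso.

    Parameters
    ----------
    X : FeatureMatrix
        Design with (qid, delay) labels; a question's delay columns form one
        selection group.
    Y : (T, V) array
        Targets; selection frequencies are computed per target and pooled by
        their mean over ``targets`` (default: all).
    B : int
        Number of subsamples (complementary contiguous-chunk halves).
    frac : float
        Subsample fraction of the time axis, 0 < frac < 1.
    lambdas : sequence of floats, optional
        Relative penalty grid as fractions of each fit's own lambda_max
        (default log-spaced 0.05 … 1, 12 points).
    target_k : int, optional
        Keep exactly k questions: the threshold becomes the k-th largest
        frequency, ties broken by higher mean |weight| then qid order.
    threshold : float, optional
        Keep questions with frequency >= threshold (default 0.5 when
        target_k is not given).
    max_active : int, optional
        Per-fit sparsity cap: penalties whose fit activates more than this
        many question groups do not count toward frequencies.  Default
        ``max(target_k, ceil(Q/4))``.

    Returns
    -------
    SelectionResult
        Reproducible for fixed seed.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    if B < 2:
        raise ValueError("B must be >= 2")
    T, V = np.asarray(Y).shape
    Y = np.asarray(Y, dtype=float)
    qids, groups = _group_columns(X)
    Q = len(qids)
    if target_k is not None and target_k > Q:
        raise ValueError("target_k exceeds the number of questions")
    if lambdas is None:
        lambdas = np.logspace(np.log10(0.05), 0.0, 12)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]  # descending
    if max_active is None:
        max_active = max(target_k or 0, int(np.ceil(Q / 4)))
    tgt_idx = np.arange(V) if targets is None else np.asarray(targets, dtype=int)

    zero_cols = np.flatnonzero(X.values.std(axis=0) == 0)
    if zero_cols.size:
        warnings.warn(
            f"{zero_cols.size} all-constant design column(s); the affected "
            "questions can never be selected"
        )

    rng = np.random.default_rng(seed)
    subs = _chunk_half_subsamples(T, chunk_len, frac, B, rng)

    n_lam = len(lambdas)
    # selected[v_pos, q, lam] counts subsamples; abs-weight accumulators for ties
    sel_count = np.zeros((len(tgt_idx), Q, n_lam))
    absw_sum = np.zeros(Q)
    absw_n = 0
    Xv = X.values
    for rows in subs:
        Xs = Xv[rows]
        mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (Xs - mu) / sd
        n = len(rows)
        for vi, v in enumerate(tgt_idx):
            y = Y[rows, v]
            ysd = y.std()
            if ysd == 0:
                continue
            yz = (y - y.mean()) / ysd
            lam_max = np.max(np.abs(Xs.T @ yz)) / n
            if lam_max == 0:
                continue
            alphas = lambdas * lam_max
            _, coefs, _ = lasso_path(Xs, yz, alphas=alphas)
            # lasso_path returns alphas in the order given (descending)
            for li in range(n_lam):
                w = coefs[:, li]
                active = [
                    qi for qi, cols in enumerate(groups)
                    if np.any(w[cols] != 0)
                ]
                if 0 < len(active) <= max_active:
                    sel_count[vi, active, li] += 1
            for qi, cols in enumerate(groups):
                absw_sum[qi] += np.abs(coefs[cols]).mean()
            absw_n += 1

    freq_per_target = sel_count.max(axis=2) / B  # (targets, Q)
    freq = freq_per_target.mean(axis=0)  # (Q,)
    mean_absw = absw_sum / max(absw_n, 1)

    order = sorted(
        range(Q), key=lambda qi: (-freq[qi], -mean_absw[qi], qids[qi])
    )
    if target_k is not None:
        chosen = order[:target_k]
        thr = float(freq[chosen[-1]]) if chosen else 1.0
    else:
        thr = 0.5 if threshold is None else float(threshold)
        chosen = [qi for qi in order if freq[qi] >= thr]
    return SelectionResult(
        frequency={qids[qi]: float(freq[qi]) for qi in range(Q)},
        selected_qids=[qids[qi] for qi in chosen],
        threshold=thr,
        b=B, frac=frac, seed=seed,
        lambdas=lambdas,
        mean_abs_weight={qids[qi]: float(mean_absw[qi]) for qi in range(Q)},
    )


def compact_design(X: FeatureMatrix, sel: SelectionResult) -> FeatureMatrix:
    """Restrict a design to the selected questions (all their delay columns).

    Original column order is preserved.
    """
    unknown = [q for q in sel.selected_qids if q not in X.qids]
    if unknown:
        raise KeyError(f"selected qids not in design: {unknown}")
    if not sel.selected_qids:
        raise ValueError("empty selection: no columns to keep")
    keep = [j for j, lab in enumerate(X.labels) if lab[0] in set(sel.selected_qids)]
    return FeatureMatrix(X.values[:, keep], [X.labels[j] for j in keep], tr=X.tr)
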