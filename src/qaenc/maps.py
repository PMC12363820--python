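"""Quantitative evaluation of selectivity maps.

A fitted encoding model yields, for each question, one weight per voxel or
electrode — a *selectivity map* read as "where does this theory explain the
response".  This module quantifies such maps: masking to well-predicted
targets, correlating against reference maps (e.g. literature meta-analysis
maps), permutation tests on the mean map correlation, Benjamini–Hochberg
FDR across questions, inter-subject consistency through a shared template
space, and condition-average comparison against responses to probe stimuli
built to emphasize single questions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import ScoreVector

__all__ = [
    "SelectivityMap",
    "ConditionResponse",
    "top_fraction_mask",
    "map_correlation",
    "permutation_pvalue_mean",
    "make_map_permutation_null",
    "bh_fdr",
    "intersubject_consistency",
    "condition_average_response",
]


@dataclass
class SelectivityMap:
    """One question's per-target weight map plus the prediction score used
    for masking."""

    qid: str
    values: np.ndarray  # (V,)
    score: ScoreVector | None = None
    space: str = ""  # subject id or template tag

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.score is not None and self.score.r.shape != self.values.shape:
            raise ValueError("score and values must cover the same targets")
        if self.score is not None:
            if not np.isfinite(self.values[self.score.valid]).all():
                raise ValueError("non-finite map values at valid targets")


@dataclass
class ConditionResponse:
    """Average response to the stimulus segments tagged to one question."""

    qid: str
    mean_response: np.ndarray  # (V,)
    n_segments: int


def top_fraction_mask(score: ScoreVector | np.ndarray, fraction: float,
                      ) -> np.ndarray:
    """Indices of the best-predicted ``ceil(fraction*V)`` targets.

    Boundary ties break toward the lower index.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    r = score.r if isinstance(score, ScoreVector) else np.asarray(score, dtype=float)
    k = int(np.ceil(fraction * len(r)))
    order = np.argsort(-r, kind="stable")  # stable: ties keep index order
    return np.sort(order[:k])


def map_correlation(a: SelectivityMap | np.ndarray, b: np.ndarray,
                    mask: np.ndarray | None = None) -> float:
    """Pearson r between a selectivity map and a reference vector over a mask.

    A constant masked vector has undefined correlation; the sentinel 0 is
    returned with a warning.
    """
    av = a.values if isinstance(a, SelectivityMap) else np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("maps must have the same length (same space)")
    if mask is not None:
        av, bv = av[mask], bv[mask]
    if len(av) < 3:
        raise ValueError("need at least 3 targets to correlate maps")
    if av.std() == 0 or bv.std() == 0:
        warnings.warn("constant map under the mask; correlation undefined, "
                      "returning sentinel 0")
        return 0.0
    return float(np.corrcoef(av, bv)[0, 1])


def permutation_pvalue_mean(observed: np.ndarray,
                            null_generator: Callable[[np.random.Generator], np.ndarray],
                            n_perm: int = 10000, seed: int = 0) -> float:
    """One-sided permutation p-value for the mean of per-question correlations.

    ``null_generator(rng)`` returns one draw of the per-question correlation
    vector under the null.  The add-one rule gives
    ``p = (1 + #{null mean >= observed mean}) / (1 + n_perm)``, so the floor
    is ``1/(1+n_perm)``.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("empty observed correlation vector")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs_mean = observed.mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if null_generator(rng).mean() >= obs_mean:
            count += 1
    return (1 + count) / (1 + n_perm)


def make_map_permutation_null(weight_maps: np.ndarray, reference_maps: np.ndarray,
                              mask: np.ndarray | None = None,
                              ) -> Callable[[np.random.Generator], np.ndarray]:
    """Null generator permuting each reference map across targets.

    Permuting the reference rather than the weights preserves the weight
    maps' spatial statistics across questions.  Returns a callable usable
    with :func:`permutation_pvalue_mean`.
    """
    W = np.asarray(weight_maps, dtype=float)
    R = np.asarray(reference_maps, dtype=float)
    if W.shape != R.shape:
        raise ValueError("weight and reference stacks must align (Q, V)")
    if mask is not None:
        W, R = W[:, mask], R[:, mask]
    Wc = W - W.mean(axis=1, keepdims=True)
    wn = np.linalg.norm(Wc, axis=1)
    wn = np.where(wn > 0, wn, 1.0)

    def draw(rng: np.random.Generator) -> np.ndarray:
        out = np.empty(W.shape[0])
        for q in range(W.shape[0]):
            perm = rng.permutation(R.shape[1])
            rp = R[q, perm]
            rc = rp - rp.mean()
            rn = np.linalg.norm(rc)
            out[q] = 0.0 if rn == 0 else float(Wc[q] @ rc / (wn[q] * rn))
        return out

    return draw


def observed_map_correlations(weight_maps: np.ndarray, reference_maps: np.ndarray,
                              mask: np.ndarray | None = None) -> np.ndarray:
    """Per-question Pearson r between weight and reference map stacks."""
    W = np.asarray(weight_maps, dtype=float)
    R = np.asarray(reference_maps, dtype=float)
    if mask is not None:
        W, R = W[:, mask], R[:, mask]
    out = np.empty(W.shape[0])
    for q in range(W.shape[0]):
        out[q] = map_correlation(W[q], R[q])
    return out


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up: indices of rejected hypotheses.

    Rejects all hypotheses up to the largest i with sorted p(i) <= i*q/m
    (inclusive at the boundary).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([], dtype=int)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(ranked <= crit)
    if passing.size == 0:
        return np.array([], dtype=int)
    k = passing[-1] + 1
    return np.sort(order[:k])


def _apply_operator(op, values: np.ndarray) -> np.ndarray:
    """Apply an alignment operator: None (identity), matrix, or callable."""
    if op is None:
        return values
    if callable(op):
        return np.asarray(op(values), dtype=float)
    return np.asarray(op @ values, dtype=float)


def intersubject_consistency(
    maps_by_subject: Mapping[str, Mapping[str, np.ndarray]],
    to_template: Mapping[str, object] | None = None,
    from_template: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Leave-one-subject-out map consistency through a template space.

    For each (held-out subject, question): the other subjects' maps are
    projected to the template with their ``to_template`` operators, averaged,
    back-projected with the held-out subject's ``from_template`` operator and
    correlated with that subject's own map.  Operators default to identity
    (all subjects already in a shared space); they may be dense/sparse
    matrices or callables — this module never performs registration itself.

    Returns a DataFrame with columns subject, qid, r.
    """
    subjects = list(maps_by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    to_template = to_template or {}
    from_template = from_template or {}
    rows = []
    for held in subjects:
        own = maps_by_subject[held]
        for qid in own:
            others = []
            for s in subjects:
                if s == held:
                    continue
                if qid not in maps_by_subject[s]:
                    warnings.warn(f"qid {qid!r} missing for subject {s!r}; skipped")
                    continue
                others.append(
                    _apply_operator(to_template.get(s), maps_by_subject[s][qid])
                )
            if not others:
                continue
            template_mean = np.mean(others, axis=0)
            back = _apply_operator(from_template.get(held), template_mean)
            r = map_correlation(np.asarray(own[qid], dtype=float), back)
            rows.append({"subject": held, "qid": qid, "r": r})
    return pd.DataFrame(rows, columns=["subject", "qid", "r"])


def condition_average_response(Y: np.ndarray,
                               segments: Sequence[tuple[str, int, int]],
                               offset: int = 2) -> list[ConditionResponse]:
    """Mean response per question over its tagged stimulus segments.

    ``segments`` is a list of (qid, start_row, end_row) half-open row ranges
    on the response grid.  Rows are shifted by ``offset`` samples (default
    +2, about 4 s at TR = 2 s) before averaging to account for the
    hemodynamic lag, and clipped to the grid.
    """
    Y = np.asarray(Y, dtype=float)
    T = Y.shape[0]
    by_qid: dict[str, list[np.ndarray]] = {}
    counts: dict[str, int] = {}
    for qid, start, end in segments:
        if end <= start:
            raise ValueError(f"empty segment for qid {qid!r}: [{start}, {end})")
        if start < 0 or end > T:
            raise ValueError(f"segment [{start}, {end}) outside [0, {T})")
        lo, hi = min(start + offset, T), min(end + offset, T)
        if hi <= lo:
            raise ValueError(
                f"segment [{start}, {end}) falls off the grid after the "
                f"+{offset}-sample hemodynamic shift"
            )
        by_qid.setdefault(qid, []).append(Y[lo:hi])
        counts[qid] = counts.get(qid, 0) + 1
    return [
        ConditionResponse(qid, np.concatenate(rows, axis=0).mean(axis=0),
                          counts[qid])
        for qid, rows in by_qid.items()
    ]
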