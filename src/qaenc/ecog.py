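"""ECoG branch: multi-timescale features, lagged word-onset encoding models,
electrode selection, weight clustering, and fMRI↔ECoG map agreement.

ECoG high-gamma responses have far better temporal resolution than fMRI, so
the QA features are built at three contextual timescales — the single word,
1.5 s of context, and 3 s of context — and optionally concatenated with
low-level spectral features.  Per-electrode encoding models are then fit at
a grid of time lags relative to word onset (negative lags probe predictive
coding before the word).  Downstream analyses select well-predicted
electrodes, cluster their question-weight profiles, and compare electrode
maps against fMRI vertex maps interpolated to electrode positions on a
shared template surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.stats import ttest_rel

from .annotate import Annotator, AnnotationCache, annotate, make_windows
from .corpus import QuestionBank, Transcript
from .encoding import (RidgeEncodingModel, RidgeEncodingResults, ScoreVector,
                       pearson_columns)
from .maps import permutation_pvalue_mean, top_fraction_mask

__all__ = [
    "WordAlignedFeatures",
    "LaggedEncodingModel",
    "LaggedEncodingResults",
    "CrossModalResult",
    "DEFAULT_LAGS_MS",
    "TIMESCALES",
    "build_multiscale_features",
    "validate_electrode_table",
    "select_electrodes_min_performance",
    "cluster_electrode_weights",
    "interpolate_fmri_to_electrodes",
    "crossmodal_correlation_test",
]

#: contextual timescales (seconds of context; 0 = single word)
TIMESCALES: tuple[tuple[str, float], ...] = (
    ("word", 0.0), ("1.5s", 1.5), ("3.0s", 3.0),
)

#: lag grid relative to word onset, milliseconds
DEFAULT_LAGS_MS: tuple[int, ...] = tuple(range(-2000, 2001, 100))


@dataclass
class WordAlignedFeatures:
    """Word-aligned design: QA columns at three timescales plus spectral.

    Labels are (qid, timescale) for QA columns and ("spectral", band) for
    spectral columns; QA entries are binary.
    """

    values: np.ndarray  # (W, F)
    labels: list[tuple]
    onsets: np.ndarray  # (W,) word onsets in seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.values.shape[0] != self.onsets.shape[0]:
            raise ValueError("one onset per word row required")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per column required")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")
        qa = [j for j, lab in enumerate(self.labels) if lab[0] != "spectral"]
        if qa and not np.isin(self.values[:, qa], (0, 1)).all():
            raise ValueError("QA columns must be binary")

    @property
    def qa_columns(self) -> list[int]:
        return [j for j, lab in enumerate(self.labels) if lab[0] != "spectral"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_multiscale_features(t: Transcript, bank: QuestionBank,
                              annotator: Annotator,
                              spectral: np.ndarray | None = None,
                              cache: AnnotationCache | None = None,
                              ) -> WordAlignedFeatures:
    """QA annotations at the word / 1.5 s / 3 s timescales, concatenated.

    With a Q-question bank the QA block has exactly 3·Q columns (105 for a
    35-question bank).  A (W, S) spectral matrix, if given, is appended
    unchanged with ("spectral", band-index) labels.
    """
    if len(bank) < 1:
        raise ValueError("question bank is empty")
    blocks, labels = [], []
    for name, context in TIMESCALES:
        if context == 0.0:
            windows = make_windows(t, mode="ngram", n=1)
        else:
            windows = make_windows(t, mode="time_context", context=context)
        A = annotate(windows, bank, annotator, cache=cache)
        blocks.append(A.values.astype(float))
        labels.extend((q, name) for q in bank.qids)
    values = np.concatenate(blocks, axis=1)
    if spectral is not None:
        spectral = np.asarray(spectral, dtype=float)
        if spectral.shape[0] != len(t):
            raise ValueError(
                f"spectral matrix has {spectral.shape[0]} rows for "
                f"{len(t)} words"
            )
        values = np.concatenate([values, spectral], axis=1)
        labels.extend(("spectral", s) for s in range(spectral.shape[1]))
    return WordAlignedFeatures(values, labels, t.onsets)


class LaggedEncodingModel:
    """Per-lag ridge encoding of word-aligned responses.

    Parameters
    ----------
    responses : (W, L, E) array
        One response value per (word, lag, electrode) — e.g. the high-gamma
        envelope averaged in a window centered ``lags[l]`` ms from each word
        onset.  Band extraction itself is upstream preprocessing, consumed
        as input.
    features : WordAlignedFeatures or (W, F) array
    lags : sequence of ints, milliseconds relative to word onset.
    """

    def __init__(self, responses: np.ndarray, features, lags: Sequence[int],
                 alphas: Sequence[float] | None = None, chunk_len: int = 50,
                 n_folds: int = 5):
        self.responses = np.asarray(responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (words, lags, electrodes)")
        self.features = features
        fv = features.values if isinstance(features, WordAlignedFeatures) \
            else np.asarray(features, dtype=float)
        if fv.shape[0] != self.responses.shape[0]:
            raise ValueError("features and responses must share the word axis")
        self.lags = list(lags)
        if sorted(self.lags) != self.lags:
            raise ValueError("lags must be sorted")
        if len(self.lags) != self.responses.shape[1]:
            raise ValueError(
                f"{len(self.lags)} lags for {self.responses.shape[1]} "
                "response lag planes"
            )
        self.alphas = alphas
        self.chunk_len = chunk_len
        self.n_folds = n_folds

    def fit(self, seed: int = 0, test_frac: float = 0.25,
            ) -> "LaggedEncodingResults":
        """One cross-validated ridge fit per lag.

        The trailing ``test_frac`` of words is held out for scoring; the
        leading words are the training set with contiguous-chunk CV for the
        per-electrode alpha choice.
        """
        W = self.responses.shape[0]
        n_test = max(3, int(round(test_frac * W)))
        tr = slice(0, W - n_test)
        te = slice(W - n_test, W)
        fv = self.features.values if isinstance(self.features, WordAlignedFeatures) \
            else np.asarray(self.features, dtype=float)
        per_lag: list[RidgeEncodingResults] = []
        scores = np.empty((len(self.lags), self.responses.shape[2]))
        valid = np.empty_like(scores, dtype=bool)
        for li in range(len(self.lags)):
            Yl = self.responses[:, li, :]
            model = RidgeEncodingModel(
                Yl[tr], fv[tr], alphas=self.alphas,
                chunk_len=self.chunk_len, n_folds=self.n_folds,
            )
            res = model.fit(seed=seed)
            sv = res.score(fv[te], Yl[te])
            per_lag.append(res)
            scores[li] = sv.r
            valid[li] = sv.valid
        labels = self.features.labels if isinstance(self.features,
                                                    WordAlignedFeatures) else None
        return LaggedEncodingResults(
            lags=list(self.lags), results_per_lag=per_lag,
            scores=scores, scores_valid=valid, labels=labels, n_test=n_test,
        )


@dataclass
class LaggedEncodingResults:
    """Per-lag fits with per-(lag, electrode) held-out correlations."""

    lags: list[int]
    results_per_lag: list[RidgeEncodingResults]
    scores: np.ndarray  # (L, E)
    scores_valid: np.ndarray  # (L, E) bool
    labels: list[tuple] | None = None
    n_test: int = 0

    def score_at(self, lag: int) -> ScoreVector:
        li = self.lags.index(lag)
        return ScoreVector(self.scores[li], self.n_test, self.scores_valid[li])

    def best_lag(self, electrodes: np.ndarray | None = None) -> int:
        """Lag maximizing the mean held-out score over ``electrodes``."""
        s = self.scores if electrodes is None else self.scores[:, electrodes]
        return self.lags[int(np.argmax(s.mean(axis=1)))]

    def question_weights_at(self, lag: int,
                            average_timescales: bool = True,
                            ) -> tuple[np.ndarray, list[str]]:
        """Per-electrode question-weight vectors at one lag.

        With ``average_timescales`` the three timescale copies of each
        question are averaged into a single weight, the form used for
        clustering and cross-modality comparison.  Spectral columns are
        dropped.  Returns ((E, Q) array, qids).
        """
        res = self.results_per_lag[self.lags.index(lag)]
        if self.labels is None:
            raise ValueError("no column labels available")
        qids: list[str] = []
        for lab in self.labels:
            if lab[0] != "spectral" and lab[0] not in qids:
                qids.append(lab[0])
        E = res.weights.shape[1]
        out = np.zeros((E, len(qids)))
        for qi, q in enumerate(qids):
            rows = [j for j, lab in enumerate(self.labels) if lab[0] == q]
            block = res.weights[rows]  # (timescales, E)
            out[:, qi] = block.mean(axis=0) if average_timescales else block.sum(axis=0)
        return out, qids

    def summary(self) -> str:
        best = self.best_lag()
        lines = [
            "Lagged ECoG encoding results",
            "=" * 32,
            f"electrodes:        {self.scores.shape[1]}",
            f"lags:              {self.lags[0]}..{self.lags[-1]} ms "
            f"({len(self.lags)} steps)",
            f"best lag:          {best} ms",
            f"mean r @ best lag: {self.scores[self.lags.index(best)].mean():.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# electrode tables and selection

ELECTRODE_COLUMNS = ("electrode_id", "subject_id", "x", "y", "z")


def validate_electrode_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an electrode table: required columns, unique ids, finite coords."""
    missing = [c for c in ELECTRODE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"electrode table missing columns {missing}")
    if table["electrode_id"].duplicated().any():
        raise ValueError("duplicate electrode ids")
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite electrode coordinates")
    return table


def select_electrodes_min_performance(
    scores_by_model: Mapping[str, ScoreVector | np.ndarray],
    threshold: float,
    table: pd.DataFrame | None = None,
):
    """Keep electrodes whose *minimum* score across models >= threshold.

    Requiring the minimum across all compared encoding models to clear the
    bar restricts analyses to electrodes every feature space can predict.
    Returns indices, or the corresponding rows when ``table`` is given.
    """
    arrays = []
    for name, sv in scores_by_model.items():
        r = sv.r if isinstance(sv, ScoreVector) else np.asarray(sv, dtype=float)
        arrays.append(r)
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError("score vectors cover different electrode sets")
    min_scores = np.min(np.stack(arrays), axis=0)
    idx = np.flatnonzero(min_scores >= threshold)
    if table is not None:
        validate_electrode_table(table)
        if len(table) != arrays[0].shape[0]:
            raise ValueError("table rows must match score length")
        return table.iloc[idx].reset_index(drop=True)
    return idx


def cluster_electrode_weights(weights: np.ndarray, k: int) -> np.ndarray:
    """Ward agglomerative clustering of electrode question-weight profiles.

    ``weights`` is (E, Q), one timescale-averaged question-weight vector per
    electrode.  Each profile is z-scored across questions (shape, not
    magnitude, defines a selectivity type) before Ward linkage; the tree is
    cut to ``k`` clusters.  Deterministic given the input.  Returns labels
    0..k-1.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2:
        raise ValueError("weights must be (electrodes, questions)")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > W.shape[0]:
        raise ValueError("more clusters than electrodes")
    sd = W.std(axis=1, keepdims=True)
    Wz = (W - W.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    Z = linkage(Wz, method="ward")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def interpolate_fmri_to_electrodes(vertex_values: np.ndarray,
                                   vertex_coords: np.ndarray,
                                   electrode_coords: np.ndarray,
                                   n_neighbors: int = 10) -> np.ndarray:
    """Inverse-distance-weighted average of the nearest template vertices.

    For each electrode the ``n_neighbors`` nearest vertices (shared template
    space) are combined with weights proportional to 1/distance, normalized
    to sum 1 — a convex combination, so outputs stay within the range of the
    vertex values.  An electrode coincident with a vertex takes that
    vertex's value exactly.
    """
    v = np.asarray(vertex_values, dtype=float)
    vc = np.asarray(vertex_coords, dtype=float)
    ec = np.asarray(electrode_coords, dtype=float)
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if vc.shape[0] != v.shape[0]:
        raise ValueError("one coordinate row per vertex value required")
    if vc.shape[0] < n_neighbors:
        warnings.warn(
            f"only {vc.shape[0]} vertices available; using all of them"
        )
        n_neighbors = vc.shape[0]
    tree = cKDTree(vc)
    dist, idx = tree.query(ec, k=n_neighbors)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    out = np.empty(ec.shape[0])
    for e in range(ec.shape[0]):
        d, ix = dist[e], idx[e]
        zero = d == 0
        if zero.any():
            out[e] = v[ix[zero]].mean()
            continue
        w = 1.0 / d
        w /= w.sum()
        out[e] = float(w @ v[ix])
    return out


@dataclass
class CrossModalResult:
    """Per-question fMRI↔ECoG map agreement and its significance."""

    qids: list[str]
    r: np.ndarray  # per-question correlation over selected electrodes
    p_permutation: float  # permutation test on the mean correlation
    p_ttest: float  # paired t-test, observed vs permuted correlations
    fraction: float
    electrodes_used: np.ndarray  # indices into the electrode axis


def crossmodal_correlation_test(fmri_vertex_maps: np.ndarray,
                                vertex_coords: np.ndarray,
                                ecog_weights: np.ndarray,
                                electrode_coords: np.ndarray,
                                electrode_scores: ScoreVector | np.ndarray,
                                qids: Sequence[str] | None = None,
                                fraction: float = 1.0,
                                n_neighbors: int = 10,
                                n_perm: int = 1000,
                                seed: int = 0) -> CrossModalResult:
    """Correlate fMRI vertex maps (interpolated to electrodes) with ECoG
    electrode weights, question by question, and test the mean.

    For each question the fMRI map is carried to electrode positions by
    inverse-distance interpolation over the ``n_neighbors`` nearest template
    vertices, then correlated with the ECoG weights over the best-predicted
    ``fraction`` of electrodes.  Significance is assessed by permuting the
    electrode assignment of the interpolated values: the primary p-value is
    a permutation test on the mean correlation; a paired t-test between the
    observed and permutation-averaged per-question correlations is also
    reported.
    """
    F = np.asarray(fmri_vertex_maps, dtype=float)  # (Q, Vvert)
    E = np.asarray(ecog_weights, dtype=float)  # (Q, n_elec)
    if F.shape[0] != E.shape[0]:
        raise ValueError("both modalities must cover the same question set")
    Q = F.shape[0]
    qids = list(qids) if qids is not None else [f"q{i}" for i in range(Q)]
    mask = top_fraction_mask(electrode_scores, fraction)
    if mask.size < 3:
        raise ValueError("fewer than 3 electrodes after masking")
    interp = np.stack([
        interpolate_fmri_to_electrodes(F[q], vertex_coords, electrode_coords,
                                       n_neighbors)
        for q in range(Q)
    ])  # (Q, n_elec)
    Wsel = E[:, mask]
    Isel = interp[:, mask]
    obs, _ = pearson_columns(Wsel.T, Isel.T)

    Wc = Wsel - Wsel.mean(axis=1, keepdims=True)
    wn = np.linalg.norm(Wc, axis=1)
    wn = np.where(wn > 0, wn, 1.0)

    def null_draw(rng: np.random.Generator) -> np.ndarray:
        out = np.empty(Q)
        for q in range(Q):
            rp = Isel[q, rng.permutation(Isel.shape[1])]
            rc = rp - rp.mean()
            rn = np.linalg.norm(rc)
            out[q] = 0.0 if rn == 0 else float(Wc[q] @ rc / (wn[q] * rn))
        return out

    p_perm = permutation_pvalue_mean(obs, null_draw, n_perm=n_perm, seed=seed)
    rng = np.random.default_rng(seed + 1)
    null_mean_per_q = np.mean([null_draw(rng) for _ in range(n_perm)], axis=0)
    if np.allclose(obs - null_mean_per_q, (obs - null_mean_per_q)[0]):
        p_t = 0.0 if not np.allclose(obs, null_mean_per_q) else 1.0
    else:
        p_t = float(ttest_rel(obs, null_mean_per_q).pvalue)
    return CrossModalResult(
        qids=qids, r=obs, p_permutation=p_perm, p_ttest=p_t,
        fraction=fraction, electrodes_used=mask,
    )
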