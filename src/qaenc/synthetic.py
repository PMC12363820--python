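"""Self-contained synthetic data with planted structure.

Every other module is testable offline against data generated here: themed
transcripts whose words deterministically trigger known questions (so the
keyword annotator reproduces the gold annotations exactly), sparse planted
question→target weight matrices, hemodynamically convolved fMRI-like
responses with AR(1) noise at a controlled SNR, and lagged ECoG-like
word-aligned responses with the signal planted at a single lag.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .annotate import AnnotationMatrix, KeywordAnnotator
from .corpus import QuestionBank, Transcript, Word
from .ecog import WordAlignedFeatures
from .features import lanczos_downsample

__all__ = [
    "SyntheticGroundTruth",
    "SyntheticCorpus",
    "default_lexicons",
    "generate_synthetic_corpus",
    "make_ground_truth",
    "canonical_hrf",
    "simulate_bold_responses",
    "simulate_ecog_responses",
    "make_electrode_profiles",
    "generate_template_geometry",
    "FILLER_WORDS",
]

#: filler vocabulary, disjoint by construction from generated lexicons
FILLER_WORDS: tuple[str, ...] = (
    "the", "and", "then", "was", "with", "that", "into", "over", "about",
    "very", "some", "would", "could", "after", "before", "while", "there",
    "came", "went", "said", "still", "again", "almost", "around", "between",
)

#: narrative-speech word rate, words per second
DEFAULT_WORD_RATE: float = 2.5


@dataclass
class SyntheticGroundTruth:
    """Planted question→target weights and the noise model used to simulate
    responses from them."""

    weights: np.ndarray  # (Q, V)
    support: np.ndarray  # (Q, V) bool
    qids: list[str]
    active_qids: list[str]  # questions with any nonzero weight
    ar_coef: float = 0.3
    snr: float = 1.0
    seed: int = 0

    @property
    def n_targets(self) -> int:
        return self.weights.shape[1]

    def active_targets_of(self, qid: str) -> np.ndarray:
        return np.flatnonzero(self.support[self.qids.index(qid)])


@dataclass
class SyntheticCorpus:
    """A themed transcript with by-construction gold annotations."""

    transcript: Transcript
    gold: AnnotationMatrix
    annotator: KeywordAnnotator
    lexicons: dict[str, tuple[str, ...]]  # question text -> keywords
    word_questions: np.ndarray  # planted question index per word (-1 filler)


def default_lexicons(bank: QuestionBank, words_per_question: int = 4,
                     ) -> dict[str, tuple[str, ...]]:
    """Deterministic per-question keyword lexicons, keyed by question text.

    Keywords are synthetic tokens derived from the qid (``q06kw1`` …), which
    keeps them trivially disjoint from the filler vocabulary and from each
    other.
    """
    out: dict[str, tuple[str, ...]] = {}
    for qid, text in bank.questions:
        out[text] = tuple(f"{qid}kw{j}" for j in range(1, words_per_question + 1))
    return out


def generate_synthetic_corpus(bank: QuestionBank,
                              lexicons: Mapping[str, Sequence[str]] | None = None,
                              n_words: int = 5000,
                              word_rate: float = DEFAULT_WORD_RATE,
                              window_positive_rate: float | Mapping[str, float] = 0.1,
                              window_n: int = 10,
                              seed: int = 0,
                              story_id: str = "synth") -> SyntheticCorpus:
    """Sample a transcript whose words trigger known questions.

    Each word slot is a lexicon word of question q with probability chosen
    so that a fraction ``window_positive_rate`` of ``window_n``-gram windows
    contains at least one keyword of q; otherwise it is a filler word.  Gold
    annotations are computed directly from the planted word identities, so
    the keyword annotator reproduces them exactly (lexicons are disjoint
    from the filler vocabulary).
    """
    lexicons = dict(lexicons) if lexicons is not None else default_lexicons(bank)
    rates = {}
    for qid, text in bank.questions:
        r = (window_positive_rate.get(qid, 0.0)
             if isinstance(window_positive_rate, Mapping)
             else window_positive_rate)
        if r > 0 and not lexicons.get(text):
            raise ValueError(f"question {qid!r} is active but has an empty lexicon")
        rates[qid] = float(r)
    if not all(0 <= r < 1 for r in rates.values()):
        raise ValueError("window positive rates must lie in [0, 1)")
    # per-word plant probability giving the requested per-window rate
    p = np.array([1.0 - (1.0 - rates[qid]) ** (1.0 / window_n)
                  for qid, _ in bank.questions])
    if p.sum() >= 0.95:
        raise ValueError(
            f"total plant probability {p.sum():.2f} too high; lower the "
            "window positive rate or use fewer active questions"
        )
    probs = np.concatenate([p, [1.0 - p.sum()]])  # last slot = filler
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(probs), size=n_words, p=probs)
    word_q = np.where(choice < len(bank), choice, -1)

    tokens = np.array(rng.choice(FILLER_WORDS, size=n_words), dtype=object)
    kw_pick = rng.integers(0, 2**31, size=n_words)  # keyword index stream
    planted_rows = np.flatnonzero(word_q >= 0)
    for i in planted_rows:
        lex = lexicons[bank.questions[word_q[i]][1]]
        tokens[i] = lex[kw_pick[i] % len(lex)]
    onsets = np.arange(n_words) / word_rate
    words = tuple(
        Word(str(tokens[i]), float(onsets[i]), float(onsets[i] + 0.9 / word_rate))
        for i in range(n_words)
    )
    transcript = Transcript(story_id, words)

    # gold: window w positive for q iff any of its words was planted for q
    Q = len(bank)
    ind = np.zeros((n_words, Q), dtype=np.int32)
    ind[planted_rows, word_q[planted_rows]] = 1
    csum = np.cumsum(ind, axis=0)
    windowed = csum.copy()
    windowed[window_n:] -= csum[:-window_n]
    gold = (windowed > 0).astype(np.uint8)
    gold_mat = AnnotationMatrix(gold, transcript.onsets, list(bank.qids), story_id)
    annotator = KeywordAnnotator({t: tuple(ws) for t, ws in lexicons.items()})
    return SyntheticCorpus(transcript, gold_mat, annotator,
                           {t: tuple(ws) for t, ws in lexicons.items()}, word_q)


def make_ground_truth(bank: QuestionBank, n_targets: int = 200,
                      n_active_questions: int = 8,
                      per_target_density: float = 0.6,
                      ar_coef: float = 0.3, snr: float = 1.0,
                      seed: int = 0) -> SyntheticGroundTruth:
    """Sparse planted weights: a global active question set, each target
    loading on a random subset of it (at least one question per target)."""
    rng = np.random.default_rng(seed)
    Q = len(bank)
    if not 1 <= n_active_questions <= Q:
        raise ValueError("n_active_questions out of range")
    active = np.sort(rng.choice(Q, size=n_active_questions, replace=False))
    support = np.zeros((Q, n_targets), dtype=bool)
    for v in range(n_targets):
        mask = rng.random(n_active_questions) < per_target_density
        if not mask.any():
            mask[rng.integers(n_active_questions)] = True
        support[active[mask], v] = True
    weights = np.zeros((Q, n_targets))
    nz = support.sum()
    # magnitudes bounded away from zero so every planted effect is detectable
    weights[support] = rng.choice([-1.0, 1.0], size=nz) * rng.uniform(0.7, 1.3, size=nz)
    qids = list(bank.qids)
    return SyntheticGroundTruth(
        weights=weights, support=support, qids=qids,
        active_qids=[qids[i] for i in active],
        ar_coef=ar_coef, snr=snr, seed=seed,
    )


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Peak at 5 s, undershoot peaking at 15 s with 1/6 relative amplitude;
    normalized to unit peak.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration + tr / 2, tr)
    # gamma pdf peaks at (a-1)*scale; choose a=6, scale=1 -> peak 5 s
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    under = gamma_dist.pdf(t, a=16.0, scale=1.0)  # peak 15 s
    h = peak / peak.max() - (under / under.max()) / 6.0
    return h / np.abs(h).max()


def _ar1_noise(shape: tuple[int, int], ar: float, rng: np.random.Generator,
               ) -> np.ndarray:
    """Unit-variance stationary AR(1) noise, columns independent."""
    from scipy.signal import lfilter

    T, V = shape
    w = rng.standard_normal((T, V)) * np.sqrt(1.0 - ar**2)
    w[0] = rng.standard_normal(V)  # stationary start
    return lfilter([1.0], [1.0, -ar], w, axis=0)


def simulate_bold_responses(gt: SyntheticGroundTruth, A: AnnotationMatrix,
                            tr: float = 2.0, n_tr: int | None = None,
                            seed: int = 0, snr: float | None = None,
                            return_signal: bool = False):
    """BOLD-like responses from planted weights.

    The annotation matrix is resampled to the TR grid, mixed by the planted
    weights, convolved with the canonical double-gamma HRF, and corrupted
    with AR(1) Gaussian noise scaled per target so that
    var(signal)/var(noise) equals ``snr`` (default: the ground truth's SNR;
    ``np.inf`` gives noise-free responses).
    """
    snr = gt.snr if snr is None else snr
    if snr <= 0:
        raise ValueError("snr must be positive (np.inf for noise-free)")
    if A.qids != gt.qids:
        raise ValueError("annotation matrix and ground truth disagree on qids")
    if n_tr is None:
        n_tr = int(np.floor(A.anchor_times.max() / tr)) + 1
    X = lanczos_downsample(A, tr, n_tr)
    S0 = X.values @ gt.weights  # (T, V)
    h = canonical_hrf(tr)
    S = fftconvolve(S0, h[:, None], axes=0)[: S0.shape[0]]
    rng = np.random.default_rng(seed)
    if np.isinf(snr):
        Y = S.copy()
    else:
        noise = _ar1_noise(S.shape, gt.ar_coef, rng)
        sig_sd = S.std(axis=0)
        noise_sd = np.where(sig_sd > 0, sig_sd / np.sqrt(snr), 1.0)
        Y = S + noise * noise_sd
    if return_signal:
        return Y, S
    return Y


def simulate_ecog_responses(weights: np.ndarray, feat: WordAlignedFeatures,
                            lags: Sequence[int], planted_lag: int,
                            snr: float | np.ndarray = 1.0,
                            seed: int = 0) -> np.ndarray:
    """Word-aligned lagged responses with signal only at ``planted_lag``.

    ``weights`` is (F, E) over the feature columns.  At the planted lag the
    response is the linear signal plus noise at the requested per-electrode
    SNR; every other lag carries independent noise of matching total
    variance.  A per-electrode SNR array grades electrodes from well- to
    poorly-predicted, which supports monotonicity analyses over
    best-electrode fractions.
    """
    lags = list(lags)
    if planted_lag not in lags:
        raise ValueError(f"planted lag {planted_lag} not in the lag grid")
    Wn, F = feat.values.shape
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != F:
        raise ValueError("weights must have one row per feature column")
    E = weights.shape[1]
    snr_vec = np.broadcast_to(np.asarray(snr, dtype=float), (E,)).copy()
    if np.any(snr_vec <= 0):
        raise ValueError("per-electrode snr must be positive")
    rng = np.random.default_rng(seed)
    Z = feat.values @ weights  # (W, E)
    sig_sd = Z.std(axis=0)
    noise_sd = np.where(sig_sd > 0, sig_sd / np.sqrt(snr_vec), 1.0)
    total_sd = np.sqrt(sig_sd**2 + noise_sd**2)
    resp = np.empty((Wn, len(lags), E))
    for li, lag in enumerate(lags):
        if lag == planted_lag:
            resp[:, li, :] = Z + rng.standard_normal((Wn, E)) * noise_sd
        else:
            resp[:, li, :] = rng.standard_normal((Wn, E)) * total_sd
    return resp


def make_electrode_profiles(n_electrodes: int, n_profiles: int, n_questions: int,
                            within_noise: float = 0.0, seed: int = 0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Planted electrode groups with distinct question-weight profiles.

    Returns ((Q, E) weights, (E,) group labels).  Profiles are orthogonal-ish
    random sign patterns; ``within_noise`` adds electrode-level jitter.
    """
    if n_profiles > n_electrodes:
        raise ValueError("more profiles than electrodes")
    rng = np.random.default_rng(seed)
    profiles = rng.choice([-1.0, 1.0], size=(n_profiles, n_questions)) \
        * rng.uniform(0.5, 1.5, size=(n_profiles, n_questions))
    labels = np.arange(n_electrodes) % n_profiles
    rng.shuffle(labels)
    W = profiles[labels].T  # (Q, E)
    if within_noise > 0:
        W = W + within_noise * rng.standard_normal(W.shape)
    return W, labels


def generate_template_geometry(n_vertices: int, n_electrodes: int,
                               extent: float = 100.0, seed: int = 0,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Random vertex and electrode coordinates in a shared template box."""
    rng = np.random.default_rng(seed)
    vertices = rng.uniform(0, extent, size=(n_vertices, 3))
    electrodes = rng.uniform(0, extent, size=(n_electrodes, 3))
    return vertices, electrodes
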