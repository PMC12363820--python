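"""Windowing and binary annotation.

The annotation unit is a text *window* ending at each word: either the up-to-n
most recent words (n-gram windows, the fMRI feature unit) or all words within
a fixed number of seconds of context before the word (the higher-resolution
unit used for electrophysiology features).  A pluggable *annotator* answers
each yes/no question about each window, producing a binary windows x
questions annotation matrix — an interpretable text embedding in which each
column is one qualitative theory.

Annotators are deterministic for a fixed (window text, question text,
annotator id) triple, backed by an append-only cache so expensive annotators
(remote LLMs) are never asked the same thing twice.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .corpus import QuestionBank, Transcript

__all__ = [
    "Window",
    "AnnotationMatrix",
    "Annotator",
    "KeywordAnnotator",
    "CallableAnnotator",
    "AnnotationCache",
    "AnnotationError",
    "make_windows",
    "annotate",
    "ensemble_vote",
    "annotator_faithfulness",
]


class AnnotationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Window:
    """A contiguous run of words ending at (and anchored to) one word."""

    story_id: str
    word_indices: tuple[int, int]  # half-open [start, stop)
    text: str
    anchor_time: float  # onset of the final word

    def __post_init__(self) -> None:
        start, stop = self.word_indices
        if stop <= start:
            raise ValueError("empty window")


@dataclass
class AnnotationMatrix:
    """Binary windows x questions answer matrix with window timestamps."""

    values: np.ndarray  # (W, Q) uint8 in {0, 1}
    anchor_times: np.ndarray  # (W,) seconds, nondecreasing
    qids: list[str]
    story_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.anchor_times = np.asarray(self.anchor_times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("annotation entries must be binary")
        self.values = self.values.astype(np.uint8)
        if self.values.shape[0] != self.anchor_times.shape[0]:
            raise ValueError("anchor_times length must match rows")
        if self.values.shape[1] != len(self.qids):
            raise ValueError("qids length must match columns")
        if len(self.anchor_times) > 1 and np.any(np.diff(self.anchor_times) < 0):
            raise ValueError("anchor times must be nondecreasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def _compatible(self, other: "AnnotationMatrix") -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch {self.shape} vs {other.shape}")
        if self.qids != other.qids:
            raise ValueError("qid mismatch")
        if not np.allclose(self.anchor_times, other.anchor_times):
            raise ValueError("anchor-time mismatch")


# ---------------------------------------------------------------------------
# windowing


def make_windows(t: Transcript, mode: str = "ngram", n: int = 10,
                 context: float | None = None) -> list[Window]:
    """One window per word of ``t``.

    mode="ngram": window = up to ``n`` most recent words ending at the anchor
    word, truncated at story start.  mode="time_context": all words whose
    onset is within ``context`` seconds before the anchor word's onset, plus
    the anchor word itself (context 0 gives word-level windows of length 1).
    """
    if mode == "ngram":
        if n < 1:
            raise ValueError("n must be >= 1")
    elif mode == "time_context":
        if context is None or context < 0:
            raise ValueError("context must be >= 0 seconds")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    onsets = t.onsets
    tokens = t.tokens
    out: list[Window] = []
    for i in range(len(t)):
        if mode == "ngram":
            start = max(0, i - n + 1)
        else:
            cutoff = onsets[i] - context
            start = int(np.searchsorted(onsets[: i + 1], cutoff, side="left"))
        out.append(
            Window(
                story_id=t.story_id,
                word_indices=(start, i + 1),
                text=" ".join(tokens[start : i + 1]),
                anchor_time=float(onsets[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotators


class Annotator(Protocol):
    """Callable answering one yes/no question about one window text.

    Must be deterministic for a fixed (text, question, identifier) triple and
    return 0 or 1.
    """

    identifier: str

    def __call__(self, window_text: str, question_text: str) -> int: ...


_WORD_RE = re.compile(r"[\w']+")


@dataclass
class KeywordAnnotator:
    """Deterministic lexicon-based annotator.

    Answers "yes" iff the window contains any keyword from the lexicon
    associated with the question.  Questions without a lexicon answer 0.
    Useful as a fully offline reference annotator and as the ground-truth
    reader for synthetic corpora.

    Parameters
    ----------
    lexicons : mapping of question text -> collection of keywords
    case_fold : lower-case both window tokens and keywords before matching
    """

    lexicons: Mapping[str, Sequence[str]]
    case_fold: bool = True
    identifier: str = "keyword"

    def __post_init__(self) -> None:
        fold = (lambda s: s.lower()) if self.case_fold else (lambda s: s)
        self._sets = {
            q: frozenset(fold(w) for w in words) for q, words in self.lexicons.items()
        }
        self._fold = fold

    def __call__(self, window_text: str, question_text: str) -> int:
        lex = self._sets.get(question_text)
        if not lex:
            return 0
        toks = _WORD_RE.findall(self._fold(window_text))
        return int(any(tok in lex for tok in toks))


@dataclass
class CallableAnnotator:
    """Adapter wrapping any (text, question) -> {0,1} function.

    This is the seam where an LLM-backed annotator plugs in: the wrapped
    callable performs the request (prompting the model to answer strictly
    "Yes" or "No"); anything non-binary must raise rather than be coerced.
    """

    fn: Callable[[str, str], int]
    identifier: str

    def __call__(self, window_text: str, question_text: str) -> int:
        return self.fn(window_text, question_text)


PROMPT_TEMPLATE = (
    "Answer the question about the quoted text with exactly one word, "
    '"Yes" or "No".\n\nQuestion: {question}\nText: "{window}"\nAnswer:'
)


def parse_yes_no(response: str) -> int:
    """Map a strict Yes/No response to 1/0; anything else is an error."""
    head = response.strip().split()
    if head:
        word = head[0].strip(".,!").lower()
        if word == "yes":
            return 1
        if word == "no":
            return 0
    raise AnnotationError(f"annotator response is not Yes/No: {response!r}")


class AnnotationCache:
    """Append-only (annotator, question, window) -> answer store.

    Keys are SHA-1 digests of the triple; persisted as a flat JSON object so
    the store is text, diffable and mergeable.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._store: dict[str, int] = {}
        if self.path is not None and self.path.exists():
            self._store.update(json.loads(self.path.read_text(encoding="utf-8")))

    @staticmethod
    def key(annotator_id: str, question_text: str, window_text: str) -> str:
        payload = "\x1f".join((annotator_id, question_text, window_text))
        return hashlib.sha1(payload.encode("utf-8")).hexdigest()

    def get(self, annotator_id: str, question_text: str, window_text: str):
        return self._store.get(self.key(annotator_id, question_text, window_text))

    def put(self, annotator_id: str, question_text: str, window_text: str,
            answer: int) -> None:
        self._store[self.key(annotator_id, question_text, window_text)] = int(answer)

    def save(self) -> None:
        if self.path is None:
            raise ValueError("cache has no backing path")
        self.path.write_text(json.dumps(self._store), encoding="utf-8")

    def __len__(self) -> int:
        return len(self._store)


# ---------------------------------------------------------------------------
# annotation


def annotate(windows: Sequence[Window], bank: QuestionBank, annotator: Annotator,
             cache: AnnotationCache | None = None, retries: int = 2,
             ) -> AnnotationMatrix:
    """Answer every question of ``bank`` for every window.

    The cache is consulted before any annotator call; new answers are written
    back.  A non-binary answer, or an annotator failure persisting across
    ``retries`` attempts, raises :class:`AnnotationError` naming the
    offending (window, qid) pair.
    """
    W, Q = len(windows), len(bank)
    values = np.zeros((W, Q), dtype=np.uint8)
    for j, (qid, qtext) in enumerate(bank.questions):
        for i, win in enumerate(windows):
            ans = None
            if cache is not None:
                ans = cache.get(annotator.identifier, qtext, win.text)
            if ans is None:
                err: Exception | None = None
                for _ in range(retries + 1):
                    try:
                        ans = annotator(win.text, qtext)
                        break
                    except Exception as exc:  # retry transient failures
                        err = exc
                if ans is None:
                    raise AnnotationError(
                        f"annotator failed for window {i} "
                        f"(anchor {win.anchor_time:.2f}s), question {qid!r}: {err}"
                    )
                if cache is not None:
                    cache.put(annotator.identifier, qtext, win.text, ans)
            if ans not in (0, 1):
                raise AnnotationError(
                    f"non-binary answer {ans!r} for window {i}, question {qid!r}"
                )
            values[i, j] = ans
    anchors = np.array([w.anchor_time for w in windows], dtype=float)
    story = windows[0].story_id if windows else ""
    return AnnotationMatrix(values, anchors, list(bank.qids), story)


def ensemble_vote(mats: Sequence[AnnotationMatrix]) -> AnnotationMatrix:
    """Majority vote across annotators; a tie votes 1 (answer present)."""
    if not mats:
        raise ValueError("need at least one annotation matrix")
    first = mats[0]
    for m in mats[1:]:
        first._compatible(m)
    stacked = np.stack([m.values for m in mats], axis=0).astype(float)
    voted = (stacked.mean(axis=0) >= 0.5).astype(np.uint8)
    return AnnotationMatrix(voted, first.anchor_times.copy(), list(first.qids),
                            first.story_id)


def annotator_faithfulness(A: AnnotationMatrix, gold: AnnotationMatrix,
                           ) -> np.ndarray:
    """Per-question agreement with gold labels, each in [0, 1].

    The overall faithfulness is the mean of the returned vector.
    """
    A._compatible(gold)
    return (A.values == gold.values).mean(axis=0)
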