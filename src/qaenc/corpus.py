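"""Transcripts and question banks.

A *transcript* is a timed word sequence for one narrative story: each word
carries an onset and offset in seconds relative to story start.  A *question
bank* is an ordered list of yes/no questions with stable ids; the order of
the bank defines the feature-column order everywhere downstream.

Two transcript dialects are supported: a canonical UTF-8 TSV with header
``word<TAB>onset<TAB>offset`` (seconds as decimals), and Praat TextGrid
interval tiers (long or short text format).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Word",
    "Transcript",
    "QuestionBank",
    "TranscriptError",
    "QuestionBankError",
    "load_transcript",
    "write_transcript",
    "load_question_bank",
    "write_question_bank",
    "load_qa35",
    "answer_correlation_matrix",
]

#: tokens treated as silence markers and dropped on load
SILENCE_TOKENS = frozenset({"", "sp", "sil", "<sil>", "{sl}", "{ns}"})


class TranscriptError(ValueError):
    """Malformed or invalid transcript input."""


class QuestionBankError(ValueError):
    """Malformed or invalid question-bank input."""


@dataclass(frozen=True)
class Word:
    token: str
    onset: float
    offset: float


@dataclass(frozen=True)
class Transcript:
    """Timed word sequence for one story.

    Invariants (checked on construction): onsets strictly increasing,
    ``offset >= onset`` for every word, and nonempty tokens.
    """

    story_id: str
    words: tuple[Word, ...]

    def __post_init__(self) -> None:
        for i, w in enumerate(self.words):
            if not w.token or not w.token.strip():
                raise TranscriptError(f"empty token at word {i} of {self.story_id!r}")
            if w.offset < w.onset:
                raise TranscriptError(
                    f"word {i} ({w.token!r}): offset {w.offset} < onset {w.onset}"
                )
        onsets = self.onsets
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
            raise TranscriptError(
                f"onsets not strictly increasing at word {bad} "
                f"({self.words[bad].token!r}, onset {self.words[bad].onset})"
            )

    @property
    def onsets(self) -> np.ndarray:
        return np.array([w.onset for w in self.words], dtype=float)

    @property
    def tokens(self) -> list[str]:
        return [w.token for w in self.words]

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class QuestionBank:
    """Ordered yes/no questions with stable unique ids.

    The ordering is load order and defines feature-column order.
    """

    questions: tuple[tuple[str, str], ...]  # (qid, text)
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for qid, text in self.questions:
            if qid in seen:
                raise QuestionBankError(f"duplicate qid {qid!r}")
            seen.add(qid)
            if text and not text.rstrip().endswith("?"):
                warnings.warn(f"question {qid!r} does not end in '?': {text!r}")

    @property
    def qids(self) -> list[str]:
        return [q for q, _ in self.questions]

    @property
    def texts(self) -> list[str]:
        return [t for _, t in self.questions]

    def text_of(self, qid: str) -> str:
        for q, t in self.questions:
            if q == qid:
                return t
        raise KeyError(qid)

    def __len__(self) -> int:
        return len(self.questions)


# ---------------------------------------------------------------------------
# transcript I/O


def _words_from_rows(rows: Iterable[tuple[str, float, float]],
                     drop_silence: bool = True) -> list[Word]:
    words = []
    for token, onset, offset in rows:
        token = str(token).strip()
        if drop_silence and token.lower() in SILENCE_TOKENS:
            continue
        words.append(Word(token, float(onset), float(offset)))
    return words


def _parse_textgrid_words(text: str) -> list[tuple[str, float, float]]:
    # Minimal interval-tier reader covering long ("xmin = 0.0") and short
    # (bare numbers / quoted strings on their own lines) TextGrid text files.
    # Only the first IntervalTier is read.
    if "IntervalTier" not in text and "intervals" not in text:
        raise TranscriptError("no interval tier found in TextGrid")
    rows: list[tuple[str, float, float]] = []
    long_fmt = re.findall(
        r"intervals\s*\[\d+\]\s*:?\s*"
        r"xmin\s*=\s*([-\d.eE]+)\s*"
        r"xmax\s*=\s*([-\d.eE]+)\s*"
        r'text\s*=\s*"((?:[^"]|"")*)"',
        text,
    )
    if long_fmt:
        for xmin, xmax, tok in long_fmt:
            rows.append((tok.replace('""', '"'), float(xmin), float(xmax)))
        return rows
    # short format: after the tier header, triples of xmin / xmax / "text"
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    try:
        start = next(i for i, ln in enumerate(lines) if "IntervalTier" in ln)
    except StopIteration:
        raise TranscriptError("unsupported TextGrid layout") from None
    i = start + 1
    # skip tier name, tier xmin/xmax, interval count
    while i < len(lines) and not _is_number(lines[i]):
        i += 1
    i += 3  # tier xmin, xmax, size
    while i + 2 < len(lines) + 1 and i + 2 <= len(lines):
        if not (_is_number(lines[i]) and _is_number(lines[i + 1])):
            break
        xmin, xmax = float(lines[i]), float(lines[i + 1])
        tok = lines[i + 2].strip('"')
        rows.append((tok, xmin, xmax))
        i += 3
    if not rows:
        raise TranscriptError("no intervals parsed from TextGrid")
    return rows


def _is_number(s: str) -> bool:
    try:
        float(s.strip('"'))
        return True
    except ValueError:
        return False


def load_transcript(path: str | Path, dialect: str = "tsv",
                    story_id: str | None = None) -> Transcript:
    """Load a transcript from ``path`` under the named dialect.

    Parameters
    ----------
    path : str or Path
    dialect : {"tsv", "textgrid"}
        TSV expects the canonical ``word\\tonset\\toffset`` header; the
        TextGrid reader takes the first interval tier as the word tier.
    story_id : str, optional
        Defaults to the file stem.

    Silence/empty tokens are dropped.  Monotonicity violations raise
    :class:`TranscriptError` naming the offending word.
    """
    path = Path(path)
    sid = story_id or path.stem
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"word": str})
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise TranscriptError(f"cannot parse {path}: {exc}") from exc
        required = {"word", "onset", "offset"}
        if not required.issubset(df.columns):
            raise TranscriptError(
                f"{path}: TSV must have columns word/onset/offset, got {list(df.columns)}"
            )
        for col in ("onset", "offset"):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise TranscriptError(
                    f"{path}: malformed {col} at data line {int(bad[0]) + 2}"
                )
        rows = list(zip(df["word"].fillna(""), df["onset"].astype(float),
                        df["offset"].astype(float)))
    elif dialect == "textgrid":
        rows = _parse_textgrid_words(Path(path).read_text(encoding="utf-8"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return Transcript(sid, tuple(_words_from_rows(rows)))


def write_transcript(t: Transcript, path: str | Path) -> None:
    """Write the canonical TSV dialect (round-trips with :func:`load_transcript`)."""
    df = pd.DataFrame(
        {"word": t.tokens, "onset": [w.onset for w in t.words],
         "offset": [w.offset for w in t.words]}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# question bank I/O


def load_question_bank(path: str | Path) -> QuestionBank:
    """Load a question bank from JSON (list of {qid,text}) or 2-column CSV.

    Order is preserved; duplicate qids are rejected; a question not ending
    in "?" raises a warning but is kept.  An empty file yields an empty bank.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = path.read_text(encoding="utf-8").strip()
        if not raw:
            return QuestionBank(())
        obj = json.loads(raw)
        items = obj["questions"] if isinstance(obj, dict) else obj
        questions = tuple((str(d["qid"]), str(d["text"])) for d in items)
        tags = {str(d["qid"]): str(d["tag"]) for d in items if "tag" in d}
        return QuestionBank(questions, tags)
    # CSV path
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return QuestionBank(())
    if df.empty and len(df.columns) == 0:
        return QuestionBank(())
    cols = [c for c in ("qid", "text") if c in df.columns]
    if len(cols) != 2:
        raise QuestionBankError(f"{path}: CSV needs qid,text columns")
    questions = tuple(zip(df["qid"].astype(str), df["text"].astype(str)))
    tags = {}
    if "tag" in df.columns:
        tags = {q: t for q, t in zip(df["qid"], df["tag"]) if isinstance(t, str)}
    return QuestionBank(questions, tags)


def write_question_bank(bank: QuestionBank, path: str | Path) -> None:
    path = Path(path)
    items = [
        {"qid": q, "text": t, **({"tag": bank.tags[q]} if q in bank.tags else {})}
        for q, t in bank.questions
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(items, indent=1), encoding="utf-8")
    else:
        pd.DataFrame(items).to_csv(path, index=False)


def load_qa35() -> QuestionBank:
    """Packaged 35-question compact bank (synthetic reconstruction).

    The bank covers the high-level categories a compact neurolinguistic
    question set spans (tactile, visuospatial, numerical, planning,
    communication, abstract/lexical); it is a stand-in written for this
    package, not an original study artifact.
    """
    with resources.files("qaenc.data").joinpath("qa35_synthetic.json").open(
        "r", encoding="utf-8"
    ) as fh:
        obj = json.load(fh)
    questions = tuple((d["qid"], d["text"]) for d in obj["questions"])
    tags = {d["qid"]: d.get("tag", "") for d in obj["questions"]}
    return QuestionBank(questions, tags)


# ---------------------------------------------------------------------------
# descriptive statistics


def answer_correlation_matrix(values: np.ndarray, return_flags: bool = False):
    """Pairwise Pearson correlation between question answer columns.

    Parameters
    ----------
    values : (W, Q) array
        Binary (or real) answers, one row per annotation window.
    return_flags : bool
        Also return a boolean vector marking constant columns.

    Returns
    -------
    (Q, Q) symmetric matrix with unit diagonal and entries in [-1, 1].
    Constant columns have undefined correlation; their off-diagonal entries
    are reported as the sentinel 0 (and flagged) so the heatmap stays
    computable on degenerate data.
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2:
        raise ValueError("expected a 2-D windows x questions matrix")
    if V.shape[0] < 2:
        raise ValueError("need at least 2 windows to correlate answers")
    sd = V.std(axis=0)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(V, rowvar=False)
    C = np.atleast_2d(C)
    C[np.isnan(C)] = 0.0
    C[:, const] = 0.0
    C[const, :] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    if return_flags:
        return C, const
    return C
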