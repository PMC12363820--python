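"""Design-matrix construction: word-rate annotations -> scan-grid regressors.

Annotation matrices live on the irregular word-onset grid.  For fMRI the
response lives on the regular TR grid, so annotation columns are low-pass
resampled onto it with a Lanczos kernel, then copies of each column shifted
by a few TRs (FIR delays) are appended so a linear model can absorb the
hemodynamic lag without an explicit HRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import AnnotationMatrix

__all__ = ["FeatureMatrix", "lanczos_downsample", "add_fir_delays",
           "DEFAULT_DELAYS"]

#: FIR delays (in TRs) spanning the hemodynamic peak at TR = 2 s
DEFAULT_DELAYS: tuple[int, ...] = (1, 2, 3, 4)


@dataclass
class FeatureMatrix:
    """Model-ready design matrix with (qid, delay) column labels.

    ``tr`` is set for TR-grid matrices and None for word-grid matrices.
    Columns are *not* standardized here; z-scoring happens inside model
    fitting using training statistics only, so no test statistics leak into
    the design.
    """

    values: np.ndarray  # (T, F) float
    labels: list[tuple] = field(default_factory=list)  # (qid, delay) per column
    tr: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("design contains NaN/Inf")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per column required")
        if len(set(map(tuple, self.labels))) != len(self.labels):
            raise ValueError("column labels must be unique")
        self.labels = [tuple(l) for l in self.labels]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def qids(self) -> list[str]:
        """Unique qids in first-appearance order."""
        seen: list[str] = []
        for lab in self.labels:
            if lab[0] not in seen:
                seen.append(lab[0])
        return seen

    def columns_for(self, qid: str) -> list[int]:
        return [j for j, lab in enumerate(self.labels) if lab[0] == qid]

    def save_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            values=self.values,
            labels=np.array([[str(a) for a in lab] for lab in self.labels]),
            tr=np.array(-1.0 if self.tr is None else self.tr),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            tr = float(z["tr"])
            labels = [
                (row[0], int(row[1]) if row[1].lstrip("-").isdigit() else row[1])
                for row in z["labels"]
            ]
            return cls(z["values"], labels, None if tr < 0 else tr)


def _lanczos_kernel(x: np.ndarray, a: int) -> np.ndarray:
    """sinc(x)·sinc(x/a) windowed to |x| < a (x in output-sample units)."""
    out = np.sinc(x) * np.sinc(x / a)
    out[np.abs(x) >= a] = 0.0
    return out


def lanczos_downsample(A: AnnotationMatrix, tr: float, n_tr: int,
                       a: int = 3) -> FeatureMatrix:
    """Low-pass resample word-rate annotation columns onto the TR grid.

    Output sample ``t`` is a Lanczos-kernel-weighted sum of the word values
    around time ``t*tr``, with the kernel cutoff at the output Nyquist
    frequency ``1/(2*tr)`` and ``a`` lobes.  Weights are normalized to sum
    to 1 per output sample, so a constant input column stays constant and a
    word exactly at a grid time passes through unchanged.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_tr < 1:
        raise ValueError("n_tr must be >= 1")
    times = A.anchor_times
    span = n_tr * tr
    if times.size == 0 or times.min() < 0 or times.max() >= span:
        raise ValueError(
            f"word anchor times must lie inside the grid span [0, {span})"
        )
    grid = np.arange(n_tr) * tr
    # (n_tr, W) offsets in units of the output sample spacing
    X = (times[None, :] - grid[:, None]) / tr
    Wgt = _lanczos_kernel(X, a)
    sums = Wgt.sum(axis=1)
    ok = np.abs(sums) > 1e-12
    Wgt[ok] /= sums[ok, None]
    Wgt[~ok] = 0.0  # grid samples with no words in the kernel support
    values = Wgt @ A.values.astype(float)
    labels = [(q, 0) for q in A.qids]
    return FeatureMatrix(values, labels, tr=tr)


def add_fir_delays(X: FeatureMatrix, delays: Sequence[int] = DEFAULT_DELAYS,
                   ) -> FeatureMatrix:
    """Append FIR-delayed copies of every column.

    Column (q, d) at row t equals input column q at row t - d; rows with
    t - d < 0 are zero-filled.  Output has F·len(delays) columns ordered
    delay-major within each input column.
    """
    delays = list(delays)
    if not delays:
        raise ValueError("delay list must be nonempty")
    if any((d != int(d)) or d < 0 for d in delays):
        raise ValueError("delays must be nonnegative integers")
    T, F = X.shape
    cols = []
    labels = []
    for j, lab in enumerate(X.labels):
        qid = lab[0]
        for d in delays:
            shifted = np.zeros(T)
            if d == 0:
                shifted[:] = X.values[:, j]
            else:
                shifted[d:] = X.values[: T - d, j]
            cols.append(shifted)
            labels.append((qid, int(d)))
    return FeatureMatrix(np.column_stack(cols), labels, tr=X.tr)
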