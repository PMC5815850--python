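"""Per-gene spatial expression traces and LOESS smoothing.

A trace is a gene's normalized expression plotted against section number.
Smoothing is classical LOESS — at each point, a degree-2 weighted least
squares fit over the span*n nearest neighbors with tricube weights,
no robustness iterations — and is presentation-layer only: peak
detection, clustering and enrichment always run on unsmoothed values.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import NormalizedMatrix

__all__ = ["ExpressionTrace", "loess_smooth", "gene_trace", "superimpose"]


@dataclass
class ExpressionTrace:
    gene_id: str
    section_ids: list[int]
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    span: float | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.section_ids):
            raise ValueError("trace length must match the section axis")
        if self.span is not None and not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")


def loess_smooth(
    y: np.ndarray,
    x: np.ndarray | None = None,
    span: float = 0.3,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at the data points.

    At each x_i a polynomial of ``degree`` is fit by weighted least
    squares over the ``ceil(span * n)`` nearest neighbors, with tricube
    weights w = (1 - (d / d_max)^3)^3 on the distance d to x_i.  No
    robustness iterations are performed.

    Raises if the window holds fewer than ``degree + 1`` points.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if x is None:
        x = np.arange(n, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) != n:
        raise ValueError("x and y lengths differ")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    k = math.ceil(span * n)
    if k < degree + 1:
        raise ValueError(
            f"window of {k} points cannot fit a degree-{degree} polynomial "
            f"(span {span} of n={n}; need span*n >= {degree + 1})"
        )
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        # k nearest neighbors; stable tie-break by index
        nn = np.argsort(d, kind="stable")[:k]
        dmax = d[nn].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = (1.0 - (d[nn] / dmax) ** 3) ** 3
        w = np.maximum(w, 0.0)
        sw = np.sqrt(w)
        # center locally for conditioning
        xc = x[nn] - x[i]
        design = np.vander(xc, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[nn] * sw, rcond=None)
        out[i] = coef[0]  # evaluation at xc = 0
    return out


def gene_trace(
    m: NormalizedMatrix,
    gene_id: str,
    span: float | None = None,
    degree: int = 2,
) -> ExpressionTrace:
    """Extract one gene's spatial trace, optionally LOESS-smoothed."""
    try:
        row = m.gene_ids.index(gene_id)
    except ValueError:
        near = difflib.get_close_matches(gene_id, m.gene_ids, n=3)
        hint = f"; nearest ids: {near}" if near else ""
        raise KeyError(f"gene {gene_id!r} not in matrix{hint}") from None
    raw = m.values_[row]
    smoothed = None
    if span is not None:
        smoothed = loess_smooth(
            raw, np.asarray(m.section_ids, dtype=float), span, degree
        )
    return ExpressionTrace(gene_id, list(m.section_ids), raw, smoothed, span)


def superimpose(
    traces: list[ExpressionTrace], scale: str = "none"
) -> pd.DataFrame:
    """Combine traces into one table (section index, one column per gene).

    ``scale="unit_max"`` divides each trace by its maximum so peak
    positions are directly comparable; the smoothed series is used when
    present, otherwise the raw one.
    """
    if not traces:
        raise ValueError("no traces to superimpose")
    axis = traces[0].section_ids
    for t in traces[1:]:
        if t.section_ids != axis:
            raise ValueError(
                f"trace {t.gene_id} has a different section axis"
            )
    if scale not in ("none", "unit_max"):
        raise ValueError("scale must be 'none' or 'unit_max'")
    data = {}
    for t in traces:
        v = t.smoothed if t.smoothed is not None else t.raw
        v = np.asarray(v, dtype=float)
        if scale == "unit_max":
            peak = v.max()
            if peak > 0:
                v = v / peak
        data[t.gene_id] = v
    return pd.DataFrame(data, index=pd.Index(axis, name="section"))
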