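"""Section-wise normalization and per-gene standardization.

Two normalization steps are implemented, mirroring how serial-section
RNA-seq data are usually corrected for technical variation:

* **total-count**: each section is scaled by its total endogenous read
  count, then re-scaled to the median of the section totals, so every
  output section total equals the median raw total exactly and values stay
  on a counts-like scale.
* **spike-in**: each section is scaled by its total ERCC spike-in read
  count (the spike-ins enter every section in equal amounts, so their
  yield tracks capture efficiency), again with a median re-scale.

When both are requested the spike-in step runs first; the order is
recorded in the output's provenance.

Per-gene standardization (``zscore_rows``) produces the Z profiles used by
section correlation, peak-gene selection and clustering, either on linear
values or in log2 space (the "zlfc" variant: each section's log2 deviation
from the gene mean, standardized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "ZMatrix",
    "total_count_normalize",
    "spikein_normalize",
    "zscore_rows",
    "Z_MIN_DEFAULT",
    "Z_MIN_STRICT",
]

# Peak-selection thresholds offered as named presets: 1.2 is the default,
# 1.25 the stricter variant used for the clustered heat map.
Z_MIN_DEFAULT = 1.2
Z_MIN_STRICT = 1.25


@dataclass
class NormalizedMatrix:
    """Continuous expression values after section normalization.

    ``provenance`` lists the applied steps in order, with parameters,
    and is embedded as ``#`` comments when the matrix is written out.
    """

    gene_ids: list[str]
    section_ids: list[int]
    values_: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values_ = np.asarray(self.values_, dtype=float)
        if self.values_.shape != (len(self.gene_ids), len(self.section_ids)):
            raise ValueError("values shape does not match gene/section ids")
        if not np.all(np.isfinite(self.values_)):
            raise ValueError("normalized values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values_.shape[0]

    @property
    def n_sections(self) -> int:
        return self.values_.shape[1]


@dataclass
class ZMatrix:
    """Per-gene standardized expression profiles.

    Every non-constant gene row has mean 0 and sample SD 1; constant rows
    are all-zero and flagged in ``constant_mask``.  ``transform_tag`` is
    ``"linear_z"`` or ``"log_z"``.
    """

    gene_ids: list[str]
    section_ids: list[int]
    z: np.ndarray
    transform_tag: str
    constant_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.transform_tag not in ("linear_z", "log_z"):
            raise ValueError("transform_tag must be 'linear_z' or 'log_z'")
        if self.constant_mask is None:
            self.constant_mask = np.zeros(len(self.gene_ids), dtype=bool)

    @property
    def n_sections(self) -> int:
        return self.z.shape[1]


def _as_values(m) -> tuple[list[str], list[int], np.ndarray, list[str]]:
    if isinstance(m, CountMatrix):
        return list(m.gene_ids), list(m.section_ids), m.counts.copy(), []
    if isinstance(m, NormalizedMatrix):
        return (
            list(m.gene_ids),
            list(m.section_ids),
            m.values_.copy(),
            list(m.provenance),
        )
    raise TypeError(f"expected CountMatrix or NormalizedMatrix, got {type(m)}")


def total_count_normalize(m) -> NormalizedMatrix:
    """Scale each section to its total count, then to the median total.

    value(g, s) = count(g, s) / T(s) * median(T), with T(s) the section
    total over the genes present in the matrix (spike-ins should be split
    off first).  Sections with zero total are dropped with a warning and a
    provenance record.
    """
    gene_ids, section_ids, values, prov = _as_values(m)
    totals = values.sum(axis=0)
    if np.all(totals == 0):
        raise ValueError("cannot normalize an all-zero matrix")
    zero = totals == 0
    if zero.any():
        dropped = [s for s, z in zip(section_ids, zero) if z]
        warnings.warn(
            f"dropping zero-total sections: {dropped}", stacklevel=2
        )
        prov.append(f"dropped zero-total sections {dropped}")
        values = values[:, ~zero]
        section_ids = [s for s, z in zip(section_ids, zero) if not z]
        totals = totals[~zero]
    med = float(np.median(totals))
    out = values / totals * med
    prov.append(f"total_count_normalize(median_total={med!r})")
    return NormalizedMatrix(gene_ids, section_ids, out, prov)


def spikein_normalize(m, spikes: CountMatrix) -> NormalizedMatrix:
    """Scale each section by its total spike-in read count.

    value(g, s) = count(g, s) / K(s) * median(K), where K(s) is the total
    spike-in count of section s.  The median re-scale keeps output on a
    counts-like scale.  A section with zero spike-in reads is an error
    (its technical scaling is unidentifiable).
    """
    gene_ids, section_ids, values, prov = _as_values(m)
    if list(spikes.section_ids) != section_ids:
        raise ValueError("spike-in matrix sections do not match data sections")
    k = spikes.counts.sum(axis=0)
    if np.any(k == 0):
        bad = [s for s, z in zip(section_ids, k == 0) if z]
        raise ValueError(
            f"zero spike-in reads in section(s) {bad}; "
            "spike-in normalization is undefined there"
        )
    med = float(np.median(k))
    out = values / k * med
    prov.append(f"spikein_normalize(median_spikein_total={med!r})")
    return NormalizedMatrix(gene_ids, section_ids, out, prov)


def zscore_rows(
    m, log_space: bool = False, pseudocount: float = 1.0
) -> ZMatrix:
    """Standardize each gene row to mean 0, sample SD 1 (n-1 denominator).

    With ``log_space`` the row is first transformed to
    ``log2(value + pseudocount)`` — the "zlfc" reading: each section's
    log2 fold deviation from the gene's mean, standardized.  Rows with
    zero variance become all-zero and are flagged constant.
    """
    gene_ids, section_ids, values, _ = _as_values(m)
    if log_space:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 in log space")
        x = np.log2(values + pseudocount)
        tag = "log_z"
    else:
        x = values
        tag = "linear_z"
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd_safe
    z[constant] = 0.0
    return ZMatrix(gene_ids, section_ids, z, tag, constant)
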