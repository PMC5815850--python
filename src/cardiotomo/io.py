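"""Reading and writing the tabular formats the pipeline touches.

The canonical on-disk format is a genes x sections tab-separated table:
first column gene ID, header row = integer section numbers along the
anterior-posterior sectioning axis.  Section numbering is 1-based and taken
verbatim from the file header (the dissected-heart dataset starts at #2);
every region of interest and report uses these labels, never 0-based
positions.

Comment lines starting with ``#`` (used to embed normalization provenance)
are ignored on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "read_expression_matrix",
    "split_spikeins",
    "write_matrix",
    "write_results_table",
]

DEFAULT_SPIKEIN_PREFIX = "ERCC-"


@dataclass
class CountMatrix:
    """Integer read counts for genes across ordered tissue sections.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers (row order).
    section_ids : list of int
        Strictly increasing section numbers (anterior to posterior).
    counts : ndarray, shape (n_genes, n_sections)
        Non-negative counts.  Integral unless ``allow_float`` was set by
        the loader (e.g. for a pre-normalized supplementary table), in
        which case ``is_float`` records the relaxation.
    spikein_mask : ndarray of bool, shape (n_genes,)
        True for spike-in control rows.
    is_float : bool
        True when the integrality invariant was explicitly relaxed.
    """

    gene_ids: list[str]
    section_ids: list[int]
    counts: np.ndarray
    spikein_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_float: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x sections matrix")
        n_genes, n_sections = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {n_genes} count rows"
            )
        if len(self.section_ids) != n_sections:
            raise ValueError(
                f"{len(self.section_ids)} section ids but {n_sections} count columns"
            )
        if n_sections < 2:
            raise ValueError("a count matrix needs at least 2 sections")
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted(
                {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            )
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        sec = list(self.section_ids)
        if any(b <= a for a, b in zip(sec, sec[1:])):
            raise ValueError("section_ids must be strictly increasing")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.is_float and not np.allclose(
            self.counts, np.round(self.counts)
        ):
            raise ValueError(
                "non-integer counts; pass allow_float=True to load a "
                "pre-normalized (float) matrix"
            )
        if self.spikein_mask is None:
            self.spikein_mask = np.zeros(n_genes, dtype=bool)
        else:
            self.spikein_mask = np.asarray(self.spikein_mask, dtype=bool)
            if self.spikein_mask.shape != (n_genes,):
                raise ValueError("spikein_mask must have one entry per gene")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sections(self) -> int:
        return self.counts.shape[1]

    def section_index(self, section_id: int) -> int:
        """Column index of a 1-based section label."""
        try:
            return self.section_ids.index(section_id)
        except ValueError:
            raise KeyError(
                f"section #{section_id} not in matrix "
                f"(sections #{self.section_ids[0]}-#{self.section_ids[-1]})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.section_ids
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype != bool:
            mask = np.zeros(self.n_genes, dtype=bool)
            mask[keep] = True
            keep = mask
        return CountMatrix(
            gene_ids=[g for g, k in zip(self.gene_ids, keep) if k],
            section_ids=list(self.section_ids),
            counts=self.counts[keep],
            spikein_mask=self.spikein_mask[keep],
            is_float=self.is_float,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.section_ids == other.section_ids
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.spikein_mask, other.spikein_mask)
        )


def read_expression_matrix(
    path: str | Path,
    genes_in: str = "rows",
    sep: str = "\t",
    allow_float: bool = False,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
) -> CountMatrix:
    """Read a genes x sections count table.

    Parameters
    ----------
    path
        Tab-separated file; first column gene IDs, header = section numbers.
        Lines starting with ``#`` are ignored.
    genes_in
        ``"rows"`` (default) or ``"columns"`` for a transposed table.
    sep
        Field separator; pass ``","`` for CSV exports.
    allow_float
        Accept non-integer values (for pre-normalized tables); the returned
        object records the relaxation in ``is_float``.
    spikein_prefix
        Gene-ID prefix marking spike-in control rows.

    Returns
    -------
    CountMatrix with sections sorted ascending regardless of file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, comment="#",
        float_precision="round_trip",
    )
    if genes_in == "columns":
        df = df.T
    elif genes_in != "rows":
        raise ValueError("genes_in must be 'rows' or 'columns'")

    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path.name}: {dupes[:5]}")

    try:
        sections = [int(c) for c in df.columns]
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"section header of {path.name} is not integer-sortable: "
            f"{list(df.columns)[:5]}"
        ) from exc

    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ValueError(
            f"missing value in {path.name} at gene {gene!r}, section {col}"
        )

    order = np.argsort(sections, kind="stable")
    sections = [sections[i] for i in order]
    values = df.to_numpy(dtype=float)[:, order]
    gene_ids = [str(g) for g in df.index]
    mask = np.array([g.startswith(spikein_prefix) for g in gene_ids])
    return CountMatrix(
        gene_ids=gene_ids,
        section_ids=sections,
        counts=values,
        spikein_mask=mask,
        is_float=allow_float,
    )


def split_spikeins(
    m: CountMatrix, prefix: str = DEFAULT_SPIKEIN_PREFIX
) -> tuple[CountMatrix, CountMatrix]:
    """Partition a matrix into (endogenous, spike-in) parts by ID prefix.

    The two outputs share the section axis, have disjoint gene sets and
    jointly exhaust the input.  Zero spike-in rows is a warning, not an
    error: spike-in normalization simply becomes unavailable downstream.
    """
    if not prefix:
        raise ValueError("spike-in prefix must be non-empty")
    is_spike = np.array([g.startswith(prefix) for g in m.gene_ids])
    if not is_spike.any():
        warnings.warn(
            f"no gene ids start with {prefix!r}; spike-in normalization "
            "will be unavailable",
            stacklevel=2,
        )
    endo = CountMatrix(
        gene_ids=[g for g, s in zip(m.gene_ids, is_spike) if not s],
        section_ids=list(m.section_ids),
        counts=m.counts[~is_spike],
        spikein_mask=np.zeros(int((~is_spike).sum()), dtype=bool),
        is_float=m.is_float,
    ) if (~is_spike).any() else _empty_like(m)
    spikes = CountMatrix(
        gene_ids=[g for g, s in zip(m.gene_ids, is_spike) if s],
        section_ids=list(m.section_ids),
        counts=m.counts[is_spike],
        spikein_mask=np.ones(int(is_spike.sum()), dtype=bool),
        is_float=m.is_float,
    ) if is_spike.any() else _empty_like(m)
    return endo, spikes


def _empty_like(m: CountMatrix) -> CountMatrix:
    out = CountMatrix.__new__(CountMatrix)
    out.gene_ids = []
    out.section_ids = list(m.section_ids)
    out.counts = np.zeros((0, m.n_sections))
    out.spikein_mask = np.zeros(0, dtype=bool)
    out.is_float = m.is_float
    return out


def write_matrix(m, path: str | Path, comments: list[str] | None = None) -> None:
    """Write a matrix-like object (CountMatrix / NormalizedMatrix / ZMatrix)
    as TSV with full float precision and input row order.

    ``comments`` (e.g. normalization provenance) are emitted as leading
    ``#``-prefixed lines.
    """
    path = Path(path)
    values = getattr(m, "counts", None)
    if values is None:
        values = getattr(m, "values_", None)
    if values is None:
        values = getattr(m, "z", None)
    if values is None:
        raise TypeError(f"cannot extract a value matrix from {type(m).__name__}")
    try:
        with open(path, "w") as fh:
            for line in comments or getattr(m, "provenance", None) or []:
                fh.write(f"# {line}\n")
            fh.write("gene\t" + "\t".join(str(s) for s in m.section_ids) + "\n")
            for gid, row in zip(m.gene_ids, values):
                fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write matrix to {path}: {exc}") from exc


def write_results_table(results, path: str | Path) -> None:
    """Write an enrichment result set as TSV.

    Row order is deterministic: descending \\|log2fc\\|, then ascending
    p-value, then gene ID.
    """
    path = Path(path)
    df = _sorted_results(results.table.copy())
    cols = ["gene_id", "mean_roi", "mean_rest", "log2fc", "pvalue", "significant"]
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for _, r in df.iterrows():
                fh.write(
                    f"{r.gene_id}\t{r.mean_roi!r}\t{r.mean_rest!r}\t"
                    f"{r.log2fc!r}\t{r.pvalue!r}\t{bool(r.significant)}\n"
                )
    except OSError as exc:
        raise OSError(f"failed to write results to {path}: {exc}") from exc


def _sorted_results(df: pd.DataFrame) -> pd.DataFrame:
    df = df.assign(_abs_fc=df["log2fc"].abs())
    df = df.sort_values(
        by=["_abs_fc", "pvalue", "gene_id"], ascending=[False, True, True]
    )
    return df.drop(columns="_abs_fc")
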