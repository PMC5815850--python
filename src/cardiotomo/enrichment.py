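"""Regional enrichment: genes upregulated in a section ROI versus the rest.

The test is a from-scratch negative-binomial exact test with a common
(shared) dispersion, the classical two-group construction for
overdispersed count data:

1.  Library sizes are equalized: every section's counts are scaled to the
    geometric mean of the section totals ("pseudo-counts").
2.  A single dispersion phi (variance = mu + phi * mu^2) is estimated by
    maximizing the negative-binomial conditional log-likelihood summed
    over genes, the likelihood of the within-group counts given each
    group's total, which is free of the per-gene mean.
3.  Per gene, the two group totals Y_A and Y_B are modeled as NB with
    group-size-scaled means and dispersion phi / k (the sum of k iid NB
    variables with common mean).  Conditioning on the grand total
    n = Y_A + Y_B, the exact p-value sums the conditional probabilities
    of every split (y, n - y) no more probable than the observed one.
    phi = 0 reduces the split distribution to a binomial.

Fold changes are computed on library-size-normalized per-section means
with a pseudocount; significance applies the thresholds
log2FC > fc_min and p < p_max to the raw p-values (no multiple-testing
correction by default; Benjamini-Hochberg available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata

from .io import CountMatrix

__all__ = [
    "ROI",
    "PAPER_ROIS",
    "DispersionEstimate",
    "EnrichmentResultSet",
    "estimate_common_dispersion",
    "nb_exact_test",
    "roi_enrichment",
    "enrichment_summary",
]

# The four cardiac sub-compartment ROIs of the dissected 2-dpf heart,
# as inclusive section-number ranges on the anterior-posterior axis.
PAPER_ROIS = {
    "ventricle": (12, 22),
    "av_canal": (19, 26),
    "atrium": (27, 37),
    "sinoatrial": (33, 39),
}

PHI_MAX = 10.0
_PHI_FLOOR = 1e-8  # numeric stand-in for phi = 0 during the search


@dataclass
class ROI:
    """A named, inclusive, contiguous range of 1-based section numbers."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"ROI {self.name}: start > end")

    @classmethod
    def parse(cls, text: str) -> "ROI":
        """Parse ``"name:start-end"``, e.g. ``"sinoatrial:33-39"``."""
        try:
            name, span = text.split(":")
            a, b = span.split("-")
            return cls(name, int(a), int(b))
        except ValueError:
            raise ValueError(
                f"cannot parse ROI {text!r}; expected name:start-end"
            ) from None

    def mask(self, section_ids: list[int]) -> np.ndarray:
        m = np.array([self.start <= s <= self.end for s in section_ids])
        covered = [s for s in range(self.start, self.end + 1)]
        present = set(section_ids)
        missing = [s for s in covered if s not in present]
        if missing:
            raise ValueError(
                f"ROI {self.name} sections {missing} absent from matrix"
            )
        return m


@dataclass
class DispersionEstimate:
    phi: float
    method: str
    n_genes_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi) or self.phi < 0:
            raise ValueError("dispersion must be finite and >= 0")


@dataclass
class EnrichmentResultSet:
    """Per-gene enrichment results for one ROI.

    ``table`` columns: gene_id, mean_roi, mean_rest, log2fc, pvalue,
    significant.  significant <=> log2fc > fc_min and pvalue < p_max
    (on BH-adjusted p when ``bh`` was requested).
    """

    roi: ROI
    table: pd.DataFrame
    fc_min: float
    p_max: float
    dispersion: DispersionEstimate
    pseudocount: float = 1.0
    bh: bool = False

    @property
    def significant_ids(self) -> set[str]:
        t = self.table
        return set(t.loc[t["significant"], "gene_id"])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def equalize_libraries(
    counts: np.ndarray, lib_sizes: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Scale each section's counts to the geometric mean library size.

    Returns (pseudo-counts, common library size).
    """
    counts = np.asarray(counts, dtype=float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must all be > 0")
    common = float(np.exp(np.mean(np.log(lib_sizes))))
    return counts * (common / lib_sizes), common


def _conditional_loglik(pseudo: np.ndarray, group_masks, phi: float) -> float:
    """NB conditional log-likelihood of within-group counts given group
    totals, summed over genes and groups; per-gene means cancel out."""
    r = 1.0 / phi
    total = 0.0
    for mask in group_masks:
        y = pseudo[:, mask]
        k = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - y.size * gammaln(r)
            - np.sum(gammaln(y + 1.0))
            - np.sum(gammaln(z + k * r)) + len(z) * gammaln(k * r)
            + np.sum(gammaln(z + 1.0))
        )
    return total


def estimate_common_dispersion(
    m: CountMatrix | np.ndarray,
    groups: np.ndarray,
    lib_sizes: np.ndarray | None = None,
    min_total: float = 1.0,
) -> DispersionEstimate:
    """Maximize the summed conditional log-likelihood over a single phi.

    ``groups`` is a boolean (or two-label) array over sections splitting
    them into the two comparison groups; each group needs >= 2 sections.
    The search is a coarse log-scale grid followed by golden-section
    refinement to a relative tolerance of 1e-4, bounded to [0, 10].
    Genes with total pseudo-count below ``min_total`` carry no
    information and are dropped.
    """
    counts = m.counts if isinstance(m, CountMatrix) else np.asarray(m, float)
    groups = np.asarray(groups)
    if groups.dtype != bool:
        labels = np.unique(groups)
        if len(labels) != 2:
            raise ValueError("groups must define exactly 2 section groups")
        groups = groups == labels[0]
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise ValueError("each group needs at least 2 sections")

    pseudo, _ = equalize_libraries(counts, lib_sizes)
    keep = pseudo.sum(axis=1) >= min_total
    pseudo = pseudo[keep]
    if pseudo.shape[0] == 0:
        raise ValueError("no informative genes for dispersion estimation")
    masks = (groups, ~groups)

    grid = np.concatenate(([_PHI_FLOOR], np.logspace(-4, np.log10(PHI_MAX), 25)))
    ll = np.array([_conditional_loglik(pseudo, masks, p) for p in grid])
    i = int(np.argmax(ll))
    if i == 0:
        return DispersionEstimate(0.0, "qcml", pseudo.shape[0])
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]

    # golden-section on log(phi)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = math.log(lo), math.log(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _conditional_loglik(pseudo, masks, math.exp(c))
    fd = _conditional_loglik(pseudo, masks, math.exp(d))
    while b - a > 1e-4:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _conditional_loglik(pseudo, masks, math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _conditional_loglik(pseudo, masks, math.exp(d))
    phi = math.exp((a + b) / 2.0)
    if phi <= _PHI_FLOOR * 10:
        phi = 0.0
    return DispersionEstimate(min(phi, PHI_MAX), "qcml", pseudo.shape[0])


def _group_total_logpmf(
    y: np.ndarray, k: int, mean_per_lib: float, phi: float
) -> np.ndarray:
    """log P(group total = y) for the sum of k iid NB(mean_per_lib, phi):
    NB with mean k * mean_per_lib and dispersion phi / k."""
    mu = k * mean_per_lib
    if phi == 0.0:
        # Poisson limit
        return y * math.log(mu) - mu - gammaln(y + 1.0)
    r = k / phi
    p_log = math.log(r) - math.log(r + mu)  # log(1-p_success of numpy param)
    q_log = math.log(mu) - math.log(r + mu)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * p_log + y * q_log
    )


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float,
    lib_sizes: np.ndarray | None = None,
    method: str = "smallp",
) -> float:
    """Two-sided exact p-value for a difference in NB means between two
    groups of sections sharing dispersion ``phi``.

    Counts are first scaled to a common effective library size (geometric
    mean of ``lib_sizes`` when given).  Conditioning on the (rounded)
    grand total n, the null conditional distribution over splits
    (y, n - y) is formed from the two group-total NB laws with equal
    per-library mean; ``method="smallp"`` sums all splits whose
    probability does not exceed the observed split's, ``method="doubled"``
    doubles the smaller tail.  Either way p is capped at 1.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    ka, kb = len(counts_a), len(counts_b)
    if lib_sizes is not None:
        lib_sizes = np.asarray(lib_sizes, dtype=float)
        if len(lib_sizes) != ka + kb:
            raise ValueError("lib_sizes must cover both groups (a then b)")
        common = float(np.exp(np.mean(np.log(lib_sizes))))
        scaled = np.concatenate([counts_a, counts_b]) * (common / lib_sizes)
        counts_a, counts_b = scaled[:ka], scaled[ka:]

    ya = float(np.round(counts_a.sum()))
    yb = float(np.round(counts_b.sum()))
    n = int(ya + yb)
    if n == 0:
        return 1.0

    mean_per_lib = n / (ka + kb)
    y = np.arange(n + 1, dtype=float)
    logp = (
        _group_total_logpmf(y, ka, mean_per_lib, phi)
        + _group_total_logpmf(n - y, kb, mean_per_lib, phi)
    )
    logp -= np.max(logp)
    probs = np.exp(logp)
    probs /= probs.sum()

    obs = int(ya)
    if method == "smallp":
        p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    elif method == "doubled":
        lower = float(probs[: obs + 1].sum())
        upper = float(probs[obs:].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(p, 1.0)


def roi_enrichment(
    m: CountMatrix,
    roi: ROI,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    pseudocount: float = 1.0,
    phi: float | None = None,
    exclude_sections: list[int] | None = None,
    bh: bool = False,
    method: str = "smallp",
) -> EnrichmentResultSet:
    """Test every gene for upregulation in ``roi`` versus all remaining
    sections of the matrix.

    The complement is every other loaded section (optionally minus
    ``exclude_sections``).  A common dispersion is estimated once per run
    unless ``phi`` is supplied.  log2fc uses library-size-normalized
    per-section means with ``pseudocount``.
    """
    section_ids = list(m.section_ids)
    if exclude_sections:
        keep = [s not in exclude_sections for s in section_ids]
        idx = np.array(keep)
        m = CountMatrix(
            gene_ids=list(m.gene_ids),
            section_ids=[s for s, k in zip(section_ids, keep) if k],
            counts=m.counts[:, idx],
            spikein_mask=m.spikein_mask,
            is_float=True,
        )
        section_ids = list(m.section_ids)

    in_roi = roi.mask(section_ids)
    if in_roi.sum() < 2 or (~in_roi).sum() < 2:
        raise ValueError(
            f"ROI {roi.name} and its complement each need >= 2 sections"
        )

    lib = m.counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero-total sections; drop them before testing")

    if phi is None:
        disp = estimate_common_dispersion(m, in_roi, lib_sizes=lib)
    else:
        disp = DispersionEstimate(phi, "fixed", m.n_genes)

    pseudo, _ = equalize_libraries(m.counts, lib)
    mean_roi = pseudo[:, in_roi].mean(axis=1)
    mean_rest = pseudo[:, ~in_roi].mean(axis=1)
    log2fc = np.log2((mean_roi + pseudocount) / (mean_rest + pseudocount))

    pvals = np.array(
        [
            nb_exact_test(
                pseudo[g, in_roi], pseudo[g, ~in_roi], disp.phi, method=method
            )
            for g in range(m.n_genes)
        ]
    )
    p_eff = _bh_adjust(pvals) if bh else pvals
    significant = (log2fc > fc_min) & (p_eff < p_max)
    table = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "mean_roi": mean_roi,
            "mean_rest": mean_rest,
            "log2fc": log2fc,
            "pvalue": p_eff,
            "significant": significant,
        }
    )
    return EnrichmentResultSet(
        roi, table, fc_min, p_max, disp, pseudocount, bh
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    ranks = rankdata(p, method="max")
    adj = p * n / ranks
    # enforce monotonicity from the largest p downwards
    order = np.argsort(p)[::-1]
    running = 1.0
    out = np.empty_like(adj)
    for i in order:
        running = min(running, adj[i])
        out[i] = running
    return np.minimum(out, 1.0)


def enrichment_summary(results: list[EnrichmentResultSet]) -> pd.DataFrame:
    """Per-ROI significant counts plus the size of the union of
    significant gene sets across ROIs (last row, roi = "union")."""
    if not results:
        raise ValueError("need at least one result set")
    rows = []
    union: set[str] = set()
    for r in results:
        sig = r.significant_ids
        union |= sig
        rows.append({"roi": r.roi.name, "start": r.roi.start,
                     "end": r.roi.end, "n_significant": len(sig)})
    rows.append({"roi": "union", "start": None, "end": None,
                 "n_significant": len(union)})
    return pd.DataFrame(rows)
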