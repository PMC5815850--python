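"""Synthetic serial-section heart datasets with known ground truth.

The generator emulates the statistical structure of a tomo-seq experiment
on a 2-dpf zebrafish heart: ~40 cryosections along the anterior-posterior
axis, a few thousand genes, contiguous anatomical compartments each with
marker genes peaking inside them, negative-binomial count noise, a
per-section multiplicative capture-efficiency factor (the technical bias
spike-in normalization corrects), and ERCC-like spike-ins whose expected
input is constant across sections.

Counts are drawn as NB(mean = e_s * mu_g(s), variance = mu + phi*mu^2)
with the efficiency factor e_s ~ Uniform(efficiency_range) fixed per
section and applied identically to endogenous genes and spike-ins — the
assumption that makes spike-in normalization identifiable.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "CompartmentSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate_heart",
    "worked_toy",
    "load_config",
]


@dataclass
class CompartmentSpec:
    """One anatomical compartment: a section span plus its marker genes.

    ``peak_height`` is the mean fold-elevation of marker expression over
    baseline inside the compartment; ``peak_shape`` is ``"plateau"``
    (flat elevation across the span) or ``"gaussian"`` (bump centered on
    the span midpoint with SD ``shape_width`` sections).
    """

    name: str
    span: tuple[int, int]
    n_markers: int = 25
    peak_height: float = 8.0
    peak_shape: str = "plateau"
    shape_width: float = 2.0

    def __post_init__(self) -> None:
        if self.span[0] > self.span[1]:
            raise ValueError(f"compartment {self.name}: inverted span")
        if self.n_markers < 0:
            raise ValueError("n_markers must be >= 0")
        if self.peak_height <= 1:
            raise ValueError("peak_height must exceed 1 (fold over baseline)")
        if self.peak_shape not in ("plateau", "gaussian"):
            raise ValueError("peak_shape must be 'plateau' or 'gaussian'")


def _default_compartments() -> list[CompartmentSpec]:
    # The four cardiac sub-compartments used for regional enrichment;
    # the sinoatrial region deliberately overlaps the atrium, as in the
    # real heart.
    return [
        CompartmentSpec("ventricle", (12, 22)),
        CompartmentSpec("av_canal", (19, 26)),
        CompartmentSpec("atrium", (27, 37)),
        CompartmentSpec("sinoatrial", (33, 39)),
    ]


@dataclass
class SyntheticConfig:
    n_sections: int = 40
    compartments: list[CompartmentSpec] = field(
        default_factory=_default_compartments
    )
    n_background_genes: int = 2000
    baseline_mean: float = 20.0
    nb_dispersion: float = 0.2
    efficiency_range: tuple[float, float] = (0.5, 2.0)
    n_spikeins: int = 92
    spikein_mean: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise ValueError("need at least 2 sections")
        if self.baseline_mean <= 0 or self.spikein_mean <= 0:
            raise ValueError("all means must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        lo, hi = self.efficiency_range
        if lo <= 0 or hi < lo:
            raise ValueError("efficiency_range must be positive and ordered")
        for c in self.compartments:
            if not (1 <= c.span[0] and c.span[1] <= self.n_sections):
                raise ValueError(
                    f"compartment {c.name} span {c.span} outside "
                    f"[1, {self.n_sections}]"
                )
            if c.span[1] < c.span[0] and c.n_markers > 0:
                raise ValueError(f"empty compartment {c.name} with markers")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset.

    ``assignments`` maps every generated gene to its compartment (or
    ``"background"`` / ``"spikein"``); ``efficiency`` holds the
    per-section capture factors e_s; ``mu`` the expected-expression
    profile mu_g(s) per gene (before efficiency).
    """

    assignments: pd.DataFrame  # gene_id, compartment
    efficiency: np.ndarray
    mu: np.ndarray
    section_ids: list[int]

    def markers_of(self, compartment: str) -> list[str]:
        a = self.assignments
        return a.loc[a["compartment"] == compartment, "gene_id"].tolist()

    def write(self, path: str | Path) -> None:
        path = Path(path)
        df = self.assignments.copy()
        for j, s in enumerate(self.section_ids):
            df[f"mu_{s}"] = self.mu[:, j]
        eff = "\t".join(repr(float(e)) for e in self.efficiency)
        with open(path, "w") as fh:
            fh.write("# efficiency\t" + eff + "\n")
            df.to_csv(fh, sep="\t", index=False)


def default_config(**overrides) -> SyntheticConfig:
    """The reference simulated heart: 40 sections, 4 overlapping
    compartments with 25 plateau markers each (8-fold elevation),
    2000 background genes, phi = 0.2, efficiency in [0.5, 2],
    92 constant-input spike-ins."""
    return SyntheticConfig(**overrides)


def _profile(
    comp: CompartmentSpec, sections: np.ndarray, baseline: float
) -> np.ndarray:
    lo, hi = comp.span
    if comp.peak_shape == "plateau":
        mu = np.where(
            (sections >= lo) & (sections <= hi),
            baseline * comp.peak_height,
            baseline,
        )
    else:
        center = (lo + hi) / 2.0
        bump = np.exp(-((sections - center) ** 2) / (2 * comp.shape_width**2))
        mu = baseline * (1.0 + (comp.peak_height - 1.0) * bump)
    return mu.astype(float)


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mean).astype(float)
    # NB via gamma-Poisson mixture: shape 1/phi, scale phi*mean
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam).astype(float)


def generate_heart(cfg: SyntheticConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one synthetic heart dataset.

    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    sections = np.arange(1, cfg.n_sections + 1)

    gene_ids: list[str] = []
    compartment_of: list[str] = []
    mu_rows: list[np.ndarray] = []
    for comp in cfg.compartments:
        prof = _profile(comp, sections, cfg.baseline_mean)
        for i in range(comp.n_markers):
            gene_ids.append(f"{comp.name}_m{i + 1:03d}")
            compartment_of.append(comp.name)
            mu_rows.append(prof)
    for i in range(cfg.n_background_genes):
        gene_ids.append(f"bg_{i + 1:05d}")
        compartment_of.append("background")
        mu_rows.append(np.full(cfg.n_sections, cfg.baseline_mean))
    for i in range(cfg.n_spikeins):
        gene_ids.append(f"ERCC-{i + 1:05d}")
        compartment_of.append("spikein")
        mu_rows.append(np.full(cfg.n_sections, cfg.spikein_mean))

    mu = np.vstack(mu_rows)
    lo, hi = cfg.efficiency_range
    efficiency = rng.uniform(lo, hi, size=cfg.n_sections)
    counts = _draw_counts(rng, mu * efficiency[None, :], cfg.nb_dispersion)

    spike_mask = np.array([c == "spikein" for c in compartment_of])
    matrix = CountMatrix(
        gene_ids=gene_ids,
        section_ids=list(map(int, sections)),
        counts=counts,
        spikein_mask=spike_mask,
    )
    truth = GroundTruth(
        assignments=pd.DataFrame(
            {"gene_id": gene_ids, "compartment": compartment_of}
        ),
        efficiency=efficiency,
        mu=mu,
        section_ids=list(map(int, sections)),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Worked toy: 8 sections, 12 genes (10 endogenous + 2 spike-ins), two
# compartments ("head" sections 2-4, "tail" sections 6-8, 2 plateau markers
# each at 8x a baseline of 10), fixed by hand so documentation examples and
# exact-value tests need no random draws.  Column totals over endogenous
# genes: 100, 240, 240, 250, 110, 240, 250, 250.

_TOY_SECTIONS = [1, 2, 3, 4, 5, 6, 7, 8]
_TOY_COUNTS = {
    "head_m001": [10, 80, 75, 85, 10, 10, 10, 10],
    "head_m002": [10, 75, 80, 80, 10, 12, 10, 10],
    "tail_m001": [10, 10, 10, 10, 12, 80, 85, 80],
    "tail_m002": [10, 12, 10, 10, 10, 75, 80, 85],
    "bg_00001": [10, 10, 10, 12, 10, 10, 10, 10],
    "bg_00002": [12, 10, 10, 10, 10, 10, 12, 10],
    "bg_00003": [10, 12, 10, 10, 12, 10, 10, 10],
    "bg_00004": [10, 10, 12, 10, 10, 10, 10, 12],
    "bg_00005": [8, 10, 10, 12, 12, 11, 12, 11],
    "bg_00006": [10, 11, 13, 11, 14, 12, 11, 12],
    "ERCC-00001": [30, 32, 30, 28, 30, 30, 32, 30],
    "ERCC-00002": [30, 28, 30, 30, 28, 30, 28, 30],
}
_TOY_COMPARTMENTS = {
    "head_m001": "head",
    "head_m002": "head",
    "tail_m001": "tail",
    "tail_m002": "tail",
}
TOY_SPANS = {"head": (2, 4), "tail": (6, 8)}


def worked_toy() -> tuple[CountMatrix, GroundTruth]:
    """A fixed, seed-free 8-section, 12-gene instance for documentation
    and exact-value tests."""
    gene_ids = list(_TOY_COUNTS)
    counts = np.array([_TOY_COUNTS[g] for g in gene_ids], dtype=float)
    spike_mask = np.array([g.startswith("ERCC-") for g in gene_ids])
    matrix = CountMatrix(
        gene_ids=gene_ids,
        section_ids=list(_TOY_SECTIONS),
        counts=counts,
        spikein_mask=spike_mask,
    )
    mu = []
    compartment_of = []
    sections = np.arange(1, 9)
    for g in gene_ids:
        if g in _TOY_COMPARTMENTS:
            comp = _TOY_COMPARTMENTS[g]
            compartment_of.append(comp)
            spec = CompartmentSpec(comp, TOY_SPANS[comp], peak_height=8.0)
            mu.append(_profile(spec, sections, 10.0))
        elif g.startswith("ERCC-"):
            compartment_of.append("spikein")
            mu.append(np.full(8, 30.0))
        else:
            compartment_of.append("background")
            mu.append(np.full(8, 10.0))
    truth = GroundTruth(
        assignments=pd.DataFrame(
            {"gene_id": gene_ids, "compartment": compartment_of}
        ),
        efficiency=np.ones(8),
        mu=np.vstack(mu),
        section_ids=list(_TOY_SECTIONS),
    )
    return matrix, truth


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a simulation config from a TOML file.

    Flat keys mirror :class:`SyntheticConfig`; compartments are
    ``[[compartment]]`` tables with name/span/n_markers/... keys.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    comp_raw = raw.pop("compartment", None)
    kwargs = dict(raw)
    if "efficiency_range" in kwargs:
        kwargs["efficiency_range"] = tuple(kwargs["efficiency_range"])
    if comp_raw is not None:
        kwargs["compartments"] = [
            CompartmentSpec(
                name=c["name"],
                span=tuple(c["span"]),
                n_markers=c.get("n_markers", 25),
                peak_height=c.get("peak_height", 8.0),
                peak_shape=c.get("peak_shape", "plateau"),
                shape_width=c.get("shape_width", 2.0),
            )
            for c in comp_raw
        ]
    return SyntheticConfig(**kwargs)
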