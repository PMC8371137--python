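"""Synthetic data generators with planted ground truth.

Three generators emulate the statistical structure of the experiments the
toolkit analyses, so every downstream stage is testable without external
data:

* :func:`generate_counts` — negative-binomial (gamma-Poisson) UMI counts for
  discrete cell types with disjoint marker programs, plus a latent
  border-proximity gradient that scales a planted gene program up or down.
* :func:`generate_fluorescence_field` — pre/post photoactivation intensity
  grids with circular cells, a nuclei channel and a rectangular activation
  mask; cells inside the mask brighten by a known uncaging factor.
* :func:`generate_flow_events` — flow-cytometry event tables where tagged
  and background populations cross a fluorescence gate at configured rates.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "SimCountConfig",
    "SimTruth",
    "SimImageConfig",
    "SimFlowConfig",
    "generate_counts",
    "generate_fluorescence_field",
    "generate_flow_events",
]


class ConfigurationError(ValueError):
    """A generator config violates one of its invariants."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {message}")


@dataclass
class SimCountConfig:
    """Parameters for the count generator.

    nb_mean is the expected UMI count of an unperturbed gene in one cell;
    nb_dispersion is the gamma shape (variance = m + m^2/dispersion);
    border_effect is a log-fold-change amplitude applied along the latent
    border-proximity gradient.
    """

    n_genes: int = 800
    n_cells: int = 500
    n_cell_types: int = 5
    markers_per_type: int = 10
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    border_program_size: int = 250
    border_effect: float = 1.0
    border_fraction: float = 0.3
    marker_fold: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_genes > 0, "n_genes", "must be positive")
        _require(self.n_cells > 0, "n_cells", "must be positive")
        _require(self.n_cell_types > 0, "n_cell_types", "must be positive")
        _require(self.markers_per_type > 0, "markers_per_type", "must be positive")
        _require(self.nb_mean > 0, "nb_mean", "must be positive")
        _require(self.nb_dispersion > 0, "nb_dispersion", "must be positive")
        _require(self.border_program_size >= 0, "border_program_size",
                 "must be non-negative")
        _require(0 <= self.border_fraction <= 1, "border_fraction",
                 "must be in [0, 1]")
        _require(self.marker_fold > 0, "marker_fold", "must be positive")
        needed = self.n_cell_types * self.markers_per_type + self.border_program_size
        _require(needed <= self.n_genes, "n_genes",
                 f"need at least {needed} genes for disjoint marker and "
                 "border programs")


@dataclass
class SimTruth:
    """Latent ground truth planted by :func:`generate_counts`."""

    cell_type: pd.Series
    border_proximity: pd.Series
    region_label: pd.Series
    program_genes_up: list = field(default_factory=list)
    program_genes_down: list = field(default_factory=list)
    marker_genes: dict = field(default_factory=dict)


def generate_counts(cfg: SimCountConfig):
    """Draw a planted-structure count matrix.

    Returns ``(CountMatrix, metadata DataFrame, SimTruth)``. Counts are
    gamma-Poisson: per entry, rate ~ Gamma(shape=dispersion,
    scale=mean/dispersion), count ~ Poisson(rate). Marker genes have their
    mean multiplied by ``marker_fold`` in their own cell type; border-program
    genes have their mean scaled by exp(+/- border_effect * proximity).
    Border-region cells draw proximity ~ Uniform(0, 1); whole-region cells
    draw proximity ~ Beta(1, 3) (skewed toward 0), so the labeled border is
    stochastically closer to the border without a hard boundary.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = np.array([f"gene{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    cells = np.array([f"cell{i:04d}" for i in range(cfg.n_cells)], dtype=object)

    cell_type = rng.integers(0, cfg.n_cell_types, size=cfg.n_cells)
    n_border = int(round(cfg.border_fraction * cfg.n_cells))
    region = np.array(["whole"] * cfg.n_cells, dtype=object)
    border_idx = rng.choice(cfg.n_cells, size=n_border, replace=False)
    region[border_idx] = "border"
    proximity = rng.beta(1.0, 3.0, size=cfg.n_cells)
    proximity[border_idx] = rng.uniform(0.0, 1.0, size=n_border)

    # disjoint gene blocks: [markers per type ...][program up][program down]
    marker_genes = {}
    pos = 0
    for t in range(cfg.n_cell_types):
        marker_genes[t] = list(genes[pos:pos + cfg.markers_per_type])
        pos += cfg.markers_per_type
    n_up = cfg.border_program_size // 2
    n_down = cfg.border_program_size - n_up
    up_idx = np.arange(pos, pos + n_up)
    down_idx = np.arange(pos + n_up, pos + n_up + n_down)

    mean = np.full((cfg.n_genes, cfg.n_cells), cfg.nb_mean, dtype=float)
    for t, names in marker_genes.items():
        rows = slice(t * cfg.markers_per_type, (t + 1) * cfg.markers_per_type)
        mean[rows, cell_type == t] *= cfg.marker_fold
    if cfg.border_program_size:
        mean[up_idx, :] *= np.exp(cfg.border_effect * proximity)[None, :]
        mean[down_idx, :] *= np.exp(-cfg.border_effect * proximity)[None, :]

    lam = rng.gamma(shape=cfg.nb_dispersion,
                    scale=mean / cfg.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    matrix = CountMatrix(sp.csr_matrix(counts), genes, cells)
    truth = SimTruth(
        cell_type=pd.Series(cell_type, index=cells, name="cell_type"),
        border_proximity=pd.Series(proximity, index=cells,
                                   name="border_proximity"),
        region_label=pd.Series(region, index=cells, name="region_label"),
        program_genes_up=list(genes[up_idx]),
        program_genes_down=list(genes[down_idx]),
        marker_genes=marker_genes,
    )
    meta = pd.DataFrame(
        {
            "region_label": truth.region_label,
            "cell_type": [f"type{t}" for t in cell_type],
            "total_counts": matrix.cell_totals(),
            "n_genes_detected": matrix.genes_per_cell(),
        },
        index=pd.Index(cells, name="cell"),
    )
    return matrix, meta, truth


@dataclass
class SimImageConfig:
    """Parameters for the fluorescence field generator.

    mask_rect is a half-open rectangle (r0, r1, c0, c1) in 0-based pixel
    coordinates; cells whose centroid falls inside are photoactivated and
    their post image scales by uncaging_factor. Gaussian pixel noise is
    truncated at zero.
    """

    field_shape: tuple = (256, 256)
    n_cells: int = 50
    cell_radius: float = 5.0
    baseline_intensity: float = 200.0
    uncaging_factor: float = 3.0
    noise_sd: float = 0.0
    mask_rect: tuple = (0, 128, 0, 256)
    seed: int = 0
    min_separation: float = None  # default 2*radius + 2

    def validate(self) -> None:
        _require(len(self.field_shape) == 2 and min(self.field_shape) > 0,
                 "field_shape", "must be two positive dimensions")
        _require(self.n_cells > 0, "n_cells", "must be positive")
        _require(self.cell_radius > 0, "cell_radius", "must be positive")
        _require(self.baseline_intensity > 0, "baseline_intensity",
                 "must be positive")
        _require(self.uncaging_factor >= 1, "uncaging_factor", "must be >= 1")
        _require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        r0, r1, c0, c1 = self.mask_rect
        _require(0 <= r0 < r1 <= self.field_shape[0]
                 and 0 <= c0 < c1 <= self.field_shape[1],
                 "mask_rect", "must lie within the field")


def generate_fluorescence_field(cfg: SimImageConfig):
    """Render pre/post photoactivation images plus nuclei and mask.

    Returns ``(image_pre, image_post, nuclei, mask, truth)`` where truth is
    a per-cell DataFrame with centroid, in_mask flag and true intensities.
    Cell centers are placed by seeded rejection sampling so discs do not
    overlap (minimum separation 2*radius + 2 px by default).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.field_shape
    r = cfg.cell_radius
    min_sep = cfg.min_separation if cfg.min_separation is not None else 2 * r + 2

    centers = []
    attempts = 0
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > 20000 * cfg.n_cells:
            raise ConfigurationError(
                "n_cells: could not place non-overlapping cells in the field"
            )
        cand = (rng.uniform(r + 1, h - r - 1), rng.uniform(r + 1, w - r - 1))
        if all((cand[0] - cy) ** 2 + (cand[1] - cx) ** 2 >= min_sep ** 2
               for cy, cx in centers):
            centers.append(cand)
    centers = np.array(centers)

    rows, cols = np.mgrid[0:h, 0:w]
    pre = np.zeros((h, w), dtype=float)
    nuclei = np.zeros((h, w), dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    r0, r1, c0, c1 = cfg.mask_rect
    mask[r0:r1, c0:c1] = True

    in_mask = []
    for cy, cx in centers:
        disc = (rows - cy) ** 2 + (cols - cx) ** 2 <= r ** 2
        pre[disc] = cfg.baseline_intensity
        nuc = (rows - cy) ** 2 + (cols - cx) ** 2 <= (r / 2.0) ** 2
        nuclei[nuc] = cfg.baseline_intensity
        in_mask.append(bool(mask[int(round(cy)), int(round(cx))]))
    in_mask = np.array(in_mask)

    post = pre.copy()
    for (cy, cx), inside in zip(centers, in_mask):
        if inside:
            disc = (rows - cy) ** 2 + (cols - cx) ** 2 <= r ** 2
            post[disc] = cfg.baseline_intensity * cfg.uncaging_factor

    if cfg.noise_sd > 0:
        pre = np.clip(pre + rng.normal(0, cfg.noise_sd, pre.shape), 0, None)
        post = np.clip(post + rng.normal(0, cfg.noise_sd, post.shape), 0, None)
        nuclei = np.clip(nuclei + rng.normal(0, cfg.noise_sd, nuclei.shape),
                         0, None)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(cfg.n_cells),
            "centroid_row": centers[:, 0],
            "centroid_col": centers[:, 1],
            "in_mask": in_mask,
            "true_pre": np.full(cfg.n_cells, cfg.baseline_intensity),
            "true_post": np.where(in_mask,
                                  cfg.baseline_intensity * cfg.uncaging_factor,
                                  cfg.baseline_intensity),
        }
    )
    return pre, post, nuclei, mask, truth


@dataclass
class SimFlowConfig:
    """Parameters for the flow-event generator.

    Defaults mirror a species-mixing sort: half the events come from the
    tagged population, tagged cells cross the gate at ~9% and untagged
    background at 0.19% (the measured false-positive rate of a
    non-photoactivated control in the FITC channel).
    """

    n_events: int = 100_000
    frac_target: float = 0.5
    tagged_positive_rate: float = 0.0872
    background_fp_rate: float = 0.0019
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_events > 0, "n_events", "must be positive")
        for name in ("frac_target", "tagged_positive_rate", "background_fp_rate"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must be in [0, 1]")


def generate_flow_events(cfg: SimFlowConfig) -> pd.DataFrame:
    """Draw a seeded flow-event table with columns true_label, gate_positive."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    is_target = rng.random(cfg.n_events) < cfg.frac_target
    rate = np.where(is_target, cfg.tagged_positive_rate, cfg.background_fp_rate)
    positive = rng.random(cfg.n_events) < rate
    return pd.DataFrame(
        {
            "true_label": np.where(is_target, "target", "background"),
            "gate_positive": positive,
        }
    )
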