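"""Synthetic inputs for every pipeline stage, with retained ground truth.

The study's raw data (microarray intensities, spheroid micrographs,
sequencing reads, microfluidic recordings) are not redistributable, so each
generator here emulates one input class with explicit, seedable randomness
and returns its ground-truth object alongside the data:

* :func:`gen_expression` — a 3-group log2 expression matrix (parental /
  TMD / BMD, 3 replicates each by default) with planted axis-separating
  genes and i.i.d. Gaussian noise on the log2 scale;
* :func:`gen_spheroid_image` — a grayscale spheroid image whose boundary is
  an ellipse modulated by low-order radial Fourier harmonics, so harmonic
  amplitude is a direct roughness dial;
* :func:`gen_scratch_pair` — before/after cell-free masks of a wound-healing
  scratch with a prescribed closure fraction;
* :func:`gen_variant_table` — an annotated somatic variant table in the
  five-column TSV dialect (symbol, description, allele_freq, base_change,
  aa_change);
* :func:`gen_passing_times` — per-cell microfluidic channel transit times
  drawn from a log-normal (log-location-scale) family.

Every generator is a pure function of its parameters and a mandatory seed;
downstream analysis code never reads the truth objects — only tests do.
All generator defaults are stand-ins: the source study publishes no
distributional information about its arrays or images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .axis import ExpressionMatrix

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = list("ACGT")


@dataclass
class ExpressionTruth:
    """Ground truth of a generated expression matrix.

    planted_axis_genes maps gene id -> signed log2 effect (TMD minus BMD);
    planted_pc1_genes maps gene id -> per-step log2 increment of a monotone
    parental -> TMD -> BMD trend.  group_means holds the true per-group mean
    of every planted gene.
    """

    planted_axis_genes: dict[str, float]
    planted_pc1_genes: dict[str, float]
    noise_sd: float
    group_means: pd.DataFrame

    def __post_init__(self) -> None:
        overlap = set(self.planted_axis_genes) & set(self.planted_pc1_genes)
        if overlap:
            raise ValueError(f"planted gene sets overlap: {sorted(overlap)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SpheroidTruth:
    """Parametric spheroid boundary: ellipse x radial Fourier perturbation.

    r(theta) = s(theta) * (1 + sum_k a_k cos(k theta + phi_k)) where
    s(theta) is the radial profile of an ellipse with semi-axes
    (base_radius * axis_ratio, base_radius) rotated by ``orientation``.
    """

    base_radius: float
    axis_ratio: float = 1.0
    orientation: float = 0.0
    boundary_harmonics: Sequence[tuple[int, float, float]] = ()
    center: tuple[float, float] | None = None  # (row, col)

    def __post_init__(self) -> None:
        if self.base_radius < 5:
            raise ValueError("base_radius must be >= 5 px")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1")
        amp = sum(abs(a) for _, a, _ in self.boundary_harmonics)
        if amp >= 1:
            raise ValueError(
                "sum of |harmonic amplitudes| must be < 1 to keep the "
                "boundary star-shaped"
            )

    @property
    def semi_major(self) -> float:
        return self.base_radius * self.axis_ratio

    @property
    def semi_minor(self) -> float:
        return self.base_radius

    def radius(self, theta: np.ndarray) -> np.ndarray:
        """Boundary radius at polar angle(s) theta (x = col, y = row frame)."""
        a, b = self.semi_major, self.semi_minor
        t = theta - self.orientation
        s = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        mod = np.ones_like(s)
        for k, amp, phase in self.boundary_harmonics:
            mod = mod + amp * np.cos(k * theta + phase)
        return s * mod


def gen_expression(
    n_genes: int,
    n_reps_per_group: int = 3,
    axis_effects: Sequence[float] = (),
    pc1_effects: Sequence[float] = (),
    noise_sd: float = 0.5,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Simulate a grouped log2 expression matrix with planted signal genes.

    Each planted axis gene g with signed effect e gets true group means
    base+e/2 (TMD), base-e/2 (BMD) and base (parental), so the TMD - BMD
    contrast equals e exactly.  Planted PC1 genes follow a monotone
    parental -> TMD -> BMD trend with the given per-step increment.
    Unplanted genes share one mean across all groups.  Gaussian noise of SD
    ``noise_sd`` (log2 units) is added i.i.d.
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_reps_per_group < 2:
        raise ValueError("n_reps_per_group must be >= 2")
    n_planted = len(axis_effects) + len(pc1_effects)
    if n_planted > n_genes:
        raise ValueError("more planted genes than genes")
    if not all(np.isfinite(axis_effects)) or not all(np.isfinite(pc1_effects)):
        raise ValueError("effects must be finite")

    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    gene_ids = [f"GENE{i:0{width}d}" for i in range(1, n_genes + 1)]
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    axis_ids = [gene_ids[i] for i in planted_idx[: len(axis_effects)]]
    pc1_ids = [gene_ids[i] for i in planted_idx[len(axis_effects):]]

    groups_order = ["parental", "TMD", "BMD"]
    sample_ids = [
        f"{g}_{r}" for g in groups_order for r in range(1, n_reps_per_group + 1)
    ]
    group_of = pd.Series(
        [g for g in groups_order for _ in range(n_reps_per_group)],
        index=sample_ids,
    )

    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    means = np.tile(base[:, None], (1, 3))  # columns parental, TMD, BMD
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for gid, eff in zip(axis_ids, axis_effects):
        i = gene_pos[gid]
        means[i, 1] = base[i] + eff / 2.0
        means[i, 2] = base[i] - eff / 2.0
    for gid, step in zip(pc1_ids, pc1_effects):
        i = gene_pos[gid]
        means[i, 0] = base[i] - step
        means[i, 2] = base[i] + step

    col_group = np.array([groups_order.index(g) for g in group_of])
    signal = means[:, col_group]
    noise = rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0
    values = pd.DataFrame(signal + noise, index=gene_ids, columns=sample_ids)

    planted_all = axis_ids + pc1_ids
    truth = ExpressionTruth(
        planted_axis_genes=dict(zip(axis_ids, axis_effects)),
        planted_pc1_genes=dict(zip(pc1_ids, pc1_effects)),
        noise_sd=noise_sd,
        group_means=pd.DataFrame(
            means[[gene_pos[g] for g in planted_all]],
            index=planted_all,
            columns=groups_order,
        ),
    )
    return ExpressionMatrix(values, group_of), truth


def rasterize_spheroid(truth: SpheroidTruth, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixel centers inside the parametric boundary."""
    center = truth.center or ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    max_r = truth.semi_major * (
        1 + sum(abs(a) for _, a, _ in truth.boundary_harmonics)
    )
    if (
        center[0] - max_r < 0
        or center[1] - max_r < 0
        or center[0] + max_r > shape[0] - 1
        or center[1] + max_r > shape[1] - 1
    ):
        raise ValueError("boundary exits the image frame")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    return r <= truth.radius(theta)


def gen_spheroid_image(
    truth: SpheroidTruth,
    image_shape: tuple[int, int] = (256, 256),
    noise_level: float = 0.05,
    seed: int | None = None,
    foreground: float = 0.8,
    background: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, SpheroidTruth]:
    """Grayscale spheroid image plus its noiseless reference mask.

    The image is the mask's two-level intensity pattern with additive
    Gaussian noise of SD ``noise_level`` (intensities clipped to [0, 1]).
    """
    if seed is None:
        raise ValueError("seed is required")
    mask = rasterize_spheroid(truth, image_shape)
    rng = np.random.default_rng(seed)
    image = np.where(mask, foreground, background).astype(float)
    if noise_level > 0:
        image = image + rng.normal(0.0, noise_level, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask, truth


def gen_scratch_pair(
    frame_shape: tuple[int, int] = (256, 256),
    scratch_width: int = 80,
    closure_fraction: float = 0.5,
    seed: int | None = None,
    edge_jitter: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-free masks of a scratch zone at t0 and after partial closure.

    True pixels mark the cell-free band (a vertical strip).  At the later
    time the band has shrunk symmetrically so its area is
    (1 - closure_fraction) times the t0 area, up to rasterization error.
    Per-row edge jitter (symmetric, zero-mean) roughens the wound margins.
    """
    if seed is None:
        raise ValueError("seed is required")
    if not 0 <= closure_fraction <= 1:
        raise ValueError("closure_fraction must be in [0, 1]")
    h, w = frame_shape
    if scratch_width > w:
        raise ValueError("scratch wider than frame")
    rng = np.random.default_rng(seed)

    def band(width: float) -> np.ndarray:
        mask = np.zeros((h, w), dtype=bool)
        if width <= 0:
            return mask
        half = width / 2.0
        c = w / 2.0
        jit_l = rng.integers(-edge_jitter, edge_jitter + 1, size=h)
        jit_r = rng.integers(-edge_jitter, edge_jitter + 1, size=h)
        cols = np.arange(w)
        left = np.maximum(0, c - half + jit_l)
        right = np.minimum(w, c + half + jit_r)
        return (cols[None, :] >= left[:, None]) & (cols[None, :] < right[:, None])

    mask_t0 = band(scratch_width)
    if closure_fraction == 0:
        return mask_t0, mask_t0.copy()
    mask_t = band(scratch_width * (1.0 - closure_fraction))
    return mask_t0, mask_t


def gen_variant_table(
    n_stopgain: int,
    n_missense: int,
    af_range: tuple[float, float] = (0.0, 1.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Annotated variant table in the five-column somatic-mutation dialect.

    Stop-gain rows get an amino-acid change ending in the "stop" token;
    missense rows are single-residue substitutions between two distinct
    residues.  Allele frequencies are uniform in ``af_range``, printed to
    two decimals.
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_stopgain < 0 or n_missense < 0:
        raise ValueError("counts must be non-negative")
    low, high = af_range
    if not 0 <= low <= high <= 1:
        raise ValueError("require 0 <= low <= high <= 1")
    rng = np.random.default_rng(seed)
    rows = []
    total = n_stopgain + n_missense
    for i in range(total):
        ref, alt = rng.choice(NUCLEOTIDES, size=2, replace=False)
        if i < n_stopgain:
            aa = f"{rng.choice(AMINO_ACIDS)}/stop"
        else:
            a, b = rng.choice(AMINO_ACIDS, size=2, replace=False)
            aa = f"{a}/{b}"
        rows.append(
            {
                "symbol": f"SYNGENE{i + 1:04d}",
                "description": "synthetic variant",
                "allele_freq": round(float(rng.uniform(low, high)), 2),
                "base_change": f"{ref}/{alt}",
                "aa_change": aa,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["symbol", "description", "allele_freq", "base_change", "aa_change"],
    )


def gen_passing_times(
    n_per_group: int,
    group_params: dict[str, tuple[float, float]],
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell channel transit times, log-normal per group.

    ``group_params`` maps group label -> (location, scale) where location is
    the median transit time in seconds and scale the SD of log-time.
    Returns a tidy frame with columns ``group`` and ``time_s``.
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    frames = []
    for group, (loc, scale) in group_params.items():
        if loc <= 0 or scale < 0:
            raise ValueError("location must be > 0 and scale >= 0")
        z = rng.normal(0.0, 1.0, size=n_per_group)
        times = loc * np.exp(scale * z)
        frames.append(pd.DataFrame({"group": group, "time_s": times}))
    return pd.concat(frames, ignore_index=True)


def gen_scratch_image(
    free_mask: np.ndarray,
    seed: int | None = None,
    cell_texture_sd: float = 0.2,
    base_level: float = 0.5,
) -> np.ndarray:
    """Textured cell field with a flat (low-variance) band where cells are
    absent — the image counterpart of a scratch free-zone mask."""
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    image = np.full(free_mask.shape, base_level, dtype=float)
    texture = rng.normal(0.0, cell_texture_sd, size=free_mask.shape)
    image[~free_mask] += texture[~free_mask]
    return np.clip(image, 0.0, 1.0)
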