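"""Quantification of motility, invasion and microfluidic transit assays.

Covers three phenotype readouts:

* wound-healing scratch assay — the area newly occupied by cells inside the
  scratched zone between two time points, and the closure fraction;
* transwell invasion assay — counting stained cells (connected components)
  on the membrane;
* microfluidic constriction assay — per-cell channel passing times
  summarised as mean +/- SD with a Welch two-sample comparison.

Group comparisons use the unequal-variance (Welch) t-test and annotate
significance with the conventional "*" (p < 0.05) and "**" (p < 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .morphometrics import BinaryMask


@dataclass
class ScratchMeasurement:
    """Free-zone areas before/after migration and the closure fraction."""

    free_area_t0: float
    free_area_t: float
    newly_occupied: float
    closure_fraction: float
    elapsed: float  # hours


@dataclass
class GroupStats:
    label: str
    n: int
    mean: float
    sd: float


@dataclass
class AssaySummary:
    """Per-group mean +/- SD with an optional two-group Welch comparison."""

    groups: list[GroupStats]
    statistic: float | None = None
    pvalue: float | None = None
    annotation: str = ""
    histogram: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["group   n   mean +/- SD"]
        for g in self.groups:
            lines.append(f"{g.label:>8s}  {g.n:3d}  {g.mean:.4g} +/- {g.sd:.4g}")
        if self.pvalue is not None:
            lines.append(
                f"Welch t = {self.statistic:.4g}, p = {self.pvalue:.4g} "
                f"{self.annotation}"
            )
        return "\n".join(lines)


def scratch_closure(
    mask_free_t0: BinaryMask | np.ndarray,
    mask_free_t: BinaryMask | np.ndarray,
    elapsed: float = 24.0,
) -> ScratchMeasurement:
    """Newly occupied area and closure fraction between two free-zone masks.

    Negative newly-occupied area (cells retracting) is clamped to zero with
    a warning.
    """
    m0 = mask_free_t0 if isinstance(mask_free_t0, BinaryMask) else BinaryMask(mask_free_t0)
    m1 = mask_free_t if isinstance(mask_free_t, BinaryMask) else BinaryMask(mask_free_t)
    if m0.pixels.shape != m1.pixels.shape:
        raise ValueError("masks must have the same shape")
    a0 = m0.n_foreground * m0.pixel_size**2
    a1 = m1.n_foreground * m1.pixel_size**2
    if a0 == 0:
        raise ValueError("empty t0 free zone")
    newly = a0 - a1
    if newly < 0:
        warnings.warn("free zone grew between time points; clamping to 0")
        newly = 0.0
    return ScratchMeasurement(
        free_area_t0=a0,
        free_area_t=a1,
        newly_occupied=newly,
        closure_fraction=newly / a0,
        elapsed=elapsed,
    )


def segment_free_zone(
    image: np.ndarray,
    window: int = 15,
    variance_threshold: float | None = None,
) -> BinaryMask:
    """Segment the low-texture (cell-free) band of a scratch-assay image.

    Cell-covered regions are textured, the scratch is flat, so pixels whose
    local intensity variance (box window) falls below the threshold are
    classed as cell-free; the largest connected such region is kept.  With
    ``variance_threshold=None`` an Otsu split of the variance image is used.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.ptp(image) == 0:
        raise ValueError("constant image")
    mean = ndimage.uniform_filter(image, size=window)
    mean_sq = ndimage.uniform_filter(image**2, size=window)
    local_var = np.maximum(mean_sq - mean**2, 0.0)
    thr = (
        threshold_otsu(local_var)
        if variance_threshold is None
        else float(variance_threshold)
    )
    free = local_var < thr
    labels, n = ndimage.label(free)
    if n == 0:
        raise ValueError("no cell-free band found")
    sizes = ndimage.sum_labels(free, labels, index=np.arange(1, n + 1))
    return BinaryMask(labels == (int(np.argmax(sizes)) + 1))


def count_invading_cells(
    image: np.ndarray,
    spot_min_area: float = 5.0,
    threshold_method: str | float = "otsu",
) -> int:
    """Count stained-cell spots: connected components >= spot_min_area px^2.

    A constant (blank) image has no stained spots and counts as zero.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.ptp(image) == 0:
        return 0
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        thr = threshold_otsu(image)
    else:
        thr = float(threshold_method)
    fg = image > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    return int((sizes >= spot_min_area).sum())


def compare_groups(
    a, b, label_a: str = "a", label_b: str = "b"
) -> AssaySummary:
    """Welch two-sided two-sample comparison with asterisk annotation.

    Degenerate zero-variance cases follow fixed conventions: equal means
    give t=0, p=1; different means give p=0 (with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    stats_out = [
        GroupStats(label_a, a.size, float(a.mean()), float(a.std(ddof=1))),
        GroupStats(label_b, b.size, float(b.mean()), float(b.std(ddof=1))),
    ]
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            warnings.warn("zero variance with different means; p -> 0")
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)
    annotation = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return AssaySummary(
        groups=stats_out, statistic=t, pvalue=p, annotation=annotation
    )


def passing_time_summary(
    times: pd.DataFrame, n_bins: int = 20
) -> AssaySummary:
    """Summarise per-cell transit times by group.

    ``times`` is tidy (columns ``group``, ``time_s``).  Emits per-group
    mean +/- SD, shared-edge histogram counts (fixed-width bins from 0 to
    the pooled 99th percentile), and — when exactly two groups are present —
    the Welch comparison.
    """
    if not {"group", "time_s"} <= set(times.columns):
        raise ValueError("times frame needs columns 'group' and 'time_s'")
    if (times["time_s"] <= 0).any():
        raise ValueError("passing times must be positive")
    counts = times.groupby("group")["time_s"].count()
    if (counts < 2).any():
        raise ValueError("need n >= 2 in every group")
    groups = list(counts.index)

    edges = np.linspace(0.0, float(np.quantile(times["time_s"], 0.99)), n_bins + 1)
    hist_rows = {}
    for g in groups:
        vals = times.loc[times["group"] == g, "time_s"].to_numpy()
        hist_rows[g], _ = np.histogram(vals, bins=edges)
    histogram = pd.DataFrame(hist_rows, index=pd.IntervalIndex.from_breaks(edges))

    if len(groups) == 2:
        va = times.loc[times["group"] == groups[0], "time_s"]
        vb = times.loc[times["group"] == groups[1], "time_s"]
        out = compare_groups(va, vb, label_a=groups[0], label_b=groups[1])
    else:
        out = AssaySummary(
            groups=[
                GroupStats(
                    g,
                    int(counts[g]),
                    float(times.loc[times["group"] == g, "time_s"].mean()),
                    float(times.loc[times["group"] == g, "time_s"].std(ddof=1)),
                )
                for g in groups
            ]
        )
    out.histogram = histogram
    return out
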