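"""PCA-plane metastasis-axis analysis of grouped expression matrices.

A log2 expression matrix from three related cell populations (parental
breast-cancer cells, tumor-derived "TMD" cells and bone-metastasis-derived
"BMD" cells) is mean-centered gene-wise and reduced to its first two
principal components by singular value decomposition.  Within that plane a
*metastasis axis* is drawn parallel to the line connecting the BMD group
centroid to the TMD group centroid, and every gene's biplot loading is
rotated into the (PC1°, PC2°) frame whose second coordinate is that axis.
Genes at the extremes of the PC2° coordinate are the candidates whose
expression most separates the pre- and post-metastatic populations.

The module exposes a statsmodels-style model/results pair
(:class:`MetastasisAxisPCA` / :class:`MetastasisAxisResults`) plus the
underlying functional steps (:func:`center_and_decompose`,
:func:`compute_metastasis_axis`, :func:`project_genes`,
:func:`select_extreme_genes`, :func:`group_fold_change`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("parental", "TMD", "BMD")


class DegenerateDecompositionError(ValueError):
    """Raised when the centered matrix has no variance to decompose."""


class UndefinedAxisError(ValueError):
    """Raised when the two group centroids coincide in the PC plane."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with a sample->group map.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as rows, samples as columns, log2 scale, no missing values.
    groups : pandas.Series or mapping
        Maps every sample id to its group label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(dict(self.groups))
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValueError("gene ids are not unique")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.values.columns)]
        counts = self.groups.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"groups with fewer than 2 samples: {small}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PlaneModel:
    """Rank-2 decomposition of a centered expression matrix plus, once set,
    the metastasis axis drawn between two group centroids.

    ``sample_scores`` holds the two orthonormal sample-space directions
    (unit-scaled); ``gene_loadings`` carry the singular values (the
    ``U @ diag(S)`` biplot convention), so a gene's projection magnitude
    reflects its covariance contribution and
    ``gene_loadings @ sample_scores.T`` is the best rank-2 approximation
    of the centered matrix.
    """

    sample_scores: pd.DataFrame          # samples x 2, orthonormal columns
    gene_loadings: pd.DataFrame          # genes x 2, singular-value scaled
    singular_values: np.ndarray          # first two, descending
    variance_explained: np.ndarray       # fraction per PC, first two
    centroids: pd.DataFrame              # group x 2
    axis: np.ndarray | None = None       # unit 2-vector (PC2deg direction)
    axis_angle_deg: float | None = None  # angle between axis and PC2, [0, 90]
    axis_from: str | None = None
    axis_to: str | None = None

    @property
    def basis(self) -> np.ndarray:
        """The two orthonormal sample-space directions, rows PC1 / PC2."""
        return self.sample_scores.to_numpy().T


def center_and_decompose(X: ExpressionMatrix) -> PlaneModel:
    """Gene-wise mean centering followed by SVD; keep the 2-D plane.

    The sign indeterminacy of the SVD is removed deterministically: PC1 is
    oriented so the parental centroid does not exceed the BMD centroid, and
    PC2 so the TMD centroid is at least the BMD centroid.  Groups absent
    from the data fall back to a largest-element-positive rule.
    """
    if X.n_samples < 3 or X.n_genes < 2:
        raise ValueError("need at least 3 samples and 2 genes")
    values = X.values.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    if not np.any(np.abs(centered) > 1e-12):
        raise DegenerateDecompositionError(
            "every gene is constant across samples; nothing to decompose"
        )
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    var = S**2
    variance_explained = var[:2] / var.sum()

    scores = Vt[:2].T.copy()       # samples x 2, orthonormal columns
    loadings = U[:, :2] * S[:2]    # genes x 2, singular-value scaled

    # deterministic sign convention
    group_arr = X.groups.to_numpy()
    for pc in (0, 1):
        flip = False
        if pc == 0 and "parental" in group_arr and "BMD" in group_arr:
            c_par = scores[group_arr == "parental", 0].mean()
            c_bmd = scores[group_arr == "BMD", 0].mean()
            flip = c_par > c_bmd
        elif pc == 1 and "TMD" in group_arr and "BMD" in group_arr:
            c_tmd = scores[group_arr == "TMD", 1].mean()
            c_bmd = scores[group_arr == "BMD", 1].mean()
            flip = c_tmd < c_bmd
        else:
            col = scores[:, pc]
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            scores[:, pc] *= -1
            loadings[:, pc] *= -1

    score_df = pd.DataFrame(scores, index=X.sample_ids, columns=["PC1", "PC2"])
    loading_df = pd.DataFrame(loadings, index=X.gene_ids, columns=["PC1", "PC2"])
    centroids = score_df.groupby(X.groups).mean()
    return PlaneModel(
        sample_scores=score_df,
        gene_loadings=loading_df,
        singular_values=S[:2].copy(),
        variance_explained=variance_explained,
        centroids=centroids,
    )


def compute_metastasis_axis(
    model: PlaneModel, from_group: str = "BMD", to_group: str = "TMD"
) -> PlaneModel:
    """Set the metastasis axis parallel to the centroid-connecting line.

    The axis is the unit vector from ``from_group``'s centroid to
    ``to_group``'s (default BMD -> TMD, so positive PC2deg projections mark
    TMD-high genes).  ``axis_angle_deg`` is the tilt of that line relative
    to the PC2 direction, folded into [0, 90] degrees.
    """
    for g in (from_group, to_group):
        if g not in model.centroids.index:
            raise ValueError(f"group {g!r} not present in the model")
    diff = (
        model.centroids.loc[to_group].to_numpy()
        - model.centroids.loc[from_group].to_numpy()
    )
    norm = np.linalg.norm(diff)
    if norm < 1e-12:
        raise UndefinedAxisError("group centroids coincide in the PC plane")
    axis = diff / norm
    angle = np.degrees(np.arccos(np.clip(abs(axis[1]), 0.0, 1.0)))
    model.axis = axis
    model.axis_angle_deg = float(angle)
    model.axis_from = from_group
    model.axis_to = to_group
    return model


def project_genes(model: PlaneModel) -> pd.DataFrame:
    """Rotate gene loadings into the (PC1deg, PC2deg) frame of the axis.

    Returns a DataFrame indexed by gene id with columns ``coord_pc1deg``,
    ``coord_pc2deg``, ``rank`` (1 = largest |PC2deg|, ties broken by gene
    id) and ``direction`` ("TMD-high" for positive projections,
    "BMD-high" for negative).
    """
    if model.axis is None:
        raise RuntimeError("metastasis axis not set; call compute_metastasis_axis")
    axis = model.axis
    perp = np.array([axis[1], -axis[0]])  # PC1deg; identity when axis == PC2
    L = model.gene_loadings.to_numpy()
    coords = pd.DataFrame(
        {"coord_pc1deg": L @ perp, "coord_pc2deg": L @ axis},
        index=model.gene_loadings.index,
    )
    order = coords.assign(
        _mag=np.abs(coords["coord_pc2deg"]), _gid=coords.index.astype(str)
    ).sort_values(["_mag", "_gid"], ascending=[False, True])
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    coords["rank"] = ranks
    coords["direction"] = np.where(
        coords["coord_pc2deg"] >= 0, f"{model.axis_to}-high", f"{model.axis_from}-high"
    )
    return coords


def select_extreme_genes(scores: pd.DataFrame, k_per_end: int = 10) -> pd.DataFrame:
    """Pick the k most-positive and k most-negative genes along the axis.

    Output is ordered by |coord_pc2deg| descending.  If ``k_per_end``
    exceeds what an end can supply the selection is clamped with a warning.
    """
    if k_per_end < 0:
        raise ValueError("k_per_end must be non-negative")
    if k_per_end == 0:
        return scores.iloc[0:0]
    srt = scores.sort_values(
        "coord_pc2deg", ascending=False, kind="mergesort"
    )
    if 2 * k_per_end > len(scores):
        warnings.warn(
            f"k_per_end={k_per_end} exceeds half the gene count; clamping",
            stacklevel=2,
        )
    top = srt.head(min(k_per_end, len(srt)))
    bottom = srt.tail(min(k_per_end, len(srt) - len(top)))
    sel = pd.concat([top, bottom])
    return sel.sort_values("rank", kind="mergesort")


def group_fold_change(
    X: ExpressionMatrix, gene: str, group_a: str, group_b: str
) -> float:
    """Linear-scale fold change 2^(mean_A - mean_B) from log2 values."""
    if gene not in X.gene_ids:
        raise KeyError(f"unknown gene {gene!r}")
    for g in (group_a, group_b):
        if g not in set(X.groups):
            raise KeyError(f"unknown group {g!r}")
    row = X.values.loc[gene]
    mean_a = row[X.groups == group_a].mean()
    mean_b = row[X.groups == group_b].mean()
    return float(2.0 ** (mean_a - mean_b))


class MetastasisAxisPCA:
    """Model object: PC-plane decomposition with a centroid-defined axis.

    Parameters
    ----------
    expression : ExpressionMatrix
        Log2 expression with group labels (parental / TMD / BMD).
    from_group, to_group : str
        Groups whose centroid difference defines the axis; the axis points
        from ``from_group`` to ``to_group``.

    Examples
    --------
    >>> model = MetastasisAxisPCA(expr)            # doctest: +SKIP
    >>> res = model.fit()                          # doctest: +SKIP
    >>> res.select_extreme_genes(10)               # doctest: +SKIP
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        from_group: str = "BMD",
        to_group: str = "TMD",
    ):
        self.expression = expression
        self.from_group = from_group
        self.to_group = to_group

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series,
        **kwargs,
    ) -> "MetastasisAxisPCA":
        return cls(ExpressionMatrix(values, pd.Series(dict(groups))), **kwargs)

    def fit(self) -> "MetastasisAxisResults":
        plane = center_and_decompose(self.expression)
        plane = compute_metastasis_axis(plane, self.from_group, self.to_group)
        return MetastasisAxisResults(self, plane)


class MetastasisAxisResults:
    """Fitted results: plane geometry, gene projections and selections."""

    def __init__(self, model: MetastasisAxisPCA, plane: PlaneModel):
        self.model = model
        self.plane = plane
        self._scores: pd.DataFrame | None = None

    # -- geometry ----------------------------------------------------
    @property
    def sample_scores(self) -> pd.DataFrame:
        return self.plane.sample_scores

    @property
    def gene_loadings(self) -> pd.DataFrame:
        return self.plane.gene_loadings

    @property
    def singular_values(self) -> np.ndarray:
        return self.plane.singular_values

    @property
    def variance_explained(self) -> np.ndarray:
        return self.plane.variance_explained

    @property
    def centroids(self) -> pd.DataFrame:
        return self.plane.centroids

    @property
    def axis(self) -> np.ndarray:
        return self.plane.axis

    @property
    def axis_angle_deg(self) -> float:
        return self.plane.axis_angle_deg

    # -- gene-level results ------------------------------------------
    def project_genes(self) -> pd.DataFrame:
        if self._scores is None:
            self._scores = project_genes(self.plane)
        return self._scores

    def select_extreme_genes(self, k_per_end: int = 10) -> pd.DataFrame:
        return select_extreme_genes(self.project_genes(), k_per_end)

    def fold_change(self, gene: str, group_a: str = "TMD", group_b: str = "BMD") -> float:
        return group_fold_change(self.model.expression, gene, group_a, group_b)

    def summary(self) -> str:
        p = self.plane
        lines = [
            "Metastasis-axis PCA results",
            "===========================",
            f"genes: {self.model.expression.n_genes}   "
            f"samples: {self.model.expression.n_samples}",
            f"singular values (PC1, PC2): "
            f"{p.singular_values[0]:.4g}, {p.singular_values[1]:.4g}",
            f"variance explained: "
            f"{p.variance_explained[0]:.3f}, {p.variance_explained[1]:.3f}",
            f"axis: {p.axis_from} -> {p.axis_to}, "
            f"tilt from PC2: {p.axis_angle_deg:.1f} deg",
            "",
            "group centroids (PC1, PC2):",
        ]
        for g, row in p.centroids.iterrows():
            lines.append(f"  {g:>10s}  {row['PC1']:+.4f}  {row['PC2']:+.4f}")
        top = self.select_extreme_genes(5)
        lines += ["", "top genes by |PC2deg| (5 per end):"]
        for gid, row in top.iterrows():
            lines.append(
                f"  {gid:>12s}  PC2deg={row['coord_pc2deg']:+.3f}  "
                f"{row['direction']}"
            )
        return "\n".join(lines)

    def plot_biplot(self, ax=None, n_labels: int = 10):
        """Samples in the PC plane with the metastasis axis overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        groups = self.model.expression.groups
        for g in self.centroids.index:
            pts = self.sample_scores[groups == g]
            ax.scatter(pts["PC1"], pts["PC2"], label=g)
        c0 = self.centroids.loc[self.plane.axis_from].to_numpy()
        c1 = self.centroids.loc[self.plane.axis_to].to_numpy()
        ax.annotate(
            "", xy=tuple(c1), xytext=tuple(c0),
            arrowprops=dict(arrowstyle="->", color="k"),
        )
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        return ax
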