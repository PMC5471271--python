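"""Metastasis-axis PCA: decomposition, axis geometry, gene ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonemet import simulate as sim
from bonemet.axis import (
    DegenerateDecompositionError,
    ExpressionMatrix,
    MetastasisAxisPCA,
    PlaneModel,
    UndefinedAxisError,
    center_and_decompose,
    compute_metastasis_axis,
    group_fold_change,
    project_genes,
    select_extreme_genes,
)

GROUPS9 = pd.Series(
    {f"{g}_{r}": g for g in ("parental", "TMD", "BMD") for r in (1, 2, 3)}
)


def _matrix(values: np.ndarray) -> ExpressionMatrix:
    df = pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(values.shape[0])],
        columns=GROUPS9.index,
    )
    return ExpressionMatrix(df, GROUPS9)


def _plane_from_centroids(c_from, c_to) -> PlaneModel:
    scores = pd.DataFrame(
        np.zeros((4, 2)), index=list("abcd"), columns=["PC1", "PC2"]
    )
    loadings = pd.DataFrame(
        np.eye(2), index=["g1", "g2"], columns=["PC1", "PC2"]
    )
    centroids = pd.DataFrame(
        [c_from, c_to], index=["BMD", "TMD"], columns=["PC1", "PC2"]
    )
    return PlaneModel(
        sample_scores=scores,
        gene_loadings=loadings,
        singular_values=np.array([1.0, 1.0]),
        variance_explained=np.array([0.5, 0.5]),
        centroids=centroids,
    )


class TestDecompose:
    def test_constant_rows_are_degenerate(self):
        with pytest.raises(DegenerateDecompositionError):
            center_and_decompose(_matrix(np.ones((5, 9)) * 3.0))

    def test_rank_one_matrix_explains_everything_on_pc1(self):
        trend = np.arange(9, dtype=float)
        values = np.outer(np.linspace(1, 2, 12), trend) + 5.0
        model = center_and_decompose(_matrix(values))
        assert model.variance_explained[0] == pytest.approx(1.0, abs=1e-10)
        assert model.variance_explained[1] == pytest.approx(0.0, abs=1e-10)

    def test_rank2_reconstruction_matches_full_svd_tail(self):
        # Eckart-Young: the rank-2 residual equals the trailing singular mass
        rng = np.random.default_rng(3)
        values = rng.normal(size=(50, 9))
        X = _matrix(values)
        model = center_and_decompose(X)
        centered = values - values.mean(axis=1, keepdims=True)
        approx = model.gene_loadings.to_numpy() @ model.sample_scores.to_numpy().T
        resid = ((centered - approx) ** 2).sum()
        s_full = np.linalg.svd(centered, compute_uv=False)  # oracle
        assert resid == pytest.approx((s_full[2:] ** 2).sum(), rel=1e-9)

    def test_scores_are_orthonormal_and_loadings_carry_scale(self):
        rng = np.random.default_rng(0)
        model = center_and_decompose(_matrix(rng.normal(size=(30, 9))))
        V = model.sample_scores.to_numpy()
        assert np.allclose(V.T @ V, np.eye(2), atol=1e-10)
        norms = np.linalg.norm(model.gene_loadings.to_numpy(), axis=0)
        assert np.allclose(norms, model.singular_values, rtol=1e-9)

    def test_reconstruction_rows_are_centered(self):
        rng = np.random.default_rng(1)
        model = center_and_decompose(_matrix(rng.normal(size=(20, 9))))
        approx = model.gene_loadings.to_numpy() @ model.sample_scores.to_numpy().T
        assert np.allclose(approx.mean(axis=1), 0.0, atol=1e-10)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = _matrix(rng.normal(size=(40, 9)))
        m = center_and_decompose(X)
        assert m.centroids.loc["parental", "PC1"] <= m.centroids.loc["BMD", "PC1"]
        assert m.centroids.loc["TMD", "PC2"] >= m.centroids.loc["BMD", "PC2"]

    def test_missing_values_rejected(self):
        values = np.ones((10, 9))
        values[0, 0] = np.nan
        with pytest.raises(ValueError):
            _matrix(values)


class TestAxis:
    def test_axis_equal_to_pc2_has_zero_angle(self):
        model = compute_metastasis_axis(_plane_from_centroids([0, 0], [0, 2.5]))
        assert np.allclose(model.axis, [0, 1])
        assert model.axis_angle_deg == pytest.approx(0.0)

    def test_twenty_degree_tilt(self):
        model = compute_metastasis_axis(
            _plane_from_centroids([0, 0], [np.tan(np.radians(20)), 1.0])
        )
        assert model.axis_angle_deg == pytest.approx(20.0, abs=1e-9)

    def test_coincident_centroids_raise(self):
        with pytest.raises(UndefinedAxisError):
            compute_metastasis_axis(_plane_from_centroids([1, 1], [1, 1]))

    def test_angle_recovered_from_noisy_synthetic_matrix(self):
        X, _ = sim.gen_expression(
            200, 3, axis_effects=[2.0] * 5 + [-2.0] * 5,
            pc1_effects=[2.0] * 5, noise_sd=0.2, seed=11,
        )
        X0, _ = sim.gen_expression(
            200, 3, axis_effects=[2.0] * 5 + [-2.0] * 5,
            pc1_effects=[2.0] * 5, noise_sd=0.0, seed=11,
        )
        noisy = MetastasisAxisPCA(X).fit().axis_angle_deg
        planted = MetastasisAxisPCA(X0).fit().axis_angle_deg
        assert abs(noisy - planted) < 5.0


class TestProjection:
    def test_identity_rotation_when_axis_is_pc2(self):
        model = compute_metastasis_axis(_plane_from_centroids([0, 0], [0, 1]))
        coords = project_genes(model)
        assert np.allclose(
            coords["coord_pc2deg"], model.gene_loadings["PC2"]
        )
        assert np.allclose(
            coords["coord_pc1deg"], model.gene_loadings["PC1"]
        )

    @settings(deadline=None, max_examples=25)
    @given(
        angle=st.floats(0, 2 * np.pi),
        lx=st.floats(-5, 5),
        ly=st.floats(-5, 5),
    )
    def test_rotation_preserves_loading_norm(self, angle, lx, ly):
        model = _plane_from_centroids([0.0, 0.0], [np.sin(angle), np.cos(angle)])
        if np.hypot(np.sin(angle), np.cos(angle)) < 1e-9:
            return
        model.gene_loadings.iloc[0] = [lx, ly]
        model = compute_metastasis_axis(model)
        coords = project_genes(model)
        norm_sq = coords.iloc[0, 0] ** 2 + coords.iloc[0, 1] ** 2
        assert norm_sq == pytest.approx(lx**2 + ly**2, abs=1e-9)

    def test_axis_unset_raises(self):
        with pytest.raises(RuntimeError):
            project_genes(_plane_from_centroids([0, 0], [0, 1]))

    def test_strongest_planted_marker_ranks_first(self):
        X, truth = sim.gen_expression(
            50, 3, axis_effects=[4.0, 2.0, -2.0], noise_sd=0.0, seed=9
        )
        coords = MetastasisAxisPCA(X).fit().project_genes()
        top_gene = coords.index[coords["rank"] == 1][0]
        strongest = max(truth.planted_axis_genes, key=lambda g: abs(truth.planted_axis_genes[g]))
        assert top_gene == strongest
        assert coords.loc[top_gene, "direction"] == "TMD-high"

    def test_rank_is_a_permutation(self, planted_expression):
        X, _ = planted_expression
        coords = MetastasisAxisPCA(X).fit().project_genes()
        assert sorted(coords["rank"]) == list(range(1, len(coords) + 1))


class TestSelection:
    def test_zero_k_gives_empty_selection(self):
        model = compute_metastasis_axis(_plane_from_centroids([0, 0], [0, 1]))
        assert len(select_extreme_genes(project_genes(model), 0)) == 0

    def test_oversized_k_clamps_with_warning(self):
        model = compute_metastasis_axis(_plane_from_centroids([0, 0], [0, 1]))
        coords = project_genes(model)
        with pytest.warns(UserWarning):
            sel = select_extreme_genes(coords, 50)
        assert len(sel) == len(coords)

    def test_planted_genes_recovered_across_seeds(self):
        # >=18 of 20 planted genes (effect +/-3, noise SD 0.3) land in the
        # top-10-per-end selection; checked across 20 seeds
        recalls = []
        for seed in range(20):
            X, truth = sim.gen_expression(
                2000, 3, axis_effects=[3.0] * 10 + [-3.0] * 10,
                noise_sd=0.3, seed=seed,
            )
            sel = MetastasisAxisPCA(X).fit().select_extreme_genes(10)
            planted = set(truth.planted_axis_genes)
            recalls.append(len(planted & set(sel.index)) / len(planted))
        assert np.mean(recalls) >= 0.9
        assert recalls[5] >= 0.9  # the seed-5 example configuration

    def test_label_permutation_destroys_recall(self):
        X, truth = sim.gen_expression(
            2000, 3, axis_effects=[3.0] * 10 + [-3.0] * 10, noise_sd=1.0, seed=3
        )
        rng = np.random.default_rng(0)
        recalls = []
        for _ in range(10):
            perm = rng.permutation(X.groups.to_numpy())
            Xp = ExpressionMatrix(X.values, pd.Series(perm, index=X.sample_ids))
            try:
                sel = MetastasisAxisPCA(Xp).fit().select_extreme_genes(10)
            except UndefinedAxisError:
                continue
            planted = set(truth.planted_axis_genes)
            recalls.append(len(planted & set(sel.index)) / len(planted))
        # chance level: 20 of 2000 genes in a 20-gene selection
        assert np.mean(recalls) < 0.5

    def test_pure_noise_selection_consistent_with_permutation_null(self):
        X, _ = sim.gen_expression(500, 3, noise_sd=1.0, seed=21)
        res = MetastasisAxisPCA(X).fit()
        observed = res.select_extreme_genes(10)["coord_pc2deg"].abs().mean()
        rng = np.random.default_rng(42)
        null = []
        for _ in range(200):
            perm = rng.permutation(X.groups.to_numpy())
            Xp = ExpressionMatrix(X.values, pd.Series(perm, index=X.sample_ids))
            try:
                sel = MetastasisAxisPCA(Xp).fit().select_extreme_genes(10)
            except UndefinedAxisError:
                continue
            null.append(sel["coord_pc2deg"].abs().mean())
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo <= observed <= hi


class TestFoldChange:
    def test_equal_means_give_unity(self):
        values = np.ones((10, 9)) * 6.0
        values[0] += np.tile([0.0, 0.1, -0.1], 3)  # avoid degenerate matrix
        X = _matrix(values)
        assert group_fold_change(X, "G1", "TMD", "BMD") == pytest.approx(1.0)

    def test_two_log2_units_is_fourfold(self):
        values = np.zeros((10, 9))
        values[0, 3:6] = 2.0  # TMD samples
        X = _matrix(values)
        assert group_fold_change(X, "G0", "TMD", "BMD") == pytest.approx(4.0)

    def test_planted_effect_matches_direct_exponentiation(self):
        X, truth = sim.gen_expression(
            20, 3, axis_effects=[2.22], noise_sd=0.0, seed=2
        )
        gene = next(iter(truth.planted_axis_genes))
        fc = group_fold_change(X, gene, "TMD", "BMD")
        assert fc == pytest.approx(2.0**2.22, rel=1e-12)
        assert fc == pytest.approx(4.66, abs=0.01)

    def test_unknown_gene_or_group(self):
        X = _matrix(np.random.default_rng(0).normal(size=(10, 9)))
        with pytest.raises(KeyError):
            group_fold_change(X, "nope", "TMD", "BMD")
        with pytest.raises(KeyError):
            group_fold_change(X, "G0", "TMD", "nope")


def test_results_summary_mentions_axis_and_groups(planted_expression):
    X, _ = planted_expression
    text = MetastasisAxisPCA(X).fit().summary()
    assert "tilt from PC2" in text
    assert "BMD" in text
    assert ("TMD-high" in text) or ("BMD-high" in text)
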