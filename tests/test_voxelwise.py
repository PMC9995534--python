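"""Voxelwise GLM, permutation FWE, cluster extraction and atlas labeling."""

import numpy as np
import pandas as pd
import pytest

from gaitbrain.cohort import BrainSimSpec, make_atlas, simulate_brain_maps
from gaitbrain.tfce import TFCEParams
from gaitbrain.voxelwise import (
    ClusterTable,
    CohortStack,
    VoxelwiseLinearModel,
    build_design,
    extract_clusters,
    fit_glm,
    label_clusters,
    permutation_fwe,
)

from conftest import random_covariates


def _stack_from_matrix(Y, shape=None):
    """Wrap an (n, v) matrix as a CohortStack over a full cuboid mask."""
    n, v = Y.shape
    if shape is None:
        shape = (v, 1, 1)
    mask = np.ones(shape, dtype=bool)
    data = np.zeros((n,) + shape)
    data[:, mask] = Y
    return CohortStack(data=data, mask=mask, affine=np.eye(4))


def _scores_table(n, rng, **kwargs):
    table = random_covariates(n, rng, **kwargs)
    table["sym_CoM"] = rng.normal(-4.6, 5.2, n)
    table["sym_StepCoM"] = rng.normal(29.0, 16.0, n)
    table["sym_intCoPCoM"] = rng.normal(-63.3, 68.1, n)
    return table


class TestDesign:
    def test_q1_column_count_and_contrast(self):
        rng = np.random.default_rng(0)
        design = build_design(_scores_table(20, rng), question="q1")
        # intercept + 3 scores + group + sex
        assert len(design.names) == 6
        c = design.contrasts["sym_StepCoM"]
        assert c.sum() == 1.0 and c[design.names.index("sym_StepCoM")] == 1.0

    def test_q2_slope_difference_contrast_sums_to_zero(self):
        rng = np.random.default_rng(1)
        design = build_design(_scores_table(20, rng), score_cols=["sym_StepCoM"], question="q2")
        assert {"sym_StepCoM:young", "sym_StepCoM:old"} <= set(design.names)
        c = design.contrasts["sym_StepCoM"]
        assert c.sum() == 0.0
        assert c[design.names.index("sym_StepCoM:young")] == 1.0
        assert c[design.names.index("sym_StepCoM:old")] == -1.0

    def test_tiv_covariate_optional(self):
        rng = np.random.default_rng(2)
        t = _scores_table(15, rng)
        assert "tiv" in build_design(t, include_tiv=True).names
        assert "tiv" not in build_design(t, include_tiv=False).names

    def test_duplicated_regressor_rank_error(self):
        rng = np.random.default_rng(3)
        t = _scores_table(15, rng)
        t["sym_dup"] = t["sym_CoM"]
        with pytest.raises(ValueError, match="collinear.*sym_CoM|collinear.*sym_dup"):
            build_design(t, score_cols=["sym_CoM", "sym_dup"])


class TestGLM:
    def test_matches_closed_form_correlation_t(self):
        """Single regressor plus intercept: the GLM t equals the correlation
        t statistic r·sqrt(n−2)/sqrt(1−r²) at every voxel."""
        rng = np.random.default_rng(4)
        n, v = 24, 500
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, v))
        table = pd.DataFrame({"x": x, "intercept": 1.0})
        design_mat = table[["intercept", "x"]]
        from gaitbrain.voxelwise import DesignMatrix

        design = DesignMatrix(design_mat, {"x": np.array([0.0, 1.0])})
        res = fit_glm(_stack_from_matrix(Y), design, "x")
        r = np.array([np.corrcoef(x, Y[:, j])[0, 1] for j in range(v)])
        t_closed = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        np.testing.assert_allclose(res.t, t_closed, atol=1e-10)
        assert res.df == n - 2

    def test_matches_statsmodels_ols(self):
        """Cross-check the full multi-covariate fit against statsmodels."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 30
        table = _scores_table(n, rng)
        design = build_design(table, question="q1", include_tiv=True)
        Y = rng.normal(size=(n, 6))
        res = fit_glm(_stack_from_matrix(Y), design, "sym_StepCoM")
        j_col = design.names.index("sym_StepCoM")
        for j in range(Y.shape[1]):
            fit = sm.OLS(Y[:, j], design.values).fit()
            assert res.t[j] == pytest.approx(fit.tvalues[j_col], abs=1e-8)

    def test_intercept_only_beta_is_voxel_mean(self):
        from gaitbrain.voxelwise import DesignMatrix

        rng = np.random.default_rng(6)
        Y = rng.normal(size=(12, 20))
        design = DesignMatrix(pd.DataFrame({"intercept": np.ones(12)}), {"i": np.array([1.0])})
        res = fit_glm(_stack_from_matrix(Y), design, "i")
        np.testing.assert_allclose(res.beta[0], Y.mean(axis=0), atol=1e-12)

    def test_orthogonal_response_gives_zero_t(self):
        from gaitbrain.voxelwise import DesignMatrix

        n = 20
        x = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        Y = np.random.default_rng(7).normal(size=(n, 5))
        Y -= (x[:, None] * Y).sum(0) * x[:, None] / n  # project out x
        design = DesignMatrix(
            pd.DataFrame({"intercept": np.ones(n), "x": x}), {"x": np.array([0.0, 1.0])}
        )
        res = fit_glm(_stack_from_matrix(Y), design, "x")
        np.testing.assert_allclose(res.t, 0.0, atol=1e-10)

    def test_zero_variance_voxels_get_t_zero(self):
        from gaitbrain.voxelwise import DesignMatrix

        n = 10
        x = np.arange(n, dtype=float)
        Y = np.column_stack([2.0 * x + 1.0, np.random.default_rng(8).normal(size=n)])
        design = DesignMatrix(
            pd.DataFrame({"intercept": np.ones(n), "x": x}), {"x": np.array([0.0, 1.0])}
        )
        res = fit_glm(_stack_from_matrix(Y), design, "x")
        assert res.n_zero_variance == 1
        assert res.t[0] == 0.0


class TestPermutationFWE:
    def test_p_floor_and_determinism(self, planted_stack):
        stack, table, _ = planted_stack
        design = build_design(table, score_cols=["sym_StepCoM"], question="q1")
        out1 = permutation_fwe(stack, design, "sym_StepCoM", n_perm=99, seed=5)
        out2 = permutation_fwe(stack, design, "sym_StepCoM", n_perm=99, seed=5)
        assert out1["p"].min() >= 1.0 / (99 + 1)
        np.testing.assert_array_equal(out1["p"], out2["p"])
        np.testing.assert_array_equal(out1["max_null"], out2["max_null"])

    def test_planted_effect_detected(self, planted_stack):
        """A strong planted slope reaches corrected p < .05 inside the ROI."""
        stack, table, truth = planted_stack
        design = build_design(table, score_cols=["sym_StepCoM"], question="q1")
        out = permutation_fwe(stack, design, "sym_StepCoM", n_perm=199, seed=1)
        roi_p = out["p_vol"][truth["roi"]]
        assert roi_p.min() < 0.05
        # detected peak slope sign matches the planted positive slope
        peak = np.unravel_index(np.argmin(out["p_vol"] + ~stack.mask), out["p_vol"].shape)
        assert out["t"][peak] > 0

    def test_tiny_n_exact_enumeration_warns(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(5, 8))
        from gaitbrain.voxelwise import DesignMatrix

        design = DesignMatrix(
            pd.DataFrame({"intercept": np.ones(5), "x": rng.normal(size=5)}),
            {"x": np.array([0.0, 1.0])},
        )
        with pytest.warns(UserWarning, match="enumerat"):
            out = permutation_fwe(_stack_from_matrix(Y), design, "x", n_perm=500, seed=0)
        assert out["n_perm"] == 119  # 5! − identity


class TestClusters:
    def _pmap(self, shape=(8, 8, 8)):
        p = np.ones(shape)
        mask = np.ones(shape, dtype=bool)
        return p, mask

    def test_constructed_blobs_extents(self):
        """Two disjoint sub-alpha blobs of 7 and 3 voxels give clusters with
        K_E 7 and 3."""
        p, mask = self._pmap()
        p[1, 1:4, 1] = 0.01  # 3 voxels
        p[5:7, 5:7, 5] = 0.02  # 4 voxels
        p[5, 5, 6] = 0.02
        p[5, 6, 6] = 0.02
        p[6, 5, 6] = 0.02  # total 7
        ct = extract_clusters(p, mask, np.eye(4), alpha=0.05)
        assert sorted(ct.table["k_e"]) == [3, 7]
        assert (ct.table["p_fwe"] <= 0.02).all()

    def test_empty_table_when_nothing_significant(self):
        p, mask = self._pmap()
        ct = extract_clusters(p, mask, np.eye(4))
        assert len(ct) == 0

    def test_peak_world_coordinates_use_affine(self):
        p, mask = self._pmap()
        p[2, 3, 4] = 0.001
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-8, -8, -8]
        ct = extract_clusters(p, mask, affine)
        row = ct.table.iloc[0]
        assert (row["x"], row["y"], row["z"]) == (-4.0, -2.0, 0.0)

    def test_matches_flood_fill_oracle(self):
        """Cluster count and extents agree with an independent BFS flood
        fill on random binary maps."""
        rng = np.random.default_rng(11)
        for conn in (6, 26):
            for _ in range(5):
                sig = rng.random((9, 9, 9)) < 0.2
                p = np.where(sig, 0.01, 0.99)
                ct = extract_clusters(p, np.ones((9, 9, 9), bool), np.eye(4),
                                      connectivity=conn)
                sizes = _flood_fill_sizes(sig, conn)
                assert sorted(ct.table["k_e"]) == sorted(sizes)


def _flood_fill_sizes(binary, connectivity):
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
        and (connectivity == 26 or abs(dz) + abs(dy) + abs(dx) == 1)
    ]
    seen = np.zeros_like(binary, bool)
    sizes = []
    for idx in np.argwhere(binary):
        if seen[tuple(idx)]:
            continue
        queue, size = [tuple(idx)], 0
        seen[tuple(idx)] = True
        while queue:
            z, y, x = queue.pop()
            size += 1
            for dz, dy, dx in offs:
                w = (z + dz, y + dy, x + dx)
                if all(0 <= w[i] < binary.shape[i] for i in range(3)):
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        sizes.append(size)
    return sizes


class TestAtlasLabels:
    def _cluster_table(self, cluster_map):
        table = pd.DataFrame(
            [{"cluster": 1, "k_e": int((cluster_map == 1).sum()), "p_fwe": 0.01,
              "i": 0, "j": 0, "k": 0, "x": 0.0, "y": 0.0, "z": 0.0}]
        )
        return ClusterTable(table, cluster_map, np.eye(4))

    def test_wholly_inside_one_label(self):
        cm = np.zeros((6, 6, 6), int)
        cm[2:4, 2:4, 2] = 1
        atlas = np.full((6, 6, 6), 3)
        lookup = pd.DataFrame({"label_id": [3], "label_name": ["somewhere"]})
        ct = label_clusters(self._cluster_table(cm), atlas, lookup)
        assert len(ct.labels) == 1
        assert ct.labels["overlap_pct"].iloc[0] == pytest.approx(100.0)

    def test_even_split_fifty_fifty(self):
        cm = np.zeros((10, 4, 4), int)
        cm[0:10, 1, 1] = 1  # 10 voxels
        atlas = np.zeros((10, 4, 4), int)
        atlas[:5] = 1
        atlas[5:] = 2
        lookup = pd.DataFrame({"label_id": [1, 2], "label_name": ["a", "b"]})
        ct = label_clusters(self._cluster_table(cm), atlas, lookup)
        assert sorted(ct.labels["overlap_pct"]) == [50.0, 50.0]

    def test_four_percent_overlap_suppressed(self):
        """A label covering 4% of a cluster is omitted under the 5% rule."""
        cm = np.zeros((5, 5, 5), int)
        flat = np.argwhere(np.ones((5, 5, 5), bool))[:25]
        cm[tuple(flat.T)] = 1  # 25-voxel cluster
        atlas = np.zeros((5, 5, 5), int)
        atlas[tuple(flat[:24].T)] = 1  # 96%
        atlas[tuple(flat[24])] = 2  # 4%
        lookup = pd.DataFrame({"label_id": [1, 2], "label_name": ["big", "tiny"]})
        ct = label_clusters(self._cluster_table(cm), atlas, lookup)
        assert set(ct.labels["label_name"]) == {"big"}
        # and it reappears with a lower threshold
        ct2 = label_clusters(self._cluster_table(cm), atlas, lookup, min_overlap_pct=3.0)
        assert set(ct2.labels["label_name"]) == {"big", "tiny"}

    def test_grid_mismatch_without_affine_errors(self):
        cm = np.zeros((5, 5, 5), int)
        cm[2, 2, 2] = 1
        atlas = np.zeros((7, 7, 7), int)
        lookup = pd.DataFrame({"label_id": [], "label_name": []})
        with pytest.raises(ValueError, match="affine"):
            label_clusters(self._cluster_table(cm), atlas, lookup)


class TestModelResults:
    def test_fit_summary_and_cluster_labels(self, planted_stack):
        stack, table, truth = planted_stack
        model = VoxelwiseLinearModel.from_dataframe(
            stack, table, score_cols=["sym_StepCoM"], question="q1"
        )
        res = model.fit(n_perm=99, seed=2, tfce_params=TFCEParams(n_steps=100))
        text = res.summary()
        assert "question Q1" in text and "permutations: 99" in text
        atlas, lookup = make_atlas(stack.mask.shape, stack.mask)
        ct = res.label_clusters(atlas, lookup)
        assert len(ct) >= 1
        assert (ct.table["k_e"] >= 1).all()
        assert ((ct.table["p_fwe"] > 0) & (ct.table["p_fwe"] <= 1)).all()

    def test_subject_count_mismatch(self, planted_stack):
        stack, table, _ = planted_stack
        with pytest.raises(ValueError, match="subjects"):
            VoxelwiseLinearModel.from_dataframe(stack, table.iloc[:-2], question="q1")

    def test_nifti_roundtrip(self, tmp_path, planted_stack):
        import nibabel as nib

        stack, _, _ = planted_stack
        for i in range(3):
            nib.save(nib.Nifti1Image(stack.data[i], stack.affine), tmp_path / f"s{i}.nii")
        nib.save(nib.Nifti1Image(stack.mask.astype(np.uint8), stack.affine),
                 tmp_path / "mask.nii")
        loaded = CohortStack.from_niftis(
            [tmp_path / f"s{i}.nii" for i in range(3)], tmp_path / "mask.nii"
        )
        np.testing.assert_allclose(loaded.data, stack.data[:3])
        np.testing.assert_array_equal(loaded.mask, stack.mask)
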