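"""Functional diversity indices against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

import traitpart as tp
from traitpart.data_model import ValidationError
from traitpart.fd import gower_distance, plot_trait_matrix

from conftest import convex_hull_area_oracle, fdis_oracle, fdiv_oracle, feve_oracle


def space_from(coords, weights=None) -> tp.TraitSpace:
    coords = np.asarray(coords, dtype=float)
    S = coords.shape[0]
    w = np.full(S, 1.0 / S) if weights is None else np.asarray(weights, float)
    return tp.TraitSpace([f"s{i}" for i in range(S)], coords, w / w.sum())


class TestFRic:
    def test_unit_square_volume_is_one(self):
        space = space_from([[0, 0], [1, 0], [1, 1], [0, 1]])
        val, flag = tp.fric(space)
        assert flag is None
        assert val == pytest.approx(1.0)

    def test_collinear_points_flagged_undefined(self):
        space = space_from([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        val, flag = tp.fric(space)
        assert np.isnan(val) and flag is not None

    def test_point_community_has_zero_volume_unflagged(self):
        space = space_from([[1.0, 2.0]] * 4)
        val, flag = tp.fric(space)
        assert val == 0.0 and flag is None

    def test_one_dimensional_volume_is_range(self):
        space = space_from([[0.0], [0.3], [2.5]])
        val, _ = tp.fric(space)
        assert val == pytest.approx(2.5)

    def test_random_cloud_matches_shoelace_oracle(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(6, 2))
        val, _ = tp.fric(space_from(pts))
        assert val == pytest.approx(convex_hull_area_oracle(pts), abs=1e-10)

    def test_zero_abundance_species_inside_hull_leaves_fric_unchanged(self):
        square = [[0, 0], [1, 0], [1, 1], [0, 1]]
        v0, _ = tp.fric(space_from(square))
        v1, _ = tp.fric(space_from(square + [[0.5, 0.5]], [0.25] * 4 + [0.0]))
        assert v1 == pytest.approx(v0)
        v2, _ = tp.fric(space_from(square + [[2.0, 0.5]], [0.25] * 4 + [0.0]))
        assert v2 > v0


class TestFEve:
    def test_equally_spaced_triplet_is_one(self):
        space = space_from([[0.0], [1.0], [2.0]])
        val, flag = tp.feve(space)
        assert flag is None
        assert val == pytest.approx(1.0)

    def test_extreme_clumping_is_zero(self):
        # two coincident species plus one far away, equal weights:
        # PEW collapses to {0, 1} and the formula evaluates to 0
        space = space_from([[0.0], [0.0], [10.0]])
        val, flag = tp.feve(space)
        assert flag is None
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_too_few_species_flagged(self):
        val, flag = tp.feve(space_from([[0.0], [1.0]]))
        assert np.isnan(val) and "3 species" in flag

    def test_bounds_on_random_communities(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            S = rng.integers(3, 10)
            space = space_from(rng.normal(size=(S, 2)), rng.dirichlet(np.ones(S)))
            val, flag = tp.feve(space)
            assert flag is None
            assert -1e-12 <= val <= 1 + 1e-12


class TestFDiv:
    def test_equidistant_from_centroid_is_one(self):
        # regular pentagon: every species equidistant from the hull centroid
        ang = np.linspace(0, 2 * np.pi, 6)[:-1]
        space = space_from(np.c_[np.cos(ang), np.sin(ang)],
                           [0.1, 0.3, 0.2, 0.25, 0.15])
        val, flag = tp.fdiv(space)
        assert flag is None
        assert val == pytest.approx(1.0)

    def test_two_cluster_toy_matches_direct_formula(self):
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [3, 3], [3.1, 3]], float)
        w = np.array([0.4, 0.1, 0.1, 0.3, 0.1])
        val, _ = tp.fdiv(space_from(pts, w))
        verts = list(ConvexHull(pts).vertices)
        assert val == pytest.approx(fdiv_oracle(pts, w, verts), abs=1e-12)

    def test_bounds_on_random_communities(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            S = rng.integers(4, 10)
            space = space_from(rng.normal(size=(S, 2)), rng.dirichlet(np.ones(S)))
            val, flag = tp.fdiv(space)
            assert flag is None
            assert 0 <= val <= 1 + 1e-12


class TestFDis:
    def test_single_species_is_zero(self):
        val, _ = tp.fdis(space_from([[3.0, 4.0]]))
        assert val == 0.0

    def test_two_species_equal_weights_half_distance(self):
        space = space_from([[0.0, 0.0], [3.0, 4.0]])
        val, _ = tp.fdis(space)
        assert val == pytest.approx(2.5)

    def test_weighted_case_matches_brute_force(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(5, 3))
        w = rng.dirichlet(np.ones(5))
        val, _ = tp.fdis(space_from(pts, w))
        assert val == pytest.approx(fdis_oracle(pts, w), abs=1e-12)

    def test_zero_iff_all_abundant_species_coincide(self):
        space = space_from([[1.0, 1.0], [1.0, 1.0], [9.9, 0.0]], [0.5, 0.5, 0.0])
        val, _ = tp.fdis(space)
        assert val == pytest.approx(0.0, abs=1e-12)


class TestInvariances:
    def test_rigid_motion_leaves_indices_unchanged(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        w = rng.dirichlet(np.ones(7))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + np.array([5.0, -2.0])
        for fn in (tp.fric, tp.feve, tp.fdis, tp.fdiv):
            a, _ = fn(space_from(pts, w))
            b, _ = fn(space_from(moved, w))
            assert b == pytest.approx(a, rel=1e-9)

    def test_bruteforce_agreement_on_random_small_communities(self):
        # independent oracle routes: Jarvis+shoelace, networkx MST, direct loops
        rng = np.random.default_rng(11)
        for _ in range(50):
            S = int(rng.integers(4, 9))
            pts = rng.normal(size=(S, 2))
            w = rng.dirichlet(np.ones(S))
            space = space_from(pts, w)
            assert tp.fric(space)[0] == pytest.approx(
                convex_hull_area_oracle(pts), abs=1e-10)
            assert tp.feve(space)[0] == pytest.approx(feve_oracle(pts, w), abs=1e-10)
            assert tp.fdis(space)[0] == pytest.approx(fdis_oracle(pts, w), abs=1e-10)
            verts = list(ConvexHull(pts).vertices)
            assert tp.fdiv(space)[0] == pytest.approx(
                fdiv_oracle(pts, w, verts), abs=1e-10)


class TestTraitSpace:
    def test_gower_single_trait_is_normalized_absolute_difference(self):
        tm = pd.DataFrame({"SLA": [10.0, 20.0, 40.0]}, index=["a", "b", "c"])
        D = gower_distance(tm)
        assert D.loc["a", "b"] == pytest.approx(10 / 30)
        assert D.loc["a", "c"] == pytest.approx(1.0)

    def test_euclidean_path_returns_raw_coordinates_when_unstandardized(self):
        tm = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0]}, index=["a", "b"])
        ab = pd.Series({"a": 1.0, "b": 1.0})
        space = tp.build_trait_space(tm, ab, geometry="zscore-euclidean",
                                     standardize=False)
        np.testing.assert_allclose(space.coords, tm.to_numpy())

    def test_pcoa_embedding_reproduces_corrected_dissimilarities(self):
        # enough traits that all S-1 axes are retained: embedding distances
        # must equal the sqrt-corrected Gower dissimilarities; checked against
        # a direct double-centred eigendecomposition oracle
        rng = np.random.default_rng(5)
        tm = pd.DataFrame(rng.lognormal(size=(5, 5)),
                          index=list("abcde"), columns=list("vwxyz"))
        ab = pd.Series(np.ones(5), index=tm.index)
        space = tp.build_trait_space(tm, ab, geometry="gower-pcoa")
        got = squareform(pdist(space.coords))
        target = np.sqrt(gower_distance(tm).to_numpy())
        np.testing.assert_allclose(got, target, atol=1e-8)

        # oracle: classical PCoA by hand
        D2 = target ** 2
        n = 5
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        eigval, eigvec = np.linalg.eigh(B)
        keep = eigval > 1e-10
        oracle = eigvec[:, keep] * np.sqrt(eigval[keep])
        np.testing.assert_allclose(
            squareform(pdist(oracle)), got, atol=1e-8)

    def test_degenerate_space_flags(self):
        tm = pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=list("abc"))
        ab = pd.Series(np.ones(3), index=tm.index)
        space = tp.build_trait_space(tm, ab)
        assert space.degenerate
        res = tp.community_fd(space, "p")
        assert res.fric == 0.0
        assert np.isnan(res.feve) and "FEve" in res.flags
        assert np.isnan(res.fdiv) and "FDiv" in res.flags

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            tp.TraitSpace(["a", "b"], np.zeros((2, 1)), np.array([0.5, 0.6]))


class TestFdTable:
    def test_full_design_has_all_metrics(self, sim_default, species_filter):
        design, ab, traits, _ = sim_default
        fd = tp.fd_table(design, ab, traits, species_filter=species_filter)
        assert list(fd.index) == design.plot_ids
        assert fd[["FRic", "FEve", "FDiv", "FDis"]].notna().all().all()
        assert ((fd["FEve"] >= 0) & (fd["FEve"] <= 1)).all()
        assert ((fd["FDiv"] >= 0) & (fd["FDiv"] <= 1)).all()

    def test_plot_trait_matrix_prefers_specific_values(self, sim_default):
        design, ab, traits, _ = sim_default
        plot = design.plot_ids[0]
        present = ab.present_species(plot)
        mat = plot_trait_matrix(traits, plot, present)
        spec = traits.specific_values("LA", plot)
        shared = mat.index.intersection(spec.index)
        np.testing.assert_allclose(mat.loc[shared, "LA"], spec.loc[shared])
        # pooled-only traits come from the fixed averages
        pooled = traits.pooled_values("seed_mass")
        np.testing.assert_allclose(mat["seed_mass"], pooled.loc[mat.index])
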