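"""Dihedral computation, sin/cos and distance featurization, PCA/LDA,
and rotamer populations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from xtalmd.core import Topology, TrajectoryEnsemble
from xtalmd.features import (
    DihedralSet,
    FeatureMatrix,
    RotamerTable,
    compute_dihedrals,
    dihedral_angle,
    featurize_ca_distances,
    featurize_sincos,
    lda_importance,
    pca_fit,
    rotamer_populations,
    rotamer_state,
    table_distance,
)
from xtalmd.synthetic import synth_dihedral_ensembles

from conftest import build_backbone, single_frame_ensemble


class TestComputeDihedrals:
    @pytest.mark.parametrize(
        "phi,psi",
        [(-60.0, -45.0), (180.0, 180.0), (-120.0, 140.0), (55.0, -170.0)],
    )
    def test_recovers_constructed_angles(self, phi, psi):
        # geometric oracle: a backbone built by internal-coordinate
        # placement must return the prescribed dihedrals
        n_res = 5
        coords, top = build_backbone([phi] * n_res, [psi] * n_res)
        ens = single_frame_ensemble(coords, top)
        ds = compute_dihedrals(ens)
        assert np.allclose(ds.phi[0, 0, 1:], phi, atol=1e-6)
        assert np.allclose(ds.psi[0, 0, :-1], psi, atol=1e-6)

    def test_terminal_angles_undefined(self):
        coords, top = build_backbone([-60.0] * 4, [-45.0] * 4)
        ds = compute_dihedrals(single_frame_ensemble(coords, top))
        assert np.isnan(ds.phi[0, 0, 0])
        assert np.isnan(ds.psi[0, 0, -1])

    def test_rigid_motion_invariance(self, rng):
        coords, top = build_backbone([-60.0] * 5, [-45.0] * 5)
        rot = Rotation.random(random_state=np.random.RandomState(2)).as_matrix()
        moved = coords @ rot.T + np.array([10.0, -3.0, 7.0])
        d1 = compute_dihedrals(single_frame_ensemble(coords, top))
        d2 = compute_dihedrals(single_frame_ensemble(moved, top))
        assert np.allclose(
            np.nan_to_num(d1.phi), np.nan_to_num(d2.phi), atol=1e-8
        )
        assert np.allclose(
            np.nan_to_num(d1.psi), np.nan_to_num(d2.psi), atol=1e-8
        )

    def test_collinear_atoms_flagged_nan(self):
        p = [np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
             np.array([2.0, 0, 0]), np.array([3.0, 1, 0])]
        assert np.isnan(dihedral_angle(*p))

    def test_angle_range_half_open(self):
        # 180 is reported as +180, never -180
        p0, p1, p2 = np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 1.0, 0])
        p3 = np.array([0.0, 1.0, 0.0])  # cis = 0 deg
        assert dihedral_angle(p0, p1, p2, p3) == pytest.approx(0.0, abs=1e-10)
        p3t = np.array([2.0, 1.0, 0.0])  # trans
        assert dihedral_angle(p0, p1, p2, p3t) == pytest.approx(180.0)


def _random_dihedral_set(rng, n_chains=2, n_frames=10, n_res=153):
    shape = (n_chains, n_frames, n_res)
    mk = lambda: rng.uniform(-179.9, 180.0, shape)
    return DihedralSet(
        np.arange(1, n_res + 1),
        np.array(["GLN"] * n_res, dtype=object),
        mk(), mk(), mk(), mk(),
    )


class TestFeaturizeSincos:
    def test_study_width_612(self, rng):
        ds = _random_dihedral_set(rng)
        fm = featurize_sincos(ds, rama_resids=np.arange(1, 94),
                              janin_resids=np.arange(94, 154))
        assert fm.n_features == (93 + 60) * 2 * 2 == 612

    def test_values_bounded_and_reconstructible(self, rng):
        ds = _random_dihedral_set(rng, n_res=6)
        fm = featurize_sincos(ds, np.arange(1, 7), np.arange(1, 7))
        assert np.all(np.abs(fm.X) <= 1.0)
        # reconstruct phi of residue 1 from the first (sin, cos) pair
        rec = np.degrees(np.arctan2(fm.X[:, 0], fm.X[:, 1]))
        orig = ds.phi[:, :, 0].reshape(-1)
        assert np.allclose(rec, orig, atol=1e-9)

    def test_quadrant_convention(self):
        ds = DihedralSet(
            np.array([1]), np.array(["GLN"], dtype=object),
            *[np.full((1, 1, 1), 90.0) for _ in range(4)],
        )
        fm = featurize_sincos(ds, np.array([1]), np.array([1]))
        assert fm.X[0, 0] == pytest.approx(1.0)  # sin(90)
        assert fm.X[0, 1] == pytest.approx(0.0, abs=1e-12)  # cos(90)

    def test_undefined_angle_in_mask_rejected(self, rng):
        ds = _random_dihedral_set(rng, n_res=6)
        ds.phi[0, 0, 2] = np.nan
        with pytest.raises(ValueError, match="mask"):
            featurize_sincos(ds, np.arange(1, 7), np.arange(1, 7))


def _ca_chain_ensemble(n_res, coords=None, rng=None):
    if coords is None:
        coords = rng.random((n_res, 3)) * 20
    top = Topology(
        np.arange(1, n_res + 1),
        np.array(["ALA"] * n_res, dtype=object),
        np.array(["CA"] * n_res, dtype=object),
        np.array(["C"] * n_res, dtype=object),
    )
    return single_frame_ensemble(coords, top)


class TestFeaturizeCaDistances:
    def test_three_residues_three_features(self, rng):
        fm = featurize_ca_distances(_ca_chain_ensemble(3, rng=rng))
        assert fm.n_features == 3

    def test_exclusion_matches_study_arithmetic(self, rng):
        # 95 residues minus the 7-residue C-terminal tail: 88*87/2 = 3828
        fm = featurize_ca_distances(
            _ca_chain_ensemble(95, rng=rng), exclude_resids=range(89, 96)
        )
        assert fm.n_features == 3828

    def test_equilateral_triangle_equal_features(self):
        side = 4.0
        coords = np.array(
            [[0, 0, 0], [side, 0, 0], [side / 2, side * np.sqrt(3) / 2, 0.0]]
        )
        fm = featurize_ca_distances(_ca_chain_ensemble(3, coords=coords))
        assert np.allclose(fm.X[0], side, atol=1e-12)

    def test_too_few_residues_rejected(self, rng):
        with pytest.raises(ValueError):
            featurize_ca_distances(
                _ca_chain_ensemble(3, rng=rng), exclude_resids=[1, 2]
            )


class TestPca:
    def test_line_gives_full_variance_on_pc1(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t])
        model, proj = pca_fit(FeatureMatrix(X, ["a", "b"]), n_components=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_mean_sample_projects_to_origin(self, rng):
        X = rng.random((40, 5))
        model, _ = pca_fit(FeatureMatrix(X, list("abcde")), n_components=3)
        assert np.allclose(model.project(X.mean(axis=0)[None]), 0.0, atol=1e-9)

    def test_duplicated_feature_shares_loading(self, rng):
        base = rng.standard_normal(100)
        X = np.column_stack([base, base, rng.standard_normal(100) * 0.01])
        model, _ = pca_fit(FeatureMatrix(X, list("abc")), n_components=1)
        # brute-force eigendecomposition oracle on the 2x2 sub-covariance
        assert abs(model.components[0, 0]) == pytest.approx(
            abs(model.components[0, 1]), abs=1e-9
        )
        assert abs(model.components[0, 0]) == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_variance_ratios_sorted_and_bounded(self, rng):
        X = rng.standard_normal((60, 8)) * np.arange(1, 9)
        model, _ = pca_fit(FeatureMatrix(X, [str(i) for i in range(8)]), 8)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(FeatureMatrix(np.ones((10, 3)), list("abc")))


class TestLda:
    def _separated(self, rng, j=4, n=200, n_feat=10, gap=5.0):
        X = rng.standard_normal((n, n_feat))
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X[y == "b", j] += gap
        return FeatureMatrix(X, [f"f{i}" for i in range(n_feat)], y)

    def test_separating_feature_ranks_first(self, rng):
        fm = self._separated(rng)
        _, imp, _ = lda_importance(fm)
        assert np.argmax(imp) == 4

    def test_label_permutation_destroys_separation(self, rng):
        fm = self._separated(rng)
        _, imp, _ = lda_importance(fm)
        perm = rng.permutation(fm.group)
        fm2 = FeatureMatrix(fm.X, fm.feature_labels, perm)
        _, imp2, _ = lda_importance(fm2)
        # the separated feature dominates before permutation, not after
        assert imp[4] / np.median(imp) > 10
        assert imp2[4] / np.median(imp2) < 5

    def test_identical_groups_near_uniform_importance(self, rng):
        X = rng.standard_normal((200, 8))
        y = np.array(["a", "b"] * 100)
        _, imp, _ = lda_importance(FeatureMatrix(X, [str(i) for i in range(8)], y))
        assert imp.max() / np.median(imp) < 10

    def test_zero_within_variance_flagged(self, rng):
        X = rng.standard_normal((40, 3))
        X[:, 1] = np.repeat([0.0, 1.0], 20)  # constant within each group
        y = np.array(["a"] * 20 + ["b"] * 20)
        _, _, flags = lda_importance(FeatureMatrix(X, list("abc"), y))
        assert flags[1] and not flags[0]

    def test_group_requirements(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            lda_importance(FeatureMatrix(X, list("ab"), np.array(["a"] * 10)))


class TestRotamers:
    def _constant_set(self, chi1, chi2):
        shape = (1, 50, 1)
        return DihedralSet(
            np.array([1]), np.array(["GLN"], dtype=object),
            np.full(shape, -60.0), np.full(shape, -45.0),
            np.full(shape, chi1), np.full(shape, chi2),
        )

    def test_single_well_population(self):
        table = rotamer_populations(self._constant_set(60.0, 60.0))
        assert table.populations[0, 0] == 1.0

    def test_state_bin_edges(self):
        assert rotamer_state(0.0) == 0
        assert rotamer_state(119.999) == 0
        assert rotamer_state(120.0) == 1
        assert rotamer_state(180.0) == 1
        assert rotamer_state(-120.0001) == 1
        assert rotamer_state(-120.0) == 2
        assert rotamer_state(-0.0001) == 2

    def test_uniform_angles_near_uniform_table(self, rng):
        n = 30000
        ds = DihedralSet(
            np.array([1]), np.array(["GLN"], dtype=object),
            np.zeros((1, n, 1)), np.zeros((1, n, 1)),
            rng.uniform(-180, 180, (1, n, 1)),
            rng.uniform(-180, 180, (1, n, 1)),
        )
        table = rotamer_populations(ds)
        # multinomial sampling oracle: SE per cell ~ sqrt(p(1-p)/n)
        assert np.all(np.abs(table.populations - 1 / 9) < 4 * np.sqrt((1 / 9) * (8 / 9) / n))

    def test_self_distance_zero(self):
        t = rotamer_populations(self._constant_set(60.0, -60.0))
        assert table_distance(t, t) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_distance_is_metric_like(self, s1, s2):
        rng1 = np.random.default_rng(s1)
        rng2 = np.random.default_rng(s2)
        p1 = rng1.random((3, 3)) + 1e-9
        p2 = rng2.random((3, 3)) + 1e-9
        t1 = RotamerTable(p1 / p1.sum(), np.zeros((3, 3)), 1)
        t2 = RotamerTable(p2 / p2.sum(), np.zeros((3, 3)), 1)
        d12 = table_distance(t1, t2)
        assert 0.0 <= d12 <= 1.0
        assert d12 == pytest.approx(table_distance(t2, t1), abs=1e-15)

    def test_empty_selection_rejected(self, rng):
        ds = self._constant_set(60.0, 60.0)
        with pytest.raises(ValueError):
            rotamer_populations(ds, resname="TRP")


class TestGroupSeparationMechanism:
    def test_pca_separates_and_lda_ranks_gln_features(self):
        # force-field-like separation: group-specific GLN rotamer wells
        g1 = np.zeros((3, 3)); g1[0, 0] = 1.0
        g2 = np.zeros((3, 3)); g2[2, 2] = 1.0
        sets = synth_dihedral_ensembles({"A": g1, "B": g2}, seed=9)
        fms = []
        for g, ds in sets.items():
            fm = featurize_sincos(ds, ds.resid[1:-1], ds.resid, group=g)
            fms.append(fm)
        fm_all = FeatureMatrix(
            np.vstack([f.X for f in fms]),
            fms[0].feature_labels,
            np.concatenate([f.group for f in fms]),
        )
        _, proj = pca_fit(fm_all, 2)
        grp = fm_all.group
        gap = abs(proj[grp == "A", 0].mean() - proj[grp == "B", 0].mean())
        spread = max(proj[grp == "A", 0].std(), proj[grp == "B", 0].std())
        assert gap > 5 * spread
        _, imp, _ = lda_importance(fm_all)
        order = np.argsort(-imp)
        gln = {"3", "9", "15"}
        top6 = [fm_all.feature_labels[i] for i in order[:6]]
        assert all(
            ("chi" in lab) and (lab.split("[")[1].split("]")[0] in gln)
            for lab in top6
        )
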