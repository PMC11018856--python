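"""Superposition, deviation metrics, native contacts, B-factors,
covariance decay, and the equilibration check."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xtalmd.core import Topology, TrajectoryEnsemble
from xtalmd.metrics import (
    B_FROM_RMSF2,
    bfactors,
    build_contact_set,
    covariance_analysis,
    deviation_metrics,
    equilibration_check,
    kabsch_superpose,
    mean_structure,
    native_contacts_q,
    superpose_frames,
)
from xtalmd.synthetic import (
    SyntheticSpec,
    make_template_chain,
    synth_crystal_trajectory,
    synth_observable_series,
)

from conftest import single_frame_ensemble


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        x = rng.random((10, 3))
        rot, t, rmsd = kabsch_superpose(x, x)
        assert np.allclose(rot, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rotation(self, rng):
        x = rng.random((20, 3))
        r0 = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        target = x @ r0.T + np.array([1.0, -2.0, 0.5])
        rot, t, rmsd = kabsch_superpose(x, target)
        assert np.linalg.norm(rot - r0) < 1e-8
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_mirror_image_gets_proper_rotation(self, rng):
        x = rng.random((15, 3))
        mirror = x * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = kabsch_superpose(x, mirror)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.05

    def test_matches_scipy_align_vectors(self, rng):
        # independent oracle for the minimized RMSD
        x = rng.random((12, 3))
        y = x + 0.3 * rng.standard_normal((12, 3))
        _, _, rmsd = kabsch_superpose(x, y)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        _, ssd = Rotation.align_vectors(yc, xc, return_sensitivity=False)
        oracle = ssd / np.sqrt(len(x))
        assert rmsd == pytest.approx(oracle, rel=1e-6)

    def test_too_few_or_collinear_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestDeviationMetrics:
    def test_zero_against_itself(self):
        tmpl, top = make_template_chain(10)
        ens = single_frame_ensemble(tmpl, top, n_frames=3)
        res = deviation_metrics(ens, tmpl, mode="rmsd_time")
        assert np.allclose(res.table["rmsd_mean"], 0.0, atol=1e-10)
        assert res.trailing_mean == pytest.approx(0.0, abs=1e-10)

    def test_rigid_translation_removed_by_superposition(self):
        tmpl, top = make_template_chain(10)
        ens = single_frame_ensemble(tmpl + 5.0, top, n_frames=2)
        res = deviation_metrics(ens, tmpl, mode="rmsd_time")
        assert np.allclose(res.table["rmsd_mean"], 0.0, atol=1e-9)

    def test_single_residue_displacement_msd(self):
        # brute-force oracle: one C-alpha displaced by d in half the frames
        # gives MSD ~ d^2/2 at that residue (alignment leakage << d^2)
        tmpl, top = make_template_chain(50)
        d = 3.0
        ca_idx = np.flatnonzero(top.calpha)[25]
        moved = tmpl.copy()
        moved[ca_idx] += [0, 0, d]
        coords = np.stack([tmpl, moved])[None]  # 1 chain, 2 frames
        ens = TrajectoryEnsemble(coords, top, [1.0, 2.0])
        res = deviation_metrics(ens, tmpl, mode="msd_residue", selection="calpha")
        msd = res.table.set_index("resid")["msd"]
        assert msd.loc[26] == pytest.approx(d**2 / 2, rel=0.05)
        assert msd.drop(26).max() < 0.05 * d**2

    def test_unknown_mode_rejected(self):
        tmpl, top = make_template_chain(5)
        ens = single_frame_ensemble(tmpl, top)
        with pytest.raises(ValueError):
            deviation_metrics(ens, tmpl, mode="bogus")


class TestMeanStructure:
    def test_identical_frames_converge_immediately(self):
        tmpl, top = make_template_chain(10)
        ens = single_frame_ensemble(tmpl, top, n_frames=4)
        mean, iters, _ = mean_structure(ens)
        assert np.allclose(mean, tmpl, atol=1e-12)
        assert iters == 1

    def test_symmetric_pair_averages_to_reference(self):
        # ref +/- delta with delta orthogonal to the rigid modes: the mean
        # is the reference (closed form, small-displacement regime)
        from xtalmd.metrics import _rigid_mode_basis

        tmpl, top = make_template_chain(20)
        rng = np.random.default_rng(3)
        delta = 0.1 * rng.standard_normal(tmpl.shape)
        q = _rigid_mode_basis(tmpl)
        flat = delta.reshape(-1)
        delta = (flat - q @ (q.T @ flat)).reshape(tmpl.shape)
        coords = np.stack([tmpl + delta, tmpl - delta])[None]
        ens = TrajectoryEnsemble(coords, top, [1.0, 2.0])
        mean, _, rmsd_ref = mean_structure(ens, selection="all", ref_coords=tmpl)
        assert rmsd_ref < 1e-3

    def test_requires_multiple_structures(self):
        tmpl, top = make_template_chain(5)
        ens = single_frame_ensemble(tmpl, top, n_frames=1)
        with pytest.raises(ValueError):
            mean_structure(ens)


class TestNativeContactsQ:
    def _ref(self):
        # the toy helix is sparse; widen the (config-exposed) cutoff so a
        # meaningful contact set exists
        tmpl, top = make_template_chain(30)
        contacts = build_contact_set(tmpl, top, cutoff=7.0)
        return tmpl, top, contacts

    def test_reference_scores_one(self):
        tmpl, top, contacts = self._ref()
        assert len(contacts) > 0
        assert native_contacts_q(tmpl, contacts) == 1.0

    def test_scrambled_frame_scores_near_zero(self, rng):
        tmpl, top, contacts = self._ref()
        scrambled = tmpl + rng.normal(0, 10.0, tmpl.shape)
        assert native_contacts_q(scrambled, contacts) < 0.1

    def test_infinite_tolerance_gives_one(self, rng):
        tmpl, top, contacts = self._ref()
        frame = tmpl + rng.normal(0, 2.0, tmpl.shape)
        assert native_contacts_q(frame, contacts, tolerance_factor=np.inf) == 1.0

    def test_monotone_in_tolerance(self, rng):
        tmpl, top, contacts = self._ref()
        frame = tmpl + rng.normal(0, 1.0, tmpl.shape)
        qs = [
            native_contacts_q(frame, contacts, tolerance_factor=f)
            for f in (0.8, 1.0, 1.2, 1.5, 2.0)
        ]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_empty_contacts_rejected(self):
        from xtalmd.metrics import ContactSet

        with pytest.raises(ValueError):
            native_contacts_q(
                np.zeros((3, 3)),
                ContactSet(np.array([], int), np.array([], int), np.array([])),
            )


class TestBFactors:
    def test_static_ensemble_is_zero(self):
        tmpl, top = make_template_chain(10)
        ens = single_frame_ensemble(tmpl, top, n_frames=3)
        for mode in ("lattice", "chain"):
            assert np.allclose(bfactors(ens, mode=mode).b, 0.0, atol=1e-10)

    def test_formula_for_unit_rmsf(self):
        # alternating +/- delta with |delta| = 1 A per atom, orthogonal to
        # the rigid modes, gives RMSF^2 = 1 and B = 8 pi^2 / 3 exactly
        from xtalmd.metrics import _rigid_mode_basis

        n = 40
        theta = np.radians(100.0) * np.arange(n)
        tmpl = np.column_stack(
            [8 * np.cos(theta), 8 * np.sin(theta), 1.5 * np.arange(n)]
        )
        top = Topology(
            np.arange(1, n + 1),
            np.array(["ALA"] * n, dtype=object),
            np.array(["CA"] * n, dtype=object),
            np.array(["C"] * n, dtype=object),
        )
        rng = np.random.default_rng(5)
        delta = rng.standard_normal(tmpl.shape)
        q = _rigid_mode_basis(tmpl)
        for _ in range(200):  # alternating projections: unit norm + no rigid part
            delta /= np.linalg.norm(delta, axis=1, keepdims=True)
            flat = delta.reshape(-1)
            delta = (flat - q @ (q.T @ flat)).reshape(tmpl.shape)
        delta /= np.linalg.norm(delta, axis=1, keepdims=True)
        coords = np.stack([tmpl + delta, tmpl - delta])[None]
        ens = TrajectoryEnsemble(coords, top, [1.0, 2.0])
        prof = bfactors(ens, mode="lattice", ref_coords=tmpl)
        assert prof.b.mean() == pytest.approx(8 * np.pi**2 / 3, rel=0.005)

    def test_lattice_exceeds_chain_with_rigid_motion(self):
        spec = SyntheticSpec(
            n_cells=(1, 1, 1), n_frames=40, n_template_residues=10,
            sigma_int=0.2, sigma_rb=0.5, corr_length=0.0, seed=6,
        )
        ens, _, _ = synth_crystal_trajectory(spec)
        bl = bfactors(ens, mode="lattice")
        bc = bfactors(ens, mode="chain")
        assert bl.b.mean() > bc.b.mean()

    def test_chain_b_matches_covariance_diagonal(self):
        spec = SyntheticSpec(
            n_cells=(1, 1, 1), n_frames=120, n_template_residues=10,
            sigma_int=0.3, sigma_rb=0.2, corr_length=5.0, seed=7,
        )
        ens, _, _ = synth_crystal_trajectory(spec)
        bc = bfactors(ens, mode="chain")
        cd = covariance_analysis(ens, min_frames=100)
        assert np.allclose(bc.rmsf_sq, np.diag(cd.covariance), atol=1e-10)
        assert np.allclose(bc.b, B_FROM_RMSF2 * np.diag(cd.covariance), atol=1e-8)

    def test_single_frame_rejected(self):
        tmpl, top = make_template_chain(5)
        ens = single_frame_ensemble(tmpl, top, n_frames=1)
        with pytest.raises(ValueError):
            bfactors(ens)

    def test_experimental_correlation_reported(self):
        spec = SyntheticSpec(
            n_cells=(1, 1, 1), n_frames=30, n_template_residues=10,
            sigma_int=0.3, sigma_rb=0.0, corr_length=0.0, seed=8,
        )
        ens, _, _ = synth_crystal_trajectory(spec)
        prof = bfactors(ens, mode="chain")
        prof2 = bfactors(ens, mode="chain", experimental_b=prof.b)
        assert prof2.pearson_r == pytest.approx(1.0, abs=1e-9)


class TestCovarianceAnalysis:
    def test_independent_noise_flagged_degenerate(self):
        spec = SyntheticSpec(
            n_cells=(1, 1, 1), n_frames=150, n_template_residues=25,
            sigma_int=0.4, sigma_rb=0.0, corr_length=0.0, seed=5,
        )
        ens, _, _ = synth_crystal_trajectory(spec)
        cd = covariance_analysis(ens)
        assert cd.degenerate

    def test_covariance_matrix_symmetric(self):
        spec = SyntheticSpec(
            n_cells=(1, 1, 1), n_frames=120, n_template_residues=15,
            sigma_int=0.4, sigma_rb=0.0, corr_length=8.0, seed=9,
        )
        ens, _, _ = synth_crystal_trajectory(spec)
        cd = covariance_analysis(ens)
        assert np.allclose(cd.covariance, cd.covariance.T, atol=1e-12)

    def test_recovers_injected_decay_length(self):
        spec = SyntheticSpec(
            n_cells=(1, 1, 1), n_frames=400, n_template_residues=40,
            sigma_int=0.5, sigma_rb=0.3, corr_length=11.0, seed=10,
        )
        ens, truth, _ = synth_crystal_trajectory(spec)
        cd = covariance_analysis(ens)
        assert cd.decay_length == pytest.approx(truth.corr_length, rel=0.10)

    def test_too_few_frames_rejected(self):
        tmpl, top = make_template_chain(10)
        ens = single_frame_ensemble(tmpl, top, n_frames=5)
        with pytest.raises(ValueError):
            covariance_analysis(ens)


class TestEquilibrationCheck:
    def test_stationary_replicas_pass(self):
        series, truth = synth_observable_series("plateau", seed=1)
        report = equilibration_check(series, seed=0)
        assert report.plateau and report.replicas_agree

    def test_monotone_drift_fails_plateau(self):
        series, truth = synth_observable_series("drift", drift_slope=0.01, seed=2)
        assert truth["plateau_should_fail"]
        report = equilibration_check(series, seed=0)
        assert not report.plateau

    def test_offset_replicas_fail_agreement(self):
        series, truth = synth_observable_series(
            "plateau", offsets=np.array([0.0, 0.5, 0.0]), seed=3
        )
        assert truth["agreement_should_fail"]
        report = equilibration_check(series, seed=0)
        assert not report.replicas_agree

    def test_input_validation(self):
        with pytest.raises(ValueError):
            equilibration_check([np.zeros(50)])
        with pytest.raises(ValueError):
            equilibration_check([np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            equilibration_check(
                [np.zeros(30), np.zeros(30)], window_fraction=0.1
            )


class TestSuperpositionInvariance:
    def test_rmsd_invariant_under_global_rigid_motion(self, rng):
        tmpl, top = make_template_chain(15)
        noisy = tmpl + rng.normal(0, 0.5, tmpl.shape)
        _, _, rmsd0 = kabsch_superpose(noisy, tmpl)
        rot = Rotation.random(random_state=np.random.RandomState(11)).as_matrix()
        moved = noisy @ rot.T + np.array([5.0, 6.0, 7.0])
        _, _, rmsd1 = kabsch_superpose(moved, tmpl)
        assert rmsd0 == pytest.approx(rmsd1, abs=1e-9)
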