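"""Coordinate frames, the 6-parameter docking chart, and the docking Z score."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcrpmhc.geometry import (
    ANGULAR_COMPONENTS,
    DockingGeometry,
    Frame,
    GeometryDistribution,
    RigidTransform,
    build_mhc_frame,
    build_tcr_frame,
    compute_docking_geometry,
    fit_geometry_distribution,
    geometry_to_transform,
    kabsch,
    load_geometry_priors,
    mahalanobis_z,
    pseudo_symmetry_transform,
    tcr_frame_from_geometry,
)
from tcrpmhc.geometry import _rotation_about_axis

from conftest import random_geometry_vectors


def angle_diff(a, b):
    return np.angle(np.exp(1j * (a - b)))


def vector_diff(v1, v2):
    dv = np.asarray(v1) - np.asarray(v2)
    for i in ANGULAR_COMPONENTS:
        dv[i] = angle_diff(v1[i], v2[i])
    return dv


def random_rigid(rng):
    return RigidTransform(
        Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix(),
        rng.normal(0, 20, 3),
    )


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(refl, np.zeros(3))

    def test_compose_inverse_is_identity(self, rng):
        t = random_rigid(rng)
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0, atol=1e-12)


class TestPseudoSymmetry:
    def test_exact_c2_set_gives_180_about_axis(self, rng):
        pts = rng.normal(0, 5, (6, 3))
        r180 = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.pi)
        t = pseudo_symmetry_transform(pts, pts @ r180.T)
        assert t.rotation_angle() == pytest.approx(np.pi, abs=1e-10)
        assert abs(t.rotation_axis()[2]) == pytest.approx(1.0, abs=1e-10)
        # zero residual: the transform maps (a,b) exactly onto (b,a)
        stacked = np.vstack([pts, pts @ r180.T])
        target = np.vstack([pts @ r180.T, pts])
        assert np.abs(t.apply(stacked) - target).max() < 1e-10

    def test_matches_independent_superposition_oracle(self, rng):
        """Brute-force oracle: scipy align_vectors on the centered swap problem."""
        a = rng.normal(0, 4, (6, 3))
        b = rng.normal(0, 4, (6, 3)) + [5.0, 0, 0]
        t = pseudo_symmetry_transform(a, b)
        mobile = np.vstack([a, b])
        fixed = np.vstack([b, a])
        rot, _ = Rotation.align_vectors(
            fixed - fixed.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        assert np.abs(t.rotation - rot.as_matrix()).max() < 1e-8

    def test_noisy_symmetric_set_stays_near_180(self, rng):
        pts = rng.normal(0, 5, (6, 3))
        r180 = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi)
        angles = []
        for _ in range(50):
            noisy_b = pts @ r180.T + rng.normal(0, 0.1, (6, 3))
            t = pseudo_symmetry_transform(pts, noisy_b)
            angles.append(np.degrees(t.rotation_angle()))
        assert max(abs(a - 180.0) for a in angles) < 2.0

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(6, dtype=float), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            pseudo_symmetry_transform(line, line + [10.0, 0, 0])


class TestFrames:
    def test_canonical_complex_has_identity_frames(self, canonical_complex, canonical_cores):
        mf = build_mhc_frame(canonical_complex, canonical_cores)
        assert np.abs(mf.origin).max() < 1e-6
        assert np.abs(mf.rotation - np.eye(3)).max() < 1e-6

    def test_frame_equivariance_under_rigid_motion(
        self, canonical_complex, canonical_cores, rng
    ):
        t = random_rigid(rng)
        moved = canonical_complex.transformed(t)
        for build in (build_mhc_frame, build_tcr_frame):
            f0 = build(canonical_complex, canonical_cores)
            f1 = build(moved, canonical_cores)
            assert np.abs(f1.origin - t.apply(f0.origin)).max() < 1e-8
            assert np.abs(f1.rotation - t.rotation @ f0.rotation).max() < 1e-8

    def test_mhc_x_axis_flips_with_peptide_side(self, canonical_complex, canonical_cores):
        """Reflecting the peptide through the frame origin flips the x-axis sign."""
        from tcrpmhc.structure import Residue, TernaryComplex

        flipped_chains = dict(canonical_complex.chains)
        flipped_chains["peptide"] = [
            Residue(r.chain_id, r.seq_index, r.aa, -r.ca_xyz)
            for r in canonical_complex.chain("peptide")
        ]
        flipped = TernaryComplex(flipped_chains, canonical_complex.annotation)
        f0 = build_mhc_frame(canonical_complex, canonical_cores)
        f1 = build_mhc_frame(flipped, canonical_cores)
        assert np.allclose(f1.x_axis, -f0.x_axis, atol=1e-8)

    def test_swapping_tcr_chain_cores_negates_z(self, canonical_complex, canonical_cores):
        from dataclasses import replace

        swapped = replace(
            canonical_cores,
            tcra_core=canonical_cores.tcrb_core,
            tcrb_core=canonical_cores.tcra_core,
        )
        # swap the chains too so indices stay valid
        from tcrpmhc.structure import TernaryComplex

        chains = dict(canonical_complex.chains)
        chains["tcra"], chains["tcrb"] = chains["tcrb"], chains["tcra"]
        ann = canonical_complex.annotation
        f0 = build_tcr_frame(canonical_complex, canonical_cores)
        f1 = build_tcr_frame(
            TernaryComplex(chains, ann), swapped
        )
        assert np.allclose(f1.z_axis, -f0.z_axis, atol=1e-8)


class TestDockingGeometryChart:
    def test_axis_aligned_construction(self):
        tcr = Frame.identity().transformed(
            RigidTransform(np.eye(3), np.array([30.0, 0, 0]))
        )
        g = compute_docking_geometry(Frame.identity(), tcr)
        assert g.d == pytest.approx(30.0)
        assert np.allclose(g.mhc_unit, [1, 0, 0])
        assert np.allclose(g.tcr_unit, [-1, 0, 0])

    def test_round_trip_sweep(self, rng):
        worst = 0.0
        for v in random_geometry_vectors(rng, 300):
            g = DockingGeometry.from_vector(v)
            g2 = compute_docking_geometry(Frame.identity(), tcr_frame_from_geometry(g))
            worst = max(worst, np.abs(vector_diff(v, g2.as_vector())).max())
        assert worst < 1e-6

    def test_invariance_under_global_motion(self, rng):
        for v in random_geometry_vectors(rng, 100):
            g = DockingGeometry.from_vector(v)
            f = tcr_frame_from_geometry(g)
            t = random_rigid(rng)
            g2 = compute_docking_geometry(
                Frame.identity().transformed(t), f.transformed(t)
            )
            assert np.abs(vector_diff(g.as_vector(), g2.as_vector())).max() < 1e-8

    def test_transform_composition_commutes_with_global_motion(self, rng):
        """Moving both frames by T conjugates the relative transform away."""
        v = random_geometry_vectors(rng, 1)[0]
        g = DockingGeometry.from_vector(v)
        rel = geometry_to_transform(g)
        t = random_rigid(rng)
        mhc = Frame.identity().transformed(t)
        tcr = tcr_frame_from_geometry(g).transformed(t)
        g_m = RigidTransform(mhc.rotation, mhc.origin)
        g_t = RigidTransform(tcr.rotation, tcr.origin)
        recovered = g_m.inverse().compose(g_t)
        assert np.abs(recovered.rotation - rel.rotation).max() < 1e-9
        assert np.abs(recovered.translation - rel.translation).max() < 1e-9

    def test_coincident_origins_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            compute_docking_geometry(Frame.identity(), Frame.identity())


class TestGeometryDistribution:
    def test_identical_inputs_give_regularizer_covariance(self):
        g = DockingGeometry.from_vector([28.0, 1.0, 0.5, 0.3, 0.6, -0.4])
        dist = fit_geometry_distribution([g] * 10, mhc_class=1)
        assert np.allclose(dist.mean, g.as_vector())
        assert np.allclose(dist.covariance, 1e-6 * np.eye(6))

    def test_too_few_samples_rejected(self):
        g = DockingGeometry.from_vector([28.0, 1.0, 0.5, 0.3, 0.6, -0.4])
        with pytest.raises(ValueError, match="at least 7"):
            fit_geometry_distribution([g] * 6, mhc_class=1)

    def test_gaussian_mean_recovery(self, rng):
        mean = np.array([28.0, 0.8, 0.6, 0.4, 0.7, -0.5])
        sd = np.array([2.0, 0.3, 0.1, 0.3, 0.1, 0.3])
        n = 500
        samples = rng.normal(mean, sd, (n, 6))
        dist = fit_geometry_distribution(
            [DockingGeometry.from_vector(v) for v in samples], mhc_class=1
        )
        se = sd / np.sqrt(n)
        assert np.all(np.abs(dist.mean - mean) < 3 * se + 1e-9)

    def test_torsion_straddling_pi_unwraps_to_pi(self, rng):
        """Angles split across the +/- pi seam must average near pi, not 0."""
        base = np.array([28.0, np.pi, 0.6, 0.4, 0.7, -0.5])
        samples = rng.normal(base, [1.0, 0.2, 0.05, 0.1, 0.05, 0.1], (100, 6))
        geoms = [DockingGeometry.from_vector(v) for v in samples]
        dist = fit_geometry_distribution(geoms, mhc_class=1)
        assert abs(angle_diff(dist.mean[1], np.pi)) < 0.1

    def test_z_zero_at_mean_and_homogeneous(self):
        mean = np.array([28.0, 0.8, 0.6, 0.4, 0.7, -0.5])
        dist = GeometryDistribution(mean, np.diag([4.0, 0.1, 0.01, 0.1, 0.01, 0.1]),
                                    mhc_class=1, n_samples=100)
        assert mahalanobis_z(DockingGeometry.from_vector(mean), dist) == pytest.approx(0.0)
        delta = np.array([1.0, 0.05, 0.02, 0.05, 0.02, 0.05])
        z1 = mahalanobis_z(DockingGeometry.from_vector(mean + delta), dist)
        z2 = mahalanobis_z(DockingGeometry.from_vector(mean + 2 * delta), dist)
        assert z2 == pytest.approx(2 * z1, rel=1e-9)

    def test_shipped_priors_load(self):
        priors = load_geometry_priors()
        assert set(priors) == {1, 2}
        for dist in priors.values():
            assert dist.covariance.shape == (6, 6)
            assert dist.n_samples >= 7


class TestKabsch:
    def test_recovers_known_transform(self, rng):
        pts = rng.normal(0, 5, (10, 3))
        t = random_rigid(rng)
        est = kabsch(t.apply(pts), pts)
        assert np.abs(est.rotation - t.rotation).max() < 1e-10
        assert np.abs(est.translation - t.translation).max() < 1e-10
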