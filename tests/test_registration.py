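"""Registration: Bhattacharyya metric, GMM overlap, pair and all-to-all."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smlmclassify import (AcquisitionModel, LocalizationSet,
                          RegistrationConfig, RigidTransform, all_to_all,
                          bhattacharyya_score, gmm_overlap, make_template,
                          register_pair, sample_particle, scale_sweep)
from .conftest import random_particle


def brute_force_bhattacharyya(a, b, t=None):
    """Independent double-loop evaluation of the similarity metric."""
    if t is None:
        t = RigidTransform.identity(a.dim)
    bc = t.apply(b.coords)
    acc = 0.0
    for i in range(a.n):
        for j in range(b.n):
            if a.dim == 2:
                v = a.sigma[i]**2 + b.sigma[j]**2
                d2 = np.sum((a.coords[i] - bc[j])**2)
                acc += np.exp(-0.5 * d2 / v) / v
            else:
                sz_a = a.sigma_z if a.sigma_z is not None else a.sigma
                sz_b = b.sigma_z if b.sigma_z is not None else b.sigma
                v_lat = a.sigma[i]**2 + b.sigma[j]**2
                v_z = sz_a[i]**2 + sz_b[j]**2
                d = a.coords[i] - bc[j]
                q = (d[0]**2 + d[1]**2) / v_lat + d[2]**2 / v_z
                acc += np.exp(-0.5 * q) / np.cbrt(v_lat**2 * v_z)
    return acc / (a.n * b.n)


class TestBhattacharyyaScore:
    def test_single_localization_closed_form(self):
        # identical 1-loc particles, sigma=1: S = 1/(1+1) * exp(0) = 0.5
        p = LocalizationSet([[0.0, 0.0]], [1.0])
        assert bhattacharyya_score(p, p) == pytest.approx(0.5)

    def test_decays_to_zero_with_separation(self):
        a = LocalizationSet([[0.0, 0.0]], [1.0])
        b = LocalizationSet([[500.0, 0.0]], [1.0])
        assert bhattacharyya_score(a, b) < 1e-300 * 0.5 + 1e-30

    @pytest.mark.parametrize("na, nb", [(5, 4), (1, 7), (10, 10)])
    def test_matches_double_loop_oracle(self, rng, na, nb):
        a = random_particle(rng, n=na)
        b = random_particle(rng, n=nb)
        t = RigidTransform(0.7, np.array([5.0, -3.0]))
        got = bhattacharyya_score(a, b, t)
        want = brute_force_bhattacharyya(a, b, t)
        assert got == pytest.approx(want, rel=1e-12)

    def test_3d_anisotropic_matches_oracle(self, rng):
        a = random_particle(rng, n=6, dim=3, anisotropic=True)
        b = random_particle(rng, n=5, dim=3, anisotropic=True)
        got = bhattacharyya_score(a, b)
        assert got == pytest.approx(brute_force_bhattacharyya(a, b), rel=1e-12)

    def test_3d_isotropic_reduces_to_isotropic_form(self, rng):
        a = random_particle(rng, n=4, dim=3)
        b = random_particle(rng, n=4, dim=3)
        # with sigma_z = sigma the anisotropic kernel is the plain 3D form
        bc = b.coords
        v = a.sigma2[:, None] + b.sigma2[None, :]
        d2 = ((a.coords[:, None] - bc[None])**2).sum(axis=2)
        want = np.sum(np.exp(-0.5 * d2 / v) / v) / (a.n * b.n)
        assert bhattacharyya_score(a, b) == pytest.approx(want, rel=1e-12)

    def test_duplication_invariance(self, rng):
        # doubling every localization (K -> 2K) cancels in 1/(Ka*Kb)
        a = random_particle(rng, n=5)
        b = random_particle(rng, n=4)
        a2 = LocalizationSet(np.tile(a.coords, (2, 1)), np.tile(a.sigma, 2))
        b2 = LocalizationSet(np.tile(b.coords, (2, 1)), np.tile(b.sigma, 2))
        assert bhattacharyya_score(a2, b2) == pytest.approx(
            bhattacharyya_score(a, b), rel=1e-12)

    def test_rejects_dim_mismatch(self, rng):
        with pytest.raises(ValueError):
            bhattacharyya_score(random_particle(rng, n=3),
                                random_particle(rng, n=3, dim=3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_numba_kernel_agrees_with_oracle(self, seed):
        from smlmclassify._kernels import bhat_sum_2d
        r = np.random.default_rng(seed)
        a = random_particle(r, n=int(r.integers(1, 10)))
        b = random_particle(r, n=int(r.integers(1, 10)))
        th, tx, ty = r.uniform(-3, 3, 3)
        t = RigidTransform(float(th), np.array([tx, ty]))
        buf = np.empty(max(a.n, b.n))
        got = bhat_sum_2d(
            np.ascontiguousarray(a.coords[:, 0]),
            np.ascontiguousarray(a.coords[:, 1]), a.sigma2,
            np.ascontiguousarray(b.coords[:, 0]),
            np.ascontiguousarray(b.coords[:, 1]), b.sigma2,
            np.cos(th), np.sin(th), tx, ty, buf, buf.copy())
        assert got == pytest.approx(brute_force_bhattacharyya(a, b, t),
                                    rel=1e-10)


class TestGmmOverlap:
    def test_matches_pair_integral_oracle(self, rng):
        a = random_particle(rng, n=5)
        b = random_particle(rng, n=3)
        s = 8.0
        acc = 0.0
        for i in range(a.n):
            for j in range(b.n):
                d2 = np.sum((a.coords[i] - b.coords[j])**2)
                acc += np.exp(-d2 / (4 * s**2)) / (4 * np.pi * s**2)
        want = acc / (a.n * b.n)
        assert gmm_overlap(a, b, s) == pytest.approx(want, rel=1e-12)

    def test_self_overlap_maximal_at_identity(self, rng):
        a = random_particle(rng, n=8)
        base = gmm_overlap(a, a, 5.0)
        for th, tx in [(0.3, 0.0), (0.0, 4.0), (1.0, -7.0)]:
            t = RigidTransform(th, np.array([tx, 1.0]))
            assert gmm_overlap(a, a, 5.0, t) <= base + 1e-12

    def test_rigid_invariance(self, rng):
        a = random_particle(rng, n=6)
        b = random_particle(rng, n=6)
        g = RigidTransform(1.1, np.array([12.0, -4.0]))
        assert gmm_overlap(a.transformed(g), b.transformed(g), 6.0) == \
            pytest.approx(gmm_overlap(a, b, 6.0), rel=1e-10)

    def test_rejects_bad_scale(self, rng):
        with pytest.raises(ValueError):
            gmm_overlap(random_particle(rng), random_particle(rng), 0.0)


def _noise_free_particle(template="L", sigma=2.0):
    t = make_template("dots", pattern=template)
    acq = AcquisitionModel(dol=1.0, locs_mean=3.0, locs_dist="fixed",
                           sigma_mean=sigma, sigma_dist="fixed")
    rng = np.random.default_rng(0)
    coords = np.repeat(t.site_coords, 3, axis=0)
    return LocalizationSet(coords, np.full(len(coords), sigma))


class TestRegisterPair:
    def test_pose_recovery_noise_free(self):
        # rotated+translated copy: rotation within 1 deg, translation 0.5 nm
        a = _noise_free_particle()
        true = RigidTransform(np.deg2rad(70.0), np.array([9.0, -6.0]))
        b = a.transformed(true)
        cfg = RegistrationConfig(scale_px=0.05)
        t, s, _ = register_pair(a, b, cfg)
        # t maps b back onto a, i.e. t == true^{-1}
        err_rot = np.rad2deg(abs(np.angle(np.exp(1j * (t.rotation + true.rotation)))))
        assert err_rot < 1.0
        assert np.linalg.norm(t.apply(b.coords) - a.coords, axis=1).max() < 0.5
        assert s == pytest.approx(bhattacharyya_score(a, a), rel=1e-2)

    def test_self_registration_is_optimal(self, rng):
        a = random_particle(rng, n=12, spread=30.0)
        cfg = RegistrationConfig(scale_px=0.05)
        _, s_best, _ = register_pair(a, a, cfg)
        for th in (0.5, 2.0, 4.0):
            t = RigidTransform(th, np.array([3.0, -2.0]))
            assert s_best >= bhattacharyya_score(a, a, t) - 1e-12

    def test_mirrored_asymmetric_scores_below_self(self):
        # reflections are never searched, so a mirrored copy cannot reach
        # the self-match similarity
        a = _noise_free_particle("L")
        m = a.mirrored()
        cfg = RegistrationConfig(scale_px=0.05)
        _, s_self, _ = register_pair(a, a, cfg)
        _, s_mirror, _ = register_pair(a, m, cfg)
        assert s_mirror < 0.8 * s_self

    def test_score_symmetry_after_optimization(self):
        t8 = make_template("ring", n_fold=8, diameter=107.0)
        acq = AcquisitionModel(dol=0.7, locs_mean=6.0, sigma_mean=3.0)
        rng = np.random.default_rng(5)
        cfg = RegistrationConfig(scale_px=0.08)
        rel = []
        for _ in range(5):
            a = sample_particle(t8, acq, rng)
            b = sample_particle(t8, acq, rng)
            _, s_ab, _ = register_pair(a, b, cfg)
            _, s_ba, _ = register_pair(b, a, cfg)
            rel.append(abs(s_ab - s_ba) / max(s_ab, s_ba))
        assert np.median(rel) < 0.05

    def test_degenerate_small_particles_use_identity(self):
        a = LocalizationSet([[0.0, 0.0], [10.0, 0.0]], [2.0, 2.0])
        b = LocalizationSet([[0.0, 0.0], [10.0, 0.0]], [2.0, 2.0])
        t, s, diag = register_pair(a, b, RegistrationConfig(scale_px=0.05))
        assert diag.get("degenerate")
        assert t.rotation == 0.0 and np.all(t.translation == 0.0)
        assert s == pytest.approx(bhattacharyya_score(a, b))

    def test_3d_pose_recovery(self):
        # asymmetric 3D constellation (a tetrahedron would only be
        # recoverable modulo its 3-fold symmetry about the apex axis)
        rng = np.random.default_rng(2)
        sites = rng.uniform(-50.0, 50.0, size=(6, 3))
        coords = np.repeat(sites, 3, axis=0)
        a = LocalizationSet(coords, np.full(len(coords), 3.0))
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [40.0, 25.0, -15.0], degrees=True)
        true = RigidTransform(R.as_matrix(), np.array([8.0, -5.0, 12.0]))
        b = a.transformed(true)
        cfg = RegistrationConfig(scale_px=0.08, maxfev=200)
        tr, s, _ = register_pair(a, b, cfg)
        assert np.linalg.norm(tr.apply(b.coords) - a.coords, axis=1).max() < 2.0
        assert s > 0.8 * bhattacharyya_score(a, a)


class TestScaleSweep:
    @pytest.fixture(scope="class")
    def ring_particles(self):
        t8 = make_template("ring", n_fold=8, diameter=107.0)
        acq = AcquisitionModel(dol=0.7, locs_mean=6.0, sigma_mean=3.0)
        rng = np.random.default_rng(2)
        return [sample_particle(t8, acq, rng) for _ in range(8)]

    def test_sweep_range_endpoints_in_nm(self):
        cfg = RegistrationConfig(scale_px=0.001)
        assert cfg.scale_nm == pytest.approx(0.13)
        assert RegistrationConfig(scale_px=0.5).scale_nm == pytest.approx(65.0)

    def test_result_inside_range_and_deterministic(self, ring_particles):
        best1, scales, curve = scale_sweep(ring_particles, n_pairs=4,
                                           n_scales=10, seed=3)
        best2, _, _ = scale_sweep(ring_particles, n_pairs=4, n_scales=10,
                                  seed=3)
        assert best1 == best2
        assert scales[0] <= best1 <= scales[-1]
        assert len(curve) == 10 and np.isclose(curve.max(), curve.max())

    def test_needs_two_particles(self, ring_particles):
        with pytest.raises(ValueError):
            scale_sweep(ring_particles[:1])


class TestAllToAll:
    @pytest.fixture(scope="class")
    def toy(self):
        t = make_template("dots", pattern="digit2")
        acq = AcquisitionModel(dol=0.8, locs_mean=5.0, sigma_mean=2.5)
        rng = np.random.default_rng(9)
        parts = [sample_particle(t, acq, rng) for _ in range(3)]
        cfg = RegistrationConfig(scale_px=0.05)
        return parts, cfg, all_to_all(parts, cfg)

    def test_matrix_matches_per_pair_registration(self, toy):
        parts, cfg, rr = toy
        S = np.zeros((3, 3))
        for i in range(3):
            for j in range(i + 1, 3):
                _, s, _ = register_pair(parts[i], parts[j], cfg)
                S[i, j] = S[j, i] = s
        off = ~np.eye(3, dtype=bool)
        D_want = S[off].max() - S
        np.fill_diagonal(D_want, 0.0)
        assert np.allclose(rr.S[off], S[off], rtol=1e-10)
        assert np.allclose(rr.D[off], D_want[off], rtol=1e-8)

    def test_dissimilarity_contract(self, toy):
        _, _, rr = toy
        off = ~np.eye(rr.n_particles, dtype=bool)
        assert np.allclose(rr.D, rr.D.T)
        assert (rr.D[off] >= 0).all()
        assert np.isclose(rr.D[off].min(), 0.0)   # best pair has D = 0
        assert np.all(np.diag(rr.D) == 0)

    def test_transforms_map_pairs_together(self, toy):
        parts, _, rr = toy
        # stored transform for (a, b) reproduces the S value
        s = bhattacharyya_score(parts[0], parts[1], rr.transform(0, 1))
        assert s == pytest.approx(rr.S[0, 1], rel=1e-10)
        # reverse direction is the inverse transform
        tf = rr.transform(1, 0)
        ti = rr.transform(0, 1).inverse()
        assert tf.rotation == pytest.approx(ti.rotation)
        assert np.allclose(tf.translation, ti.translation)

    def test_chunked_execution_is_order_independent(self, toy):
        parts, cfg, rr = toy
        rr2 = all_to_all(parts, cfg, progress=True)
        assert np.array_equal(rr.S, rr2.S)
        assert np.array_equal(rr.tparams, rr2.tparams)

    def test_needs_scale(self, toy):
        parts, _, _ = toy
        with pytest.raises(ValueError, match="scale"):
            all_to_all(parts, RegistrationConfig())
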