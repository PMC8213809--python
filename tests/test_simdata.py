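"""Synthetic data generator: templates, acquisition statistics, mixtures."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from smlmclassify import (AcquisitionModel, MixtureComponent, MixtureSpec,
                          RigidTransform, make_dataset, make_template,
                          sample_particle)
from smlmclassify.simdata import _exact_counts


class TestTemplates:
    def test_grid_12_sites_20nm(self):
        t = make_template("grid", rows=3, cols=4, spacing=20.0)
        assert t.n_sites == 12
        d = pdist(t.site_coords)
        assert np.isclose(d.min(), 20.0)
        # centered at the origin
        assert np.allclose(t.site_coords.mean(axis=0), 0.0)

    @pytest.mark.parametrize("n_fold, expected_deg", [(8, 45.0), (9, 40.0)])
    def test_ring_angular_spacing(self, n_fold, expected_deg):
        t = make_template("ring", n_fold=n_fold, diameter=107.0)
        assert t.n_sites == n_fold
        ang = np.sort(np.arctan2(t.site_coords[:, 1], t.site_coords[:, 0]))
        gaps = np.degrees(np.diff(ang))
        assert np.allclose(gaps, expected_deg)
        assert np.allclose(np.linalg.norm(t.site_coords, axis=1), 53.5)

    def test_tetrahedron_geometry(self):
        t = make_template("tetrahedron", edge=100.0, height=90.0)
        assert t.dim == 3 and t.n_sites == 4
        z = t.site_coords[:, 2]
        assert np.isclose(z.max() - z.min(), 90.0)
        base = t.site_coords[np.argsort(z)[:3]]
        assert np.allclose(pdist(base), 100.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_template("banana")
        with pytest.raises(ValueError):
            make_template("grid", spacing=-1.0)
        with pytest.raises(ValueError):
            make_template("ring", diameter=0.0)
        with pytest.raises(ValueError):
            make_template("dots", pattern="no-such-glyph")


class TestSampleParticle:
    def test_noise_free_limit_reproduces_sites(self):
        t = make_template("grid", rows=3, cols=4, spacing=20.0)
        acq = AcquisitionModel(dol=1.0, locs_mean=1.0, locs_dist="fixed",
                               sigma_mean=1e-9, sigma_dist="fixed")
        p = sample_particle(t, acq, np.random.default_rng(0))
        assert p.n == 12
        # localizations coincide with the sites up to the 1e-9 sigma
        d = np.linalg.norm(p.coords[:, None] - t.site_coords[None], axis=2)
        assert d.min(axis=1).max() < 1e-6

    def test_underlabeling_binomial_expectation(self):
        # DoL 0.5 on a 12-site grid: mean retained sites per particle = 6
        t = make_template("grid", rows=3, cols=4, spacing=20.0)
        acq = AcquisitionModel(dol=0.5, locs_mean=1.0, locs_dist="fixed",
                               sigma_mean=1e-9, sigma_dist="fixed")
        rng = np.random.default_rng(7)
        counts = [sample_particle(t, acq, rng).n for _ in range(2000)]
        se = np.sqrt(12 * 0.25 / 2000)
        assert abs(np.mean(counts) - 6.0) < 4 * se + 0.01

    def test_mirror_is_exact_reflection_under_same_seed(self):
        t = make_template("dots", pattern="L")
        acq = AcquisitionModel(dol=0.8, locs_mean=5.0, sigma_mean=2.0)
        a = sample_particle(t, acq, np.random.default_rng(3), mirror=False)
        b = sample_particle(t, acq, np.random.default_rng(3), mirror=True)
        ref = a.coords.copy()
        ref[:, -1] *= -1
        assert np.array_equal(b.coords, ref)
        assert np.array_equal(a.sigma, b.sigma)

    def test_noise_calibration_matches_sigma_distribution(self):
        # empirical per-axis RMS deviation == sqrt(E[sigma^2]) of the Gamma
        t = make_template("ring", n_fold=8, diameter=107.0)
        acq = AcquisitionModel(dol=1.0, locs_mean=20.0, sigma_mean=3.0,
                               sigma_shape=9.0)
        rng = np.random.default_rng(11)
        dev = []
        for _ in range(100):
            p = sample_particle(t, acq, rng)
            d = np.linalg.norm(p.coords[:, None] - t.site_coords[None], axis=2)
            site = np.argmin(d, axis=1)
            dev.append(p.coords - t.site_coords[site])
        dev = np.concatenate(dev)
        assert dev.shape[0] > 10_000
        rms = np.sqrt(np.mean(dev**2))
        expected = 3.0 * np.sqrt(1 + 1 / 9.0)   # sqrt(E[sigma^2]), Gamma k=9
        assert abs(rms - expected) / expected < 0.05

    def test_deformation_preserves_area_and_scales_axes(self):
        t = make_template("ring", n_fold=8, diameter=100.0)
        acq = AcquisitionModel(dol=1.0, locs_mean=1.0, locs_dist="fixed",
                               sigma_mean=1e-9, sigma_dist="fixed")
        p = sample_particle(t, acq, np.random.default_rng(0), deformation=1.44)
        x_ext = p.coords[:, 0].max() - p.coords[:, 0].min()
        y_ext = p.coords[:, 1].max() - p.coords[:, 1].min()
        assert x_ext / y_ext == pytest.approx(1.44, rel=1e-3)


class TestMakeDataset:
    def _spec(self, seed, mode="multinomial", n=200, fractions=(0.98, 0.02)):
        t8 = make_template("ring", n_fold=8, diameter=107.0)
        t9 = make_template("ring", n_fold=9, diameter=107.0)
        return MixtureSpec(
            components=[MixtureComponent(t8, fractions[0]),
                        MixtureComponent(t9, fractions[1])],
            n_particles=n, seed=seed, count_mode=mode)

    def test_fractions_must_sum_to_one(self):
        t = make_template("ring", n_fold=8)
        with pytest.raises(ValueError, match="sum"):
            MixtureSpec(components=[MixtureComponent(t, 0.6),
                                    MixtureComponent(t, 0.3)],
                        n_particles=10, seed=0)

    def test_single_component_all_labels_identical(self):
        t = make_template("grid")
        spec = MixtureSpec(components=[MixtureComponent(t, 1.0)],
                           n_particles=25, seed=0)
        ds = make_dataset(spec, AcquisitionModel())
        assert np.all(ds.labels == 0)

    def test_same_seed_identical_output(self):
        acq = AcquisitionModel()
        a = make_dataset(self._spec(5), acq)
        b = make_dataset(self._spec(5), acq)
        assert np.array_equal(a.labels, b.labels)
        for p, q in zip(a.particles, b.particles):
            assert np.array_equal(p.coords, q.coords)
            assert np.array_equal(p.sigma, q.sigma)

    def test_rare_class_count_expectation(self):
        # fractions (0.98, 0.02) at n=500: expectation 10 rare particles
        acq = AcquisitionModel(locs_mean=1.0, locs_dist="fixed")
        counts = [np.sum(make_dataset(self._spec(s, n=500), acq).labels == 1)
                  for s in range(12)]
        mean = np.mean(counts)
        se = np.sqrt(500 * 0.02 * 0.98 / len(counts))
        assert abs(mean - 10.0) < 4 * se

    def test_exact_count_mode(self):
        ds = make_dataset(self._spec(3, mode="exact", n=500), AcquisitionModel())
        assert np.sum(ds.labels == 1) == 10
        assert np.sum(ds.labels == 0) == 490

    def test_exact_counts_largest_remainder(self):
        counts = _exact_counts(np.array([0.5, 0.3, 0.2]), 7)
        assert counts.sum() == 7
        assert np.array_equal(np.sort(counts)[::-1], [4, 2, 1])

    def test_label_bookkeeping(self):
        ds = make_dataset(self._spec(9, n=300), AcquisitionModel())
        assert len(ds.particles) == 300 == len(ds.poses)
        assert np.bincount(ds.labels, minlength=2).sum() == 300

    def test_mirror_component_flag(self):
        t = make_template("dots", pattern="L")
        spec = MixtureSpec(
            components=[MixtureComponent(t, 0.5),
                        MixtureComponent(t, 0.5, mirror=True)],
            n_particles=20, seed=1, count_mode="exact")
        ds = make_dataset(spec, AcquisitionModel())
        assert ds.class_names == ["dots-L", "dots-L~mirror"]
        assert np.sum(ds.labels == 1) == 10


def test_acquisition_model_validation():
    with pytest.raises(ValueError):
        AcquisitionModel(dol=0.0)
    with pytest.raises(ValueError):
        AcquisitionModel(dol=1.2)
    with pytest.raises(ValueError):
        AcquisitionModel(sigma_mean=-1.0)
    with pytest.raises(ValueError):
        AcquisitionModel(locs_mean=0.0)


def test_pose_application_order():
    # pose acts after mirroring: a pure translation moves every localization
    t = make_template("grid")
    acq = AcquisitionModel(dol=1.0, locs_mean=1.0, locs_dist="fixed",
                           sigma_mean=1e-9, sigma_dist="fixed")
    pose = RigidTransform(0.0, np.array([100.0, -50.0]))
    p0 = sample_particle(t, acq, np.random.default_rng(2))
    p1 = sample_particle(t, acq, np.random.default_rng(2), pose=pose)
    assert np.allclose(p1.coords, p0.coords + np.array([100.0, -50.0]))
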