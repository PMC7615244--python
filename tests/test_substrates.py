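"""Diameter distributions, discretisation, bundle geometry, Watson dispersion."""

import numpy as np
import pytest

from tdrsim import (
    DiameterDistribution,
    Substrate,
    discretise,
    fibre_configuration,
    watson_orientations,
)
from tdrsim.substrates import truncation_mean_shift


class TestPresets:
    @pytest.mark.parametrize(
        "name,geometry,mean,std",
        [
            ("small_cylinders", "cylinder", 1.93, 0.81),
            ("large_cylinders", "cylinder", 5.33, 3.00),
            ("small_spheres", "sphere", 7.0, 0.5),
            ("large_spheres", "sphere", 15.0, 0.5),
        ],
    )
    def test_reference_distributions(self, substrates, name, geometry, mean, std):
        sub = substrates[name]
        assert sub.geometry == geometry
        assert sub.distribution.mean == mean
        assert sub.distribution.std == std
        assert sub.diffusivity == 2.0

    def test_gamma_shape_scale_recover_moments(self):
        d = DiameterDistribution("gamma", mean=5.33, std=3.00)
        assert d.gamma_shape * d.gamma_scale == pytest.approx(5.33)
        assert np.sqrt(d.gamma_shape) * d.gamma_scale == pytest.approx(3.00)


class TestDiscretise:
    def test_point_mass(self):
        wd = discretise(DiameterDistribution("delta", mean=5.0, std=0.0), "cylinder")
        assert wd.diameters.tolist() == [5.0]
        assert wd.weights.tolist() == [1.0]

    @pytest.mark.parametrize("geometry", ["cylinder", "sphere"])
    @pytest.mark.parametrize("n_bins", [1, 10, 50])
    def test_weights_normalised_and_truncated(self, geometry, n_bins):
        dist = DiameterDistribution("gamma", mean=5.33, std=3.00)
        wd = discretise(dist, geometry, n_bins=n_bins)
        assert wd.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(wd.diameters > 0)
        assert np.all(wd.diameters <= 20.0)

    def test_moments_stable_under_bin_doubling(self):
        """Number- and volume-weighted means change <0.5% from 50 to 100 bins."""
        dist = DiameterDistribution("gamma", mean=5.33, std=3.00)
        for geometry in ("cylinder", "sphere"):
            m = {}
            for nb in (50, 100):
                wd = discretise(dist, geometry, n_bins=nb)
                m[nb] = float(wd.weights @ wd.diameters)
            assert abs(m[100] - m[50]) / m[50] < 0.005

    def test_volume_weighting_shifts_mass_to_large_pores(self):
        dist = DiameterDistribution("gamma", mean=5.33, std=3.00)
        wd = discretise(dist, "cylinder", n_bins=100)
        assert float(wd.weights @ wd.diameters) > dist.mean

    def test_truncation_admissibility_rule(self):
        """Large-cylinder reference passes the 10% truncated-mean rule."""
        ok = DiameterDistribution("gamma", mean=5.33, std=3.00)
        assert truncation_mean_shift(ok) < 0.10
        heavy_tail = DiameterDistribution("gamma", mean=12.0, std=10.0)
        assert truncation_mean_shift(heavy_tail) > 0.10

    def test_invalid_args(self):
        dist = DiameterDistribution("gamma", mean=5.33, std=3.00)
        with pytest.raises(ValueError):
            discretise(dist, "cylinder", n_bins=0)
        with pytest.raises(ValueError):
            discretise(dist, "cube")


class TestFibreConfiguration:
    def test_single_bundle_along_x(self):
        assert fibre_configuration(1) == ((1.0, 0.0, 0.0),)

    @pytest.mark.parametrize("n", [2, 3])
    def test_mutually_orthogonal_unit_axes(self, n):
        axes = np.array(fibre_configuration(n))
        np.testing.assert_allclose(np.linalg.norm(axes, axis=1), 1.0)
        dots = axes @ axes.T - np.eye(n)
        np.testing.assert_allclose(dots, 0.0, atol=1e-15)

    def test_unsupported_count(self):
        with pytest.raises(ValueError):
            fibre_configuration(4)


class TestSubstrateValidation:
    def test_sphere_rejects_axes(self):
        with pytest.raises(ValueError):
            Substrate(
                geometry="sphere",
                distribution=DiameterDistribution("normal", mean=7.0, std=0.5),
                bundle_axes=((1.0, 0.0, 0.0),),
            )

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            Substrate(
                geometry="cylinder",
                distribution=DiameterDistribution("gamma", mean=5.33, std=3.0),
                bundle_axes=((1.0, 1.0, 0.0),),
            )

    def test_equal_fractions_default(self):
        sub = Substrate(
            geometry="cylinder",
            distribution=DiameterDistribution("gamma", mean=5.33, std=3.0),
            bundle_axes=fibre_configuration(3),
        )
        assert sub.bundle_fractions == (pytest.approx(1 / 3),) * 3


class TestWatson:
    def test_weights_normalised_and_antipodal(self):
        os_ = watson_orientations(6.0, (0.0, 0.0, 1.0), n_samples=200)
        assert os_.weights.sum() == pytest.approx(1.0)
        n = len(os_.weights) // 2
        # grid is built as hemisphere + antipodes with identical density weight
        np.testing.assert_allclose(os_.vectors[:n], -os_.vectors[n:])
        np.testing.assert_allclose(os_.weights[:n], os_.weights[n:])

    def test_high_concentration_close_to_mean_axis(self):
        """κ=100 puts >90% of the weight within 15° of ±μ."""
        mu = np.array([0.0, 0.0, 1.0])
        os_ = watson_orientations(100.0, mu, n_samples=500)
        ang = np.degrees(np.arccos(np.abs(np.clip(os_.vectors @ mu, -1, 1))))
        assert os_.weights[ang <= 15.0].sum() > 0.90

    def test_concentration_orders_weight_fractions(self):
        mu = np.array([0.0, 0.0, 1.0])
        fracs = []
        for kappa in (1.0, 6.0, 100.0):
            os_ = watson_orientations(kappa, mu, n_samples=500)
            ang = np.degrees(np.arccos(np.abs(np.clip(os_.vectors @ mu, -1, 1))))
            fracs.append(os_.weights[ang <= 15.0].sum())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_infinite_concentration_limit(self):
        """Very large κ collapses the effective orientation onto the axis."""
        mu = np.array([0.0, 0.0, 1.0])
        os_ = watson_orientations(1e5, mu, n_samples=500)
        mean_cos2 = float(os_.weights @ (os_.vectors @ mu) ** 2)
        assert mean_cos2 > 0.99

    def test_sampled_mode_reproducible(self):
        a = watson_orientations(6.0, (1.0, 0.0, 0.0), n_samples=100, seed=7)
        b = watson_orientations(6.0, (1.0, 0.0, 0.0), n_samples=100, seed=7)
        np.testing.assert_array_equal(a.vectors, b.vectors)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            watson_orientations(0.0)
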