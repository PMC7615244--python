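"""TDR statistics: subsets, Rician noise, ensembles, cross-config variation."""

import math

import numpy as np
import pytest

from tdrsim import (
    NoiseSpec,
    ShellSignals,
    Substrate,
    add_rician_noise,
    cov_across_configs,
    fibre_configuration,
    preset_substrates,
    spherical_mean,
    substrate_shell,
    tdr,
    tdr_noise_ensemble,
    tdr_subset,
    tdr_subset_curve,
)
from tdrsim.tdr import DegenerateSignalError, ensemble_curves


def _shell(signals, dirs=None, w=None, noisy=False):
    from tdrsim import SDEWaveform

    signals = np.asarray(signals, dtype=float)
    if dirs is None:
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(signals.shape[0], 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if w is None:
        w = SDEWaveform.from_b(8.0, 6.9, 9.0)
    return ShellSignals(w, dirs, signals, noisy=noisy)


class TestBasics:
    def test_spherical_mean_constant(self):
        assert spherical_mean(_shell([0.3] * 7)) == pytest.approx(0.3)

    def test_spherical_mean_empty_raises(self):
        with pytest.raises(ValueError):
            spherical_mean(np.array([]))

    def test_tdr_equal_signals_zero(self):
        assert tdr(0.4, 0.4) == 0.0

    def test_tdr_negative_allowed(self):
        assert tdr(0.5, 0.4) < 0.0

    def test_tdr_degenerate_raises(self):
        with pytest.raises(DegenerateSignalError):
            tdr(0.1, 0.0)

    def test_tdr_scale_invariant(self):
        assert tdr(0.2, 0.5) == pytest.approx(tdr(0.02, 0.05))


class TestSubsets:
    def test_hand_worked_top_two(self):
        """Top-2 of s2=[.9,.5,.1], s1=[.6,.3,.1]: (1.4-0.9)/1.4."""
        s1 = _shell([0.6, 0.3, 0.1])
        s2 = _shell([0.9, 0.5, 0.1], dirs=s1.directions)
        assert tdr_subset(s1, s2, 2) == pytest.approx((1.4 - 0.9) / 1.4)

    def test_full_set_equals_spherical_mean_tdr(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.05, 0.4, size=30)
        b = a + rng.uniform(0.0, 0.3, size=30)
        s1, s2 = _shell(a), None
        s2 = _shell(np.clip(b, 0, 1), dirs=s1.directions)
        assert tdr_subset(s1, s2, 30) == pytest.approx(
            tdr(spherical_mean(s1), spherical_mean(s2))
        )

    def test_permutation_invariance_at_full_M(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.1, 0.5, 20)
        b = rng.uniform(0.2, 0.9, 20)
        perm = rng.permutation(20)
        s1, s2 = _shell(a), None
        s2 = _shell(b, dirs=s1.directions)
        s1p = _shell(a[perm], dirs=s1.directions)
        s2p = _shell(b[perm], dirs=s1.directions)
        assert tdr_subset(s1p, s2p, 20) == pytest.approx(tdr_subset(s1, s2, 20))

    def test_mismatched_directions_rejected(self):
        s1 = _shell([0.1, 0.2, 0.3])
        other = np.roll(s1.directions, 1, axis=0)
        s2 = _shell([0.1, 0.2, 0.3], dirs=other)
        with pytest.raises(ValueError):
            tdr_subset(s1, s2, 2)

    def test_invalid_M(self):
        s1 = _shell([0.1, 0.2])
        s2 = _shell([0.1, 0.2], dirs=s1.directions)
        with pytest.raises(ValueError):
            tdr_subset(s1, s2, 0)
        with pytest.raises(ValueError):
            tdr_subset(s1, s2, 3)

    def test_noise_free_curve_constant_in_M(self, preclinical_optimum, dirs60):
        """Without noise the sorted-subset statistic is flat in M."""
        sub = preset_substrates()["large_cylinders"]
        s1 = substrate_shell(sub, preclinical_optimum.shell1, dirs60)
        s2 = substrate_shell(sub, preclinical_optimum.shell2, dirs60)
        curve = tdr_subset_curve(s1.signals, s2.signals)
        assert np.ptp(curve) < 0.01


class TestRicianNoise:
    def test_infinite_snr_identity(self):
        s = _shell([0.2, 0.5, 0.8])
        out = add_rician_noise(s, NoiseSpec(math.inf, 1, 0))
        assert out is s

    def test_zero_signal_floor(self):
        """|n1 + i n2| for zero signal has mean σ√(π/2)."""
        sigma = 1 / 20
        s = _shell(np.zeros(200_000))
        out = add_rician_noise(s, NoiseSpec(20.0, 1, 11))
        assert out.signals.mean() == pytest.approx(
            sigma * math.sqrt(math.pi / 2), rel=0.01
        )

    def test_seeded_reproducibility(self):
        s = _shell([0.2, 0.5, 0.8])
        a = add_rician_noise(s, NoiseSpec(20.0, 1, 5)).signals
        b = add_rician_noise(s, NoiseSpec(20.0, 1, 5)).signals
        np.testing.assert_array_equal(a, b)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            NoiseSpec(-1.0, 10, 0)
        with pytest.raises(ValueError):
            NoiseSpec(20.0, 0, 0)


@pytest.fixture(scope="module")
def bundle_shells(preclinical_optimum, dirs60):
    sub = preset_substrates()["large_cylinders"]
    s1 = substrate_shell(sub, preclinical_optimum.shell1, dirs60)
    s2 = substrate_shell(sub, preclinical_optimum.shell2, dirs60)
    return s1, s2


class TestEnsembles:
    def test_rician_noise_depresses_tdr(self, bundle_shells):
        s1, s2 = bundle_shells
        clean = tdr_subset_curve(s1.signals, s2.signals)
        mean_c, _ = ensemble_curves(s1, s2, NoiseSpec(20.0, 4000, 42))
        assert mean_c[59] < clean[59]
        assert mean_c[11] < clean[11]

    def test_bias_worsens_with_subset_size(self, bundle_shells):
        """The Rician floor penalises including the low-signal directions."""
        s1, s2 = bundle_shells
        clean = tdr_subset_curve(s1.signals, s2.signals)
        mean_c, _ = ensemble_curves(s1, s2, NoiseSpec(20.0, 4000, 42))
        bias = 1.0 - mean_c / clean
        assert bias[59] > bias[11] > 0

    def test_precision_improves_with_measurements(self, bundle_shells):
        s1, s2 = bundle_shells
        _, std_c = ensemble_curves(s1, s2, NoiseSpec(20.0, 4000, 42))
        assert std_c[11] < std_c[2] < std_c[0]

    def test_gaussian_noise_unbiased(self, bundle_shells):
        """Real-valued (Gaussian) noise leaves the full-set TDR unbiased."""
        s1, s2 = bundle_shells
        clean = tdr_subset_curve(s1.signals, s2.signals)
        mean_c, std_c = ensemble_curves(
            s1, s2, NoiseSpec(50.0, 8000, 42), gaussian=True
        )
        se = std_c[59] / math.sqrt(8000)
        assert abs(mean_c[59] - clean[59]) < 5 * se + 0.002

    def test_result_container(self, preclinical_optimum, dirs60):
        sub = preset_substrates()["large_cylinders"]
        res = tdr_noise_ensemble(
            sub,
            (preclinical_optimum.shell1, preclinical_optimum.shell2),
            12,
            NoiseSpec(20.0, 2000, 1),
            dirs=dirs60,
        )
        assert res.subset_size == 12 and res.n_directions == 60
        assert res.ensemble_std > 0
        assert res.ensemble_mean < res.tdr  # noise floor depresses the mean


class TestCovAcrossConfigs:
    def test_identical_configs_agree(self, preclinical_optimum, dirs60):
        sub = preset_substrates()["large_cylinders"]
        cov, _ = cov_across_configs(
            [sub, sub],
            (preclinical_optimum.shell1, preclinical_optimum.shell2),
            NoiseSpec(20.0, 3000, 10),
            dirs60,
            pooled=False,
        )
        # identical substrates: ensemble means differ only by Monte-Carlo error
        assert np.all(cov < 0.01)

    def test_noise_free_configs_have_negligible_cov(self, preclinical_optimum, dirs60):
        dist = preset_substrates()["large_cylinders"].distribution
        configs = [
            Substrate(
                geometry="cylinder",
                distribution=dist,
                bundle_axes=fibre_configuration(n),
            )
            for n in (1, 2, 3)
        ]
        cov, _ = cov_across_configs(
            configs,
            (preclinical_optimum.shell1, preclinical_optimum.shell2),
            NoiseSpec(math.inf, 1, 0),
            dirs60,
            pooled=False,
        )
        assert np.all(cov < 0.01)

    def test_requires_two_configs(self, preclinical_optimum, dirs60):
        with pytest.raises(ValueError):
            cov_across_configs(
                [preset_substrates()["large_cylinders"]],
                (preclinical_optimum.shell1, preclinical_optimum.shell2),
                NoiseSpec(20.0, 100, 0),
                dirs60,
            )
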