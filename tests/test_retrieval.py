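import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import circular_diff, lsq_stepping_oracle
from lungdfi.forward import SystemConfig, simulate_scan, stepping_curve
from lungdfi.retrieval import fit_stepping, retrieve, wrap_phase


class TestFitStepping:
    def test_inverts_known_curve(self):
        a0, a1, phi = fit_stepping(np.array([130.0, 100.0, 70.0, 100.0]))
        np.testing.assert_allclose((a0, a1), (100.0, 30.0), atol=1e-12)
        assert circular_diff(phi, 0.0) < 1e-12

    def test_flat_curve_phi_convention(self):
        a0, a1, phi = fit_stepping(np.array([100.0] * 4))
        assert (a0, a1, phi) == (100.0, 0.0, 0.0)

    def test_noisy_curve_matches_lsq_oracle(self, rng):
        """Even off-model (perturbed) samples: DFT == least squares on a
        uniform grid, checked against an independent grid-search fit."""
        curve = stepping_curve(200.0, 0.25, 1.1, 8)
        curve = curve + rng.normal(0, 3.0, size=8)
        got = fit_stepping(curve)
        want = lsq_stepping_oracle(curve)
        np.testing.assert_allclose(got[:2], want[:2], atol=1e-6)
        assert circular_diff(got[2], want[2]) < 1e-6

    def test_oracle_agreement_on_random_noiseless_curves(self, rng):
        """1000 random noiseless curves: estimator == grid-search LSQ to 1e-9."""
        for _ in range(1000):
            M = int(rng.integers(3, 9))
            a0 = rng.uniform(10, 1e4)
            V = rng.uniform(0, 1)
            phi = rng.uniform(-np.pi, np.pi)
            curve = stepping_curve(a0, V, phi, M)
            got = fit_stepping(curve)
            want = lsq_stepping_oracle(curve)
            np.testing.assert_allclose(got[0], want[0], rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(got[1], want[1], rtol=1e-7, atol=1e-7 * a0)
            if got[1] > 1e-6 * a0:
                assert circular_diff(got[2], want[2]) < 1e-7


class TestWrapPhase:
    @pytest.mark.parametrize("delta, expected", [
        (3 * np.pi / 2, -np.pi / 2),
        (np.pi, np.pi),
        (-np.pi, np.pi),
        (0.3, 0.3),
    ])
    def test_wrapping_rule(self, delta, expected):
        assert wrap_phase(delta) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(x=st.floats(-50, 50))
    def test_periodicity_and_range(self, x):
        w = wrap_phase(x)
        assert -np.pi < w <= np.pi
        assert circular_diff(w, x) < 1e-9


class _Maps:
    def __init__(self, T, eps, phi):
        self.transmission_map = T
        self.extinction_map = eps
        self.phase_map = phi
        self.shape = T.shape


def _roundtrip(T, eps, phi, config=None):
    cfg = config or SystemConfig(noise="none")
    phantom = _Maps(T, eps, phi)
    ref = simulate_scan(None, cfg, shape=T.shape)
    sam = simulate_scan(phantom, cfg)
    return retrieve(sam, ref)


class TestRetrieve:
    def test_identity_when_sample_equals_reference(self):
        cfg = SystemConfig(noise="none")
        ref = simulate_scan(None, cfg, shape=(5, 5))
        out = retrieve(ref, ref)
        np.testing.assert_allclose(out.absorption, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.darkfield, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.phase, 0.0, atol=1e-12)

    def test_uniform_phantom_inverts_exactly(self):
        shape = (4, 4)
        out = _roundtrip(np.full(shape, 0.5), np.full(shape, 0.2), np.full(shape, 0.3))
        np.testing.assert_allclose(out.absorption, np.log(2), atol=1e-12)
        np.testing.assert_allclose(out.darkfield, 0.2, atol=1e-12)
        np.testing.assert_allclose(out.phase, 0.3, atol=1e-12)

    def test_air_phantom_yields_zero_modalities(self):
        shape = (6, 6)
        out = _roundtrip(np.ones(shape), np.zeros(shape), np.zeros(shape))
        for img in (out.absorption, out.darkfield, out.phase):
            np.testing.assert_allclose(img, 0.0, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), mode=st.sampled_from(["flat", "linear_carrier"]))
    def test_exact_inversion_of_random_phantoms(self, seed, mode):
        """Noiseless forward + retrieval recovers arbitrary maps to 1e-9
        (phase compared modulo 2*pi), in both reference-phase modes."""
        rng = np.random.default_rng(seed)
        shape = (12, 12)
        T = rng.uniform(0.05, 1.0, shape)
        eps = rng.uniform(0.0, 3.0, shape)
        phi = rng.uniform(-np.pi, np.pi, shape)
        cfg = SystemConfig(noise="none", reference_phase_mode=mode)
        out = _roundtrip(T, eps, phi, cfg)
        assert np.abs(out.absorption - (-np.log(T))).max() < 1e-9
        assert np.abs(out.darkfield - eps).max() < 1e-9
        assert circular_diff(out.phase, phi).max() < 1e-9

    def test_phase_difference_is_wrapped(self):
        shape = (3, 3)
        out = _roundtrip(np.full(shape, 0.8), np.zeros(shape), np.full(shape, 3 * np.pi / 2))
        np.testing.assert_allclose(out.phase, -np.pi / 2, atol=1e-9)

    def test_mismatched_stacks_rejected(self):
        cfg = SystemConfig(noise="none")
        ref = simulate_scan(None, cfg, shape=(4, 4))
        other = simulate_scan(None, SystemConfig(noise="none", n_steps=5), shape=(4, 4))
        with pytest.raises(ValueError):
            retrieve(other, ref)

    def test_ill_posed_pixels_masked_not_raised(self):
        cfg = SystemConfig(noise="none")
        ref = simulate_scan(None, cfg, shape=(4, 4))
        sam = simulate_scan(None, cfg, shape=(4, 4))
        sam.frames[:, 0, 0] = 0.0  # dead pixel: a0 == 0
        out = retrieve(sam, ref)
        assert not out.quality_mask[0, 0]
        assert np.isnan(out.absorption[0, 0])
        assert out.quality_mask[1:, :].all()
        assert np.isfinite(out.absorption[out.quality_mask]).all()

    def test_noise_robust_absorption_mean(self):
        """Poisson noise at N0=1e4: spatial-mean absorption of a uniform
        T=0.5 region on 128x128 stays within 0.01 of ln 2."""
        shape = (128, 128)
        cfg = SystemConfig(noise="poisson", photons_per_pixel=1e4)
        rng = np.random.default_rng(11)
        phantom = _Maps(np.full(shape, 0.5), np.zeros(shape), np.zeros(shape))
        ref = simulate_scan(None, cfg, shape=shape, rng=rng)
        sam = simulate_scan(phantom, cfg, rng=rng)
        out = retrieve(sam, ref)
        assert abs(np.nanmean(out.absorption) - np.log(2)) < 0.01
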