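import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mrphasor import (SampledAxis, SignalStack, compute_phasor,
                      compute_phasor_field, from_printed_steps, subsample_axis)
from mrphasor.phasor_core import PhasorError, mean_filter, preprocess_stack

from conftest import monoexp, naive_phasor

# frozen from an arbitrary-precision summation of exp(-k*7.23/105), k=0..63,
# kernel exp(+2*pi*i*k/64)
TAU105_RE = 0.352280806578412766
TAU105_IM = 0.453748608976995227


class TestSampledAxis:
    def test_strictly_increasing_required(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SampledAxis([1.0, 1.0, 2.0])

    def test_minimum_length(self):
        with pytest.raises(ValueError, match="at least 3"):
            SampledAxis([1.0, 2.0])

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            SampledAxis([1.0, 2.0, 3.0], kind="wavelength")

    def test_relative_starts_at_zero(self, echo64):
        assert echo64.relative[0] == 0.0
        assert echo64.relative[-1] == pytest.approx(63 * 7.23)

    def test_kind_sets_unit_label_only(self):
        a = SampledAxis([0.0, 1.0, 2.0], kind="echo_time")
        b = SampledAxis([0.0, 1.0, 2.0], kind="b_value")
        assert a.unit != b.unit
        assert np.array_equal(a.values, b.values)


class TestComputePhasor:
    def test_delta_first_sample(self):
        # fast-decay limit: all signal in the first sample
        sig = np.zeros(64)
        sig[0] = 7.5
        p = compute_phasor(sig)
        assert p.re == pytest.approx(1.0, abs=1e-15)
        assert p.im == pytest.approx(0.0, abs=1e-15)

    def test_constant_signal_maps_to_origin(self):
        p = compute_phasor(np.full(64, 3.3))
        assert abs(p.re) < 1e-14
        assert abs(p.im) < 1e-14

    def test_monoexp_frozen_value(self, echo64):
        p = compute_phasor(monoexp(echo64, 105.0))
        assert p.re == pytest.approx(TAU105_RE, abs=1e-14)
        assert p.im == pytest.approx(TAU105_IM, abs=1e-14)

    def test_zero_signal_rejected(self):
        with pytest.raises(PhasorError):
            compute_phasor(np.zeros(8))

    def test_nonfinite_rejected(self):
        sig = np.ones(8)
        sig[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_phasor(sig)

    def test_harmonic_range(self):
        with pytest.raises(ValueError, match="harmonic"):
            compute_phasor(np.ones(8), harmonic=4)

    def test_oracle_equivalence_1000_random_signals(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(3, 80)
            sig = rng.uniform(0.0, 10.0, n)
            if sig.sum() <= 0:
                continue
            p = compute_phasor(sig)
            re, im = naive_phasor(sig)
            assert p.re == pytest.approx(re, abs=1e-12)
            assert p.im == pytest.approx(im, abs=1e-12)

    @given(
        sig=hnp.arrays(float, st.integers(4, 64),
                       elements=st.floats(0.0, 1e6)),
        c=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_invariance(self, sig, c):
        if sig.sum() <= 0 or (c * sig).sum() <= 0:
            return
        p1 = compute_phasor(sig)
        p2 = compute_phasor(c * sig)
        assert p1.re == pytest.approx(p2.re, abs=1e-12)
        assert p1.im == pytest.approx(p2.im, abs=1e-12)

    @given(sig=hnp.arrays(float, st.integers(4, 64),
                          elements=st.floats(0.0, 1e3)))
    @settings(max_examples=200, deadline=None)
    def test_modulus_bound(self, sig):
        if sig.sum() <= 0:
            return
        assert compute_phasor(sig).modulus <= 1.0 + 1e-12

    def test_mixing_linearity_random_mixtures(self, echo64):
        # phasor of a positive mixture == integral-weighted sum of phasors
        rng = np.random.default_rng(0)
        x = echo64.relative
        for _ in range(1000):
            taus = rng.uniform(5.0, 600.0, 3)
            amps = rng.uniform(0.1, 2.0, 3)
            comps = [a * np.exp(-x / t) for a, t in zip(amps, taus)]
            mix = np.sum(comps, axis=0)
            p = compute_phasor(mix)
            weights = np.array([c.sum() for c in comps]) / mix.sum()
            expect = sum(w * complex(*compute_phasor(c))
                         for w, c in zip(weights, comps))
            assert p.re == pytest.approx(expect.real, abs=1e-12)
            assert p.im == pytest.approx(expect.imag, abs=1e-12)


class TestPhasorField:
    def _uniform_stack(self, axis, tau=105.0, shape=(16, 16)):
        profile = monoexp(axis, tau)
        data = np.broadcast_to(profile, shape + (axis.n,)).copy()
        return SignalStack(data, axis)

    def test_homogeneous_phantom_matches_single_phasor(self, echo64):
        stack = self._uniform_stack(echo64)
        field = compute_phasor_field(stack)
        ref = compute_phasor(monoexp(echo64, 105.0))
        assert field.valid.all()
        np.testing.assert_allclose(field.re, ref.re, atol=1e-12)
        np.testing.assert_allclose(field.im, ref.im, atol=1e-12)

    def test_mean_filter_identity_on_constant_field(self, echo64):
        stack = self._uniform_stack(echo64)
        f0 = compute_phasor_field(stack, mean_filter_radius=0)
        f1 = compute_phasor_field(stack, mean_filter_radius=1)
        np.testing.assert_allclose(f1.re, f0.re, atol=1e-12)
        np.testing.assert_allclose(f1.im, f0.im, atol=1e-12)

    def test_two_tissue_mixture_is_weighted_mean(self, echo64):
        # every pixel 50/50 mixture: phasor == intensity-weighted mean of pures
        x = echo64.relative
        s1, s2 = np.exp(-x / 40.0), np.exp(-x / 300.0)
        data = np.broadcast_to(0.5 * s1 + 0.5 * s2, (8, 8, 64)).copy()
        field = compute_phasor_field(SignalStack(data, echo64))
        w1 = 0.5 * s1.sum() / (0.5 * s1.sum() + 0.5 * s2.sum())
        expect = w1 * complex(*compute_phasor(s1)) + (1 - w1) * complex(*compute_phasor(s2))
        np.testing.assert_allclose(field.re[field.valid], expect.real, atol=1e-12)
        np.testing.assert_allclose(field.im[field.valid], expect.imag, atol=1e-12)

    def test_threshold_invalidates_dim_pixels(self, echo64):
        stack = self._uniform_stack(echo64)
        stack.data[0, 0] *= 1e-4
        field = compute_phasor_field(stack, intensity_threshold=0.05)
        assert not field.valid[0, 0]
        assert np.isnan(field.re[0, 0])
        assert field.valid[5, 5]

    def test_empty_valid_set_warns(self, echo64):
        stack = self._uniform_stack(echo64)
        with pytest.warns(UserWarning, match="threshold"):
            compute_phasor_field(stack, intensity_threshold=1e9,
                                 threshold_absolute=True)

    def test_mean_filter_shrinks_at_borders(self):
        img = np.ones((5, 5))
        out = mean_filter(img, 1)
        np.testing.assert_allclose(out, 1.0)  # constant preserved everywhere

    def test_noise_floor_correction_removes_baseline(self, echo64):
        profile = monoexp(echo64, 105.0)
        sigma = 0.05
        floored = np.sqrt(profile ** 2 + 0.5 * np.pi * sigma ** 2)
        data = np.broadcast_to(floored, (6, 6, 64)).copy()
        stack = SignalStack(data, echo64)
        corrected = preprocess_stack(stack, noise_floor_sigma=sigma)
        np.testing.assert_allclose(corrected.data[3, 3], profile, atol=1e-12)


class TestSubsampleAxis:
    def _stack(self, echo64):
        data = np.random.default_rng(1).uniform(0.1, 1.0, (4, 4, 64))
        return SignalStack(data, echo64)

    def test_16_echo_subset(self, echo64):
        # printed steps 2, 6, 10, ..., 62 (1-based)
        idx = from_printed_steps(range(2, 63, 4))
        sub = subsample_axis(self._stack(echo64), idx)
        assert sub.axis.n == 16
        assert sub.data.shape[-1] == 16
        assert sub.axis.values[0] == pytest.approx(2 * 7.23)

    def test_4_echo_subset(self, echo64):
        idx = from_printed_steps([4, 20, 36, 52])
        sub = subsample_axis(self._stack(echo64), idx)
        assert sub.axis.n == 4
        np.testing.assert_allclose(sub.axis.values, np.array([4, 20, 36, 52]) * 7.23)

    def test_identity_subset(self, echo64):
        stack = self._stack(echo64)
        sub = subsample_axis(stack, list(range(64)))
        np.testing.assert_array_equal(sub.data, stack.data)
        np.testing.assert_array_equal(sub.axis.values, echo64.values)

    def test_too_few_indices(self, echo64):
        with pytest.raises(ValueError, match="at least 3"):
            subsample_axis(self._stack(echo64), [0, 5])

    def test_non_increasing_indices(self, echo64):
        with pytest.raises(ValueError, match="strictly increasing"):
            subsample_axis(self._stack(echo64), [0, 5, 5, 7])

    def test_out_of_range(self, echo64):
        with pytest.raises(IndexError):
            subsample_axis(self._stack(echo64), [0, 5, 64])

    def test_printed_steps_are_one_based(self):
        assert from_printed_steps([1, 2, 10]) == [0, 1, 9]
        with pytest.raises(ValueError):
            from_printed_steps([0, 1, 2])
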