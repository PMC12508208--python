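"""EMD/EEMD: extrema detection, envelopes, sifting, completeness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tremorsep.emd import (DecompositionError, EEMDConfig, EMDConfig,
                           InsufficientExtremaError, count_zero_crossings,
                           eemd, emd, envelope_mean, find_extrema,
                           sift_one_imf, stoppage_criterion)


class TestFindExtrema:
    def test_monotone_and_constant_have_none(self):
        for x in (np.arange(10.0), np.full(10, 3.0)):
            maxima, minima = find_extrema(x)
            assert maxima.size == 0 and minima.size == 0

    def test_sine_extrema_positions(self, tone_factory):
        x = tone_factory(1.0, duration_s=2.0)  # sin(2*pi*t), 200 samples
        maxima, minima = find_extrema(x)
        assert np.abs(np.asarray(maxima) - np.array([25, 125])).max() <= 1
        assert np.abs(np.asarray(minima) - np.array([75, 175])).max() <= 1

    def test_plateau_contributes_midpoint_once(self):
        x = np.array([0, 1, 2, 2, 2, 1, 0, -1, -1, 0], dtype=float)
        maxima, minima = find_extrema(x)
        assert list(maxima) == [3]
        assert list(minima) == [7]


class TestEnvelopeMean:
    def test_odd_symmetry(self, tone_factory):
        x = tone_factory(2.0) + 0.3 * tone_factory(9.0)
        mx, mn = find_extrema(x)
        m_pos = envelope_mean(x, mx, mn)
        mx2, mn2 = find_extrema(-x)
        m_neg = envelope_mean(-x, mx2, mn2)
        np.testing.assert_allclose(m_neg, -m_pos, atol=1e-9)

    def test_pure_tone_mean_is_small(self, tone_factory):
        x = tone_factory(1.0, duration_s=10.0)  # 10 periods
        mx, mn = find_extrema(x)
        m = envelope_mean(x, mx, mn)
        interior = slice(50, -50)
        assert np.max(np.abs(m[interior])) <= 0.05

    def test_translation_equivariance(self, tone_factory):
        x = tone_factory(3.0)
        mx, mn = find_extrema(x)
        m0 = envelope_mean(x, mx, mn)
        m5 = envelope_mean(x + 5.0, mx, mn)
        np.testing.assert_allclose(m5, m0 + 5.0, atol=1e-9)

    def test_too_few_extrema_raises(self):
        with pytest.raises(InsufficientExtremaError):
            envelope_mean(np.arange(10.0), np.array([2]), np.array([5]))


class TestStoppageCriterion:
    @pytest.mark.parametrize("h_prev,h_curr,expected", [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
        ([1.0, 2.0], [0.0, 0.0], 1.0),
        ([1.0, 1.0], [1.0, 0.0], 0.5),
    ])
    def test_direct_values(self, h_prev, h_curr, expected):
        assert stoppage_criterion(np.array(h_prev),
                                  np.array(h_curr)) == pytest.approx(expected)

    def test_zero_energy_rejected(self):
        with pytest.raises(DecompositionError):
            stoppage_criterion(np.zeros(5), np.ones(5))


class TestSiftOneIMF:
    def test_pure_tone_is_returned_nearly_unchanged(self, tone_factory):
        x = tone_factory(5.0)
        imf, _ = sift_one_imf(x)
        assert np.corrcoef(imf, x)[0, 1] > 0.99

    def test_termination_contract(self, tone_factory):
        # when sifting terminates before the cap, D < threshold holds
        x = tone_factory(5.0) + 0.2 * tone_factory(1.0)
        cfg = EMDConfig()
        h = x.copy()
        d_last = None
        for _ in range(cfg.max_siftings):
            mx, mn = find_extrema(h)
            if mx.size < 2 or mn.size < 2:
                break
            m = envelope_mean(h, mx, mn)
            h_new = h - m
            d_last = stoppage_criterion(h, h_new)
            h = h_new
            if d_last < cfg.stoppage_threshold:
                break
        imf, n_sifts = sift_one_imf(x, cfg)
        assert n_sifts < cfg.max_siftings
        assert d_last is not None and d_last < cfg.stoppage_threshold
        np.testing.assert_allclose(imf, h, atol=1e-12)

    def test_resifting_an_imf_converges_immediately(self, tone_factory):
        x = tone_factory(5.0) + 0.3 * tone_factory(1.5)
        imf, _ = sift_one_imf(x)
        _, n_again = sift_one_imf(imf)
        assert n_again <= 2

    def test_monotone_input_rejected(self):
        with pytest.raises(InsufficientExtremaError):
            sift_one_imf(np.arange(20.0))


class TestEMD:
    def test_monotone_ramp_yields_no_imfs(self):
        x = np.linspace(0, 1, 100)
        dec = emd(x)
        assert dec.n_imfs == 0
        np.testing.assert_array_equal(dec.residual, x)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_completeness_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(500) / 100
        x = (rng.standard_normal(500).cumsum() / 10
             + np.sin(2 * np.pi * rng.uniform(1, 10) * t))
        dec = emd(x)
        assert np.max(np.abs(dec.reconstruct() - x)) < 1e-8

    def test_two_tone_separation(self, tone_factory):
        hi, lo = tone_factory(6.0), tone_factory(1.0)
        dec = emd(hi + lo)
        assert dec.n_imfs >= 2
        assert np.corrcoef(dec.imfs[0], hi)[0, 1] > 0.9
        later = max(np.corrcoef(dec.imfs[k], lo)[0, 1]
                    for k in range(1, dec.n_imfs))
        assert later > 0.9

    def test_amplitude_equivariance(self, tone_factory):
        x = tone_factory(5.0) + tone_factory(1.0)
        a, b = emd(x), emd(3.0 * x)
        assert a.n_imfs == b.n_imfs
        np.testing.assert_allclose(b.imfs, 3.0 * a.imfs, atol=1e-9)
        np.testing.assert_allclose(b.residual, 3.0 * a.residual, atol=1e-9)

    def test_imfs_satisfy_zero_crossing_criterion(self):
        rng = np.random.default_rng(4)
        t = np.arange(1000) / 100
        x = (np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 1.3 * t)
             + 0.05 * rng.standard_normal(1000))
        dec = emd(x)
        assert dec.n_imfs >= 2
        for k in range(dec.n_imfs):
            imf = dec.imfs[k]
            mx, mn = find_extrema(imf)
            n_ext = mx.size + mn.size
            n_zc = count_zero_crossings(imf)
            assert abs(n_ext - n_zc) <= 1, f"IMF{k + 1}: {n_ext} vs {n_zc}"

    def test_short_signal_rejected(self):
        with pytest.raises(DecompositionError):
            emd(np.sin(np.arange(5.0)))

    def test_missing_values_rejected(self):
        x = np.sin(np.arange(100) / 5)
        x[10] = np.nan
        with pytest.raises(DecompositionError):
            emd(x)


class TestEEMD:
    def test_degenerate_ensemble_reproduces_emd_bitwise(self, tone_factory):
        x = tone_factory(5.0) + tone_factory(1.0)
        plain = emd(x)
        degen = eemd(x, EEMDConfig(n_ensembles=1, noise_std_ratio=0.0, seed=9))
        assert degen.n_imfs == plain.n_imfs
        np.testing.assert_array_equal(degen.imfs, plain.imfs)
        np.testing.assert_array_equal(degen.residual, plain.residual)

    def test_seed_determinism(self, tone_factory):
        x = tone_factory(5.0) + tone_factory(1.0)
        cfg = EEMDConfig(n_ensembles=10, seed=3)
        a, b = eemd(x, cfg), eemd(x, cfg)
        np.testing.assert_array_equal(a.imfs, b.imfs)

    def test_ensemble_mean_completeness_bound(self, tone_factory):
        x = tone_factory(5.0) + tone_factory(1.0)
        cfg = EEMDConfig(n_ensembles=25, noise_std_ratio=0.2, seed=1)
        dec = eemd(x, cfg)
        # residue is exactly the mean of the injected noise: its RMS
        # concentrates at noise_std/sqrt(N); the max over ~1000 samples sits
        # near 3.5 sigma, so the pointwise bound uses 5 sigma
        scale = cfg.noise_std_ratio * np.std(x) / np.sqrt(cfg.n_ensembles)
        err = dec.reconstruct() - x
        assert np.sqrt(np.mean(err ** 2)) <= 1.5 * scale
        assert np.max(np.abs(err)) <= 5 * scale
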