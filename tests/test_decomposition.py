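"""EMD core, envelopes, sifting and the ensemble variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aircast.decomposition import (
    DecompositionConfig,
    IMFSet,
    ceemdan,
    compute_envelopes,
    decompose,
    eemd,
    emd,
    find_extrema,
    imf_criterion_gap,
    sift,
    zero_crossings,
)


def _corr(a, b):
    return float(np.corrcoef(a, b)[0, 1])


class TestFindExtrema:
    def test_simple_alternation(self):
        mx, mn = find_extrema(np.array([0.0, 1.0, 0.0, -1.0, 0.0]))
        assert list(mx) == [1] and list(mn) == [3]

    def test_sine_counts_match_brute_force(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * 5 * t / 1000.0)
        mx, mn = find_extrema(x)
        # brute-force interior scan
        bf_max = [i for i in range(1, 999) if x[i - 1] < x[i] > x[i + 1]]
        bf_min = [i for i in range(1, 999) if x[i - 1] > x[i] < x[i + 1]]
        assert list(mx) == bf_max and list(mn) == bf_min
        assert len(mx) == 5 and len(mn) == 5

    def test_monotone_ramp_has_none(self):
        mx, mn = find_extrema(np.linspace(0, 1, 50))
        assert len(mx) == 0 and len(mn) == 0

    def test_constant_signal_has_none(self):
        mx, mn = find_extrema(np.full(20, 3.0))
        assert len(mx) == 0 and len(mn) == 0

    def test_plateau_yields_midpoint(self):
        x = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        mx, _ = find_extrema(x)
        assert list(mx) == [3]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_extrema(np.array([1.0, 2.0]))


class TestEnvelopes:
    def test_sinusoid_mean_near_zero_on_interior(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * 10 * t / 1000.0)
        mx, mn = find_extrema(x)
        upper, lower, mean = compute_envelopes(x, mx, mn)
        interior = slice(100, 900)
        assert np.max(np.abs(mean[interior])) < 0.05

    def test_translation_equivariance(self):
        t = np.arange(500)
        x = np.sin(2 * np.pi * 7 * t / 500.0)
        mx, mn = find_extrema(x)
        _, _, mean = compute_envelopes(x, mx, mn)
        _, _, mean_shifted = compute_envelopes(x + 3.5, mx, mn)
        assert np.allclose(mean_shifted, mean + 3.5, atol=1e-10)

    def test_envelopes_interpolate_their_extrema(self):
        # the splines pass exactly through their own knots, so the signal
        # touches the upper envelope at maxima and the lower at minima
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(size=300))
        mx, mn = find_extrema(x)
        upper, lower, mean = compute_envelopes(x, mx, mn)
        assert np.allclose(upper[mx], x[mx], atol=1e-9)
        assert np.allclose(lower[mn], x[mn], atol=1e-9)
        # and the mean is exactly the envelope average
        assert np.allclose(mean, 0.5 * (upper + lower), atol=1e-12)

    def test_too_few_extrema_signals_residue(self):
        x = np.linspace(0, 1, 50)
        mx, mn = find_extrema(x)
        assert compute_envelopes(x, mx, mn) is None


class TestSift:
    def test_pure_tone_is_fixed_point(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * 0.02 * t)
        h = sift(x)
        assert np.linalg.norm(h - x) / np.linalg.norm(x) < 1e-3

    def test_two_tone_yields_fast_component(self, two_tone):
        h = sift(two_tone.signal)
        fast = two_tone.components[1]
        assert _corr(h, fast) > 0.95

    def test_candidate_satisfies_imf_criterion(self, two_tone):
        assert imf_criterion_gap(sift(two_tone.signal)) <= 1


class TestEMD:
    def test_constant_input_gives_empty_imfs(self):
        x = np.full(50, 2.5)
        d = emd(x)
        assert len(d) == 0
        assert np.array_equal(d.residue, x)

    def test_two_tone_components_recovered(self, two_tone):
        d = emd(two_tone.signal)
        assert len(d) >= 2
        slow, fast = two_tone.components
        assert _corr(d.imfs[0], fast) > 0.95
        assert _corr(d.imfs[1], slow) > 0.95

    def test_reconstruction_identity(self, two_tone):
        d = emd(two_tone.signal)
        rel = np.max(np.abs(d.reconstruct() - two_tone.signal)) / np.max(
            np.abs(two_tone.signal)
        )
        assert rel < 1e-8

    def test_zero_crossing_count_non_increasing(self, two_tone):
        d = emd(two_tone.signal)
        counts = [zero_crossings(c) for c in d.imfs]
        assert counts == sorted(counts, reverse=True)

    def test_max_imfs_respected(self, two_tone):
        d = emd(two_tone.signal, DecompositionConfig(max_imfs=1))
        assert len(d) == 1

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reconstruction_property_random_walks(self, seed):
        x = np.cumsum(np.random.default_rng(seed).normal(size=200))
        d = emd(x)
        assert np.max(np.abs(d.reconstruct() - x)) <= 1e-8 * max(1.0, np.max(np.abs(x)))


class TestCEEMDAN:
    def test_exact_reconstruction_any_seed(self, rng):
        x = np.cumsum(rng.normal(size=300))
        for seed in (0, 5):
            d = ceemdan(x, DecompositionConfig(ensemble_size=8, seed=seed))
            assert np.max(np.abs(d.reconstruct() - x)) < 1e-10 * np.max(np.abs(x))

    def test_deterministic_under_seed(self, rng):
        x = np.cumsum(rng.normal(size=256))
        cfg = DecompositionConfig(ensemble_size=8, seed=3)
        a, b = ceemdan(x, cfg), ceemdan(x, cfg)
        assert len(a) == len(b)
        for ca, cb in zip(a.imfs, b.imfs):
            assert np.array_equal(ca, cb)

    def test_small_noise_approaches_plain_emd(self, two_tone):
        x = two_tone.signal
        ref = emd(x)
        dists = []
        for eps in (0.2, 0.02):
            d = ceemdan(x, DecompositionConfig(ensemble_size=4, noise_scale=eps, seed=1))
            k = min(len(d), len(ref))
            dists.append(
                sum(np.linalg.norm(d.imfs[i] - ref.imfs[i]) for i in range(k))
                / np.linalg.norm(x)
            )
        assert dists[1] < dists[0]

    def test_odd_ensemble_with_paired_noise_rejected(self):
        with pytest.raises(ValueError, match="even"):
            DecompositionConfig(ensemble_size=5, paired_noise=True)

    def test_imfs_satisfy_imf_criterion(self, rng):
        x = np.cumsum(rng.normal(size=300))
        d = ceemdan(x, DecompositionConfig(ensemble_size=8, seed=2))
        assert all(imf_criterion_gap(c) <= 1 for c in d.imfs)


class TestEEMD:
    def test_deterministic_under_seed(self, rng):
        x = np.cumsum(rng.normal(size=256))
        cfg = DecompositionConfig(ensemble_size=8, seed=4)
        a, b = eemd(x, cfg), eemd(x, cfg)
        for ca, cb in zip(a.imfs, b.imfs):
            assert np.array_equal(ca, cb)

    def test_reconstruction_within_reported_tolerance(self, rng):
        x = np.cumsum(rng.normal(size=256))
        d = eemd(x, DecompositionConfig(ensemble_size=8, seed=4))
        # paired noise cancels in the ensemble mean, so reconstruction is
        # tight even though eemd gives no exactness guarantee
        rel = np.max(np.abs(d.reconstruct() - x)) / np.max(np.abs(x))
        assert rel < 1e-6


def test_decompose_dispatch_unknown_method():
    with pytest.raises(ValueError, match="unknown decomposition"):
        decompose(np.arange(20.0), "vmd")


def test_imfset_validates_lengths():
    with pytest.raises(ValueError):
        IMFSet([np.zeros(5)], np.zeros(4), 5)
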