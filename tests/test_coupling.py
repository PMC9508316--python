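"""2-D cross-correlation algebra, trimming, panels and null ensembles."""

import numpy as np
import pytest
import scipy.signal

from steercouple.containers import InvalidParameterError
from steercouple.coupling import (
    Mask,
    halfsplit_null,
    shuffle_null,
    trial_coupling,
    trim_nonsignificant_rows,
    xcorr2,
)


def xcorr2_oracle(mask, panel):
    """Nested-loop implementation of the published definition."""
    M, N = mask.shape
    P, Q = panel.shape
    out = np.zeros((P + M - 1, Q + N - 1), dtype=np.result_type(mask, panel))
    for i in range(P + M - 1):
        for j in range(Q + N - 1):
            acc = 0
            for u in range(M):
                for v in range(N):
                    pi, pj = u + i - (M - 1), v + j - (N - 1)
                    if 0 <= pi < P and 0 <= pj < Q:
                        acc += mask[u, v] * panel[pi, pj]
            out[i, j] = acc
    return out


class TestXCorr2:
    def test_published_dimension_algebra(self, rng):
        out = xcorr2(rng.random((13, 50)), rng.random((198, 300)))
        assert out.values.shape == (210, 349)
        trimmed = trim_nonsignificant_rows(out, 12)
        assert trimmed.values.shape == (198, 349)
        assert trimmed.row_lags[0] == 0

    def test_identity_kernel_returns_panel(self, rng):
        panel = rng.random((6, 7))
        out = xcorr2(np.ones((1, 1)), panel)
        np.testing.assert_allclose(out.values, panel)

    def test_hand_worked_two_by_two_ones(self):
        out = xcorr2(np.ones((2, 2), dtype=int), np.ones((3, 3), dtype=int))
        expected = np.array(
            [[1, 2, 2, 1], [2, 4, 4, 2], [2, 4, 4, 2], [1, 2, 2, 1]]
        )
        np.testing.assert_array_equal(out.values, expected)

    @pytest.mark.parametrize("shape_m,shape_p", [((2, 3), (5, 4)), ((7, 7), (20, 20)), ((13, 5), (8, 20))])
    def test_integer_instances_exact_against_oracle(self, rng, shape_m, shape_p):
        mask = rng.integers(-9, 10, shape_m)
        panel = rng.integers(-9, 10, shape_p)
        np.testing.assert_array_equal(xcorr2(mask, panel).values, xcorr2_oracle(mask, panel))

    def test_float_instances_match_oracle_to_1e10(self, rng):
        mask = rng.standard_normal((6, 9))
        panel = rng.standard_normal((15, 18))
        out = xcorr2(mask, panel).values
        ref = xcorr2_oracle(mask, panel)
        assert np.abs(out - ref).max() <= 1e-10 * np.abs(ref).max()

    def test_linearity_in_mask(self, rng):
        mask = rng.standard_normal((4, 5))
        panel = rng.standard_normal((9, 11))
        np.testing.assert_allclose(
            xcorr2(3.5 * mask, panel).values, 3.5 * xcorr2(mask, panel).values, rtol=1e-12
        )

    def test_flip_convolution_identity(self, rng):
        """xcorr2(mask, panel) equals full convolution with the flipped
        mask (independent scipy.signal.convolve2d route)."""
        mask = rng.standard_normal((5, 8))
        panel = rng.standard_normal((12, 10))
        conv = scipy.signal.convolve2d(panel, mask[::-1, ::-1], mode="full")
        np.testing.assert_allclose(xcorr2(mask, panel).values, conv, atol=1e-12)

    def test_normalized_variant_affine_invariant(self, rng):
        """The normalized variant is unchanged when either input is
        rescaled and shifted; the default output scales linearly."""
        mask = rng.standard_normal((4, 6))
        panel = rng.standard_normal((9, 12))
        base = xcorr2(mask, panel, normalized=True).values
        scaled = xcorr2(3.0 * mask + 5.0, 0.5 * panel - 2.0, normalized=True).values
        np.testing.assert_allclose(scaled, base, atol=1e-12)
        assert not np.allclose(
            xcorr2(3.0 * mask, panel).values, xcorr2(mask, panel).values
        )

    def test_empty_inputs_raise(self):
        with pytest.raises(InvalidParameterError):
            xcorr2(np.empty((0, 3)), np.ones((4, 4)))

    @pytest.mark.parametrize("n_rows", [-1, 5, 99])
    def test_trim_bounds_checked(self, rng, n_rows):
        out = xcorr2(rng.random((2, 2)), rng.random((4, 4)))  # 5 x 5
        with pytest.raises(InvalidParameterError):
            trim_nonsignificant_rows(out, n_rows)

    def test_trim_zero_rows_is_identity(self, rng):
        out = xcorr2(rng.random((2, 3)), rng.random((4, 5)))
        np.testing.assert_array_equal(trim_nonsignificant_rows(out, 0).values, out.values)


def _mask(rng, shape=(3, 4)):
    return Mask(rng.standard_normal(shape), np.arange(shape[0]), np.arange(shape[1]))


class TestTrialCoupling:
    def test_single_trial_mean_is_that_trial(self, rng):
        mask = _mask(rng)
        trials = rng.standard_normal((1, 6, 8))
        got = trial_coupling(mask, trials, n_trim=2).values
        ref = xcorr2(mask, trials[0]).values[2:]
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_trial_average_equals_average_of_trials(self, rng):
        """Linearity: the matrix of the mean panel is the mean of the
        per-trial matrices."""
        mask = _mask(rng)
        trials = rng.standard_normal((5, 6, 8))
        got = trial_coupling(mask, trials, n_trim=0).values
        ref = np.mean([xcorr2(mask, tp).values for tp in trials], axis=0)
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_zero_mask_zero_panels(self, rng):
        mask = Mask(np.zeros((3, 4)), np.arange(3), np.arange(4))
        trials = rng.standard_normal((4, 6, 8))
        assert np.all(trial_coupling(mask, trials, 1).values == 0)


def _null_inputs(rng, n_subjects=2, n_trials=12):
    masks = {
        str(s): {c: _mask(rng) for c in ("left", "right")} for s in range(n_subjects)
    }
    nonsteer = {
        str(s): {"delt_l": rng.standard_normal((n_trials, 6, 8))}
        for s in range(n_subjects)
    }
    steer = {
        str(s): {
            "delt_l": {
                "left": rng.standard_normal((n_trials, 6, 8)),
                "right": rng.standard_normal((n_trials, 6, 8)),
            }
        }
        for s in range(n_subjects)
    }
    return masks, nonsteer, steer


class TestNullEnsembles:
    def test_reproducible_under_seed_and_sized(self, rng):
        masks, nonsteer, steer = _null_inputs(rng)
        a = halfsplit_null(nonsteer, masks, n_iter=5, seed=3, n_trim=1)
        b = halfsplit_null(nonsteer, masks, n_iter=5, seed=3, n_trim=1)
        np.testing.assert_array_equal(a["delt_l"], b["delt_l"])
        assert a["delt_l"].shape == (5,)
        c = shuffle_null(steer, masks, n_iter=4, seed=3, n_trim=1)
        d = shuffle_null(steer, masks, n_iter=4, seed=3, n_trim=1)
        np.testing.assert_array_equal(c["delt_l"], d["delt_l"])
        assert c["delt_l"].shape == (4,)

    def test_exchangeable_nulls_center_at_zero(self, rng):
        """With the same mask for both pseudo-conditions the split noise is
        symmetric, so the pseudo-condition difference centers at zero."""
        masks, nonsteer, steer = _null_inputs(rng, n_trials=24)
        for subj in masks.values():
            subj["right"] = subj["left"]
        half = halfsplit_null(nonsteer, masks, n_iter=80, seed=0, n_trim=1)["delt_l"]
        shuf = shuffle_null(steer, masks, n_iter=80, seed=0, n_trim=1)["delt_l"]
        assert abs(half.mean()) < 3 * half.std() / np.sqrt(half.size)
        assert abs(shuf.mean()) < 3 * shuf.std() / np.sqrt(shuf.size)

    def test_null_centers_on_data_conditional_expectation(self, rng):
        """With distinct condition masks the half-split ensemble centers on
        the linearity oracle: xcorr of each mask with the all-trial mean."""
        masks, nonsteer, _ = _null_inputs(rng, n_trials=40)
        half = halfsplit_null(nonsteer, masks, n_iter=150, seed=1, n_trim=1)["delt_l"]
        expected = np.mean(
            [
                xcorr2(masks[s]["left"], nonsteer[s]["delt_l"].mean(axis=0)).values[1:]
                for s in masks
            ],
            axis=0,
        ).mean() - np.mean(
            [
                xcorr2(masks[s]["right"], nonsteer[s]["delt_l"].mean(axis=0)).values[1:]
                for s in masks
            ],
            axis=0,
        ).mean()
        assert abs(half.mean() - expected) < 4 * half.std() / np.sqrt(half.size) + 1e-9
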