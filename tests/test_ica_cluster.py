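"""ICA recovery, brain-component screening, K-means and stability index."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from steercouple import EpochSet
from steercouple.containers import InvalidParameterError
from steercouple.ica_cluster import (
    decompose,
    kmeans_scalp_maps,
    normalize_map,
    select_brain_ics,
    stability_select_k,
)


def _three_source_epochs(rng, n=30000):
    S = rng.laplace(size=(3, n))  # super-Gaussian sources
    A = rng.normal(size=(8, 3))
    X = A @ S
    ep = EpochSet(X.reshape(8, 10, n // 10).transpose(1, 0, 2), 500.0, (0.0, n / 10 / 500.0))
    return ep, A


class TestDecompose:
    def test_recovers_known_mixing(self, rng):
        """Hungarian-matched cosines between recovered and true mixing
        columns exceed 0.95."""
        ep, A = _three_source_epochs(rng)
        d = decompose(ep, 3, seed=0)
        M = d.mixing / np.linalg.norm(d.mixing, axis=0)
        T = A / np.linalg.norm(A, axis=0)
        C = np.abs(M.T @ T)
        r, c = linear_sum_assignment(-C)
        assert np.all(C[r, c] > 0.95)

    def test_deterministic_under_seed(self, rng):
        ep, _ = _three_source_epochs(rng)
        d1 = decompose(ep, 3, seed=5)
        d2 = decompose(ep, 3, seed=5)
        np.testing.assert_array_equal(d1.mixing, d2.mixing)
        np.testing.assert_array_equal(d1.activations.values, d2.activations.values)

    def test_mixing_unmixing_identity(self, rng):
        ep, _ = _three_source_epochs(rng)
        d = decompose(ep, 3, seed=0)
        np.testing.assert_allclose(d.unmixing @ d.mixing, np.eye(3), atol=1e-8)

    def test_rank_deficient_input_reduced(self, rng, caplog):
        S = rng.laplace(size=(2, 10000))
        A = rng.normal(size=(6, 2))
        X = (A @ S).reshape(6, 10, 1000).transpose(1, 0, 2)
        ep = EpochSet(X, 500.0, (0.0, 2.0))
        with caplog.at_level("WARNING"):
            d = decompose(ep, 4, seed=0)
        assert d.n_components == 2
        assert "rank" in caplog.text


class TestSelectBrainICs:
    def test_smooth_rhythm_kept_noise_rejected(self, rng):
        """A forward-mixed bursty 10 Hz source must pass the screen; a
        spatially random white-noise component must fail it (flat
        spectrum, rough map)."""
        from steercouple.synth import SessionSpec, gen_session
        from steercouple.pipeline import detect_steering_events
        from steercouple.config import PipelineConfig
        from steercouple.behavior import epoch
        from steercouple.preprocess import common_average_reference
        from steercouple.synth import forward_maps

        sess = gen_session(SessionSpec(n_trials_left=6, n_trials_right=6, seed=11))
        ev, _ = detect_steering_events(sess.wheel, PipelineConfig())
        ep = common_average_reference(
            epoch(sess.eeg, sess.fs, ev, (-2.5, 2.5), ch_names=sess.eeg_ch_names)
        )
        d = decompose(ep, 8, seed=11)
        kept = select_brain_ics(d)
        maps = forward_maps(sess.eeg.shape[0])
        maps = maps - maps.mean(axis=0, keepdims=True)
        maps /= np.linalg.norm(maps, axis=0)
        match = np.abs(d.scalp_maps() @ maps)  # components x 2 true sources
        mu_ic = int(np.argmax(match[:, 0]))
        assert match[mu_ic, 0] > 0.8
        assert mu_ic in kept
        # the component least like either true map is a noise component
        # with a spatially rough map
        noise_ic = int(np.argmin(match.max(axis=1)))
        assert noise_ic not in kept
        assert d.scores["smoothness"][noise_ic] < 0.6

    def test_white_noise_component_fails_spectral_slope(self, rng):
        """A flat-spectrum component is excluded by the 1/f slope
        criterion even when its scalp map is smooth."""
        from steercouple.synth import (
            SessionSpec,
            _bursty_envelope,
            _narrowband_noise,
            forward_maps,
            ideal_layout,
        )

        n = 40000
        fs = 500.0
        spec = SessionSpec()
        s1 = _bursty_envelope(rng, n, fs, 0.5) * _narrowband_noise(rng, n, fs, 10.0, 2.0)
        s2 = rng.standard_normal(n)  # white noise, smooth map
        maps = forward_maps(32)
        X = maps @ np.vstack([s1, s2]) + 0.05 * rng.standard_normal((32, n))
        ep = EpochSet(X.reshape(32, 10, n // 10).transpose(1, 0, 2), fs, (0.0, n / 10 / fs))
        d = decompose(ep, 4, seed=0)
        kept = select_brain_ics(d, layout=ideal_layout(32))
        nm = maps / np.linalg.norm(maps, axis=0)
        match = np.abs(d.scalp_maps() @ nm)
        mu_ic = int(np.argmax(match[:, 0]))
        white_ic = int(np.argmax(match[:, 1]))
        assert mu_ic in kept
        assert white_ic not in kept
        assert d.scores["spectral_slope"][white_ic] > -0.5
        assert d.scores["spectral_slope"][mu_ic] <= -0.5


class TestKMeans:
    def test_two_orthogonal_groups_perfectly_separated(self, rng):
        base = np.eye(6)[:2]
        maps = np.concatenate(
            [base[0] + 0.01 * rng.standard_normal((10, 6)),
             base[1] + 0.01 * rng.standard_normal((10, 6))]
        )
        out = kmeans_scalp_maps(maps, 2, seed=0)
        assert len(set(out.labels[:10])) == 1
        assert len(set(out.labels[10:])) == 1
        assert out.labels[0] != out.labels[10]

    def test_k1_matches_closed_form_objective(self, rng):
        maps = rng.standard_normal((7, 5))
        X = np.stack([normalize_map(m) for m in maps])
        out = kmeans_scalp_maps(maps, 1, seed=0)
        centroid = X.mean(axis=0)
        expected = ((X - centroid) ** 2).sum()
        assert out.objective == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(
            out.centroids[0], centroid / np.linalg.norm(centroid), atol=1e-12
        )

    def test_duplicates_share_a_cluster(self, rng):
        m = normalize_map(rng.standard_normal(5))
        other = normalize_map(rng.standard_normal(5))
        maps = np.stack([m, m, m, other, other])
        out = kmeans_scalp_maps(maps, 2, seed=0)
        assert len(set(out.labels[:3])) == 1

    def test_input_order_invariance(self, rng):
        maps = rng.standard_normal((12, 6))
        out1 = kmeans_scalp_maps(maps, 3, seed=4)
        perm = rng.permutation(12)
        out2 = kmeans_scalp_maps(maps[perm], 3, seed=4)
        # same partition up to label renaming
        co1 = out1.labels[perm][:, None] == out1.labels[perm][None, :]
        co2 = out2.labels[:, None] == out2.labels[None, :]
        np.testing.assert_array_equal(co1, co2)
        assert out2.objective == pytest.approx(out1.objective, rel=1e-9)

    def test_polarity_flip_invariance(self, rng):
        """Sign-canonicalization makes clustering immune to ICA polarity."""
        maps = rng.standard_normal((10, 6))
        flips = np.where(rng.random(10) < 0.5, -1.0, 1.0)
        out1 = kmeans_scalp_maps(maps, 3, seed=2)
        out2 = kmeans_scalp_maps(maps * flips[:, None], 3, seed=2)
        np.testing.assert_array_equal(out1.labels, out2.labels)


class TestStability:
    @staticmethod
    def _blobs(rng, k=3, per=12, dim=8, spread=0.05):
        centers = np.eye(dim)[:k]
        return np.concatenate(
            [c + spread * rng.standard_normal((per, dim)) for c in centers]
        )

    def test_three_blobs_select_three(self, rng):
        maps = self._blobs(rng)
        k_star, curve = stability_select_k(maps, range(2, 6), n_boot=10, seed=0)
        assert k_star == 3
        assert curve[3] > 0.95

    def test_uniform_maps_fall_back_to_argmax(self, rng, caplog):
        maps = rng.standard_normal((20, 8))
        with caplog.at_level("INFO"):
            k_star, curve = stability_select_k(
                maps, range(2, 6), n_boot=8, seed=1, threshold=0.999
            )
        assert "argmax" in caplog.text
        assert k_star == max(curve, key=lambda k: (np.nan_to_num(curve[k], nan=-np.inf), -k))

    def test_invalid_k_range(self, rng):
        maps = rng.standard_normal((6, 4))
        with pytest.raises(InvalidParameterError):
            stability_select_k(maps, range(2, 7), n_boot=3, seed=0)


def test_distance_identity_and_objective_monotonicity(rng):
    """d(x, c) >= 0 with equality iff x == c; restarts keep the best
    (lowest) objective so more restarts can only improve it."""
    x = normalize_map(rng.standard_normal(6))
    assert ((x - x) ** 2).sum() == 0.0
    maps = rng.standard_normal((15, 6))
    o1 = kmeans_scalp_maps(maps, 4, n_restarts=1, seed=0).objective
    o10 = kmeans_scalp_maps(maps, 4, n_restarts=10, seed=0).objective
    assert o10 <= o1 + 1e-12
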