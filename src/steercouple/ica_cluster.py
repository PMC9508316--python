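"""Independent components of epoched EEG and scalp-map clustering.

Decomposition uses a negentropy-based ICA (FastICA) on concatenated
epochs, with deterministic ordering (by explained sensor variance) and a
sign convention (largest-|weight| element of each scalp map positive) so
results are reproducible and squared-Euclidean clustering is immune to
ICA polarity flips. Components are screened by three configurable
brain-likeness criteria (smooth unimodal map, 1/f-like spectrum with an
alpha peak allowed, non-spiky activation). Maps are grouped across
subjects by K-means under d(x, c) = (x - c)(x - c)', with the number of
clusters chosen by a bootstrap stability index (correlation of
co-assignment matrices over subsample pairs, Ben-Hur style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.stats
from sklearn.decomposition import FastICA

from .containers import EpochSet, InvalidParameterError
from .synth import ideal_layout

log = logging.getLogger(__name__)


def normalize_map(weights: np.ndarray) -> np.ndarray:
    """Unit-norm scalp map with the largest-|weight| element positive."""
    w = np.asarray(weights, dtype=float)
    nrm = np.linalg.norm(w)
    if nrm == 0 or not np.all(np.isfinite(w)):
        raise InvalidParameterError("scalp map must be finite and nonzero")
    w = w / nrm
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


@dataclass
class ICDecomposition:
    """Unmixing/mixing matrices, activations, per-component scores."""

    mixing: np.ndarray  # channels x components (scalp maps in columns)
    unmixing: np.ndarray  # components x channels
    activations: EpochSet
    scores: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def scalp_maps(self) -> np.ndarray:
        """(n_components, n_channels) unit-norm sign-fixed maps."""
        return np.stack([normalize_map(self.mixing[:, k]) for k in range(self.n_components)])


def decompose(eeg: EpochSet, n_components: int, seed: int = 0) -> ICDecomposition:
    """FastICA of concatenated epochs, deterministic given ``seed``.

    Components are ordered by explained sensor variance, signs fixed at the
    scalp-map level. Rank-deficient input is reduced to the numerical rank
    with a warning. mixing @ unmixing is the identity on the retained
    subspace.
    """
    n_trials, n_ch, n_samp = eeg.values.shape
    X = eeg.values.transpose(1, 0, 2).reshape(n_ch, n_trials * n_samp)
    X = X - X.mean(axis=1, keepdims=True)
    if n_trials * n_samp < 5 * n_ch * n_components:
        log.warning(
            "only %d samples for %d channels: ICA may be underdetermined",
            n_trials * n_samp,
            n_ch,
        )
    sv = np.linalg.svd(X, compute_uv=False)
    rank = int((sv > sv[0] * 1e-10).sum())
    if n_components > rank:
        log.warning("rank-deficient input: reducing n_components %d -> %d", n_components, rank)
        n_components = rank

    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=seed,
        max_iter=5000,
        tol=1e-4,
    )
    S = ica.fit_transform(X.T).T  # components x samples
    mixing = ica.mixing_.copy()  # channels x components
    unmixing = ica.components_.copy()

    # order by explained sensor variance, then fix signs
    expl = (mixing**2).sum(axis=0) * S.var(axis=1)
    order = np.argsort(expl)[::-1]
    mixing, unmixing, S = mixing[:, order], unmixing[order], S[order]
    for k in range(n_components):
        if mixing[np.argmax(np.abs(mixing[:, k])), k] < 0:
            mixing[:, k] *= -1
            unmixing[k] *= -1
            S[k] *= -1

    acts = EpochSet(
        S.reshape(n_components, n_trials, n_samp).transpose(1, 0, 2),
        eeg.fs,
        eeg.window,
        [f"IC{k:03d}" for k in range(n_components)],
        eeg.event_labels,
    )
    return ICDecomposition(mixing=mixing, unmixing=unmixing, activations=acts)


def select_brain_ics(
    decomp: ICDecomposition,
    layout: np.ndarray | None = None,
    smoothness_min: float = 0.6,
    max_peaks: int = 2,
    slope_max: float = -0.5,
    kurtosis_max: float = 30.0,
) -> list[int]:
    """Indices of components passing the brain-likeness screen.

    Criteria (thresholds configurable): (a) spatially smooth, near-unimodal
    scalp map -- neighbor-average correlation >= ``smoothness_min`` and at
    most ``max_peaks`` local maxima above half the map peak; (b) 1/f-like
    activation spectrum -- log-log PSD slope <= ``slope_max`` with the
    7-14 Hz alpha region excluded from the fit so a mu/alpha peak is
    allowed; (c) activation kurtosis <= ``kurtosis_max`` (no spiky
    artifact). May return an empty list with a warning.
    """
    n_ch = decomp.mixing.shape[0]
    pos = ideal_layout(n_ch) if layout is None else np.asarray(layout)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    neighbors = np.argsort(d2, axis=1)[:, :4]

    fs = decomp.activations.fs
    acts = decomp.activations.values  # trials x comps x samples
    flat = acts.transpose(1, 0, 2).reshape(decomp.n_components, -1)
    f, psd = scipy.signal.welch(flat, fs=fs, nperseg=min(flat.shape[1], int(4 * fs)))
    fit_band = (f >= 2) & (f <= min(40.0, fs / 2 - 1)) & ~((f >= 7) & (f <= 14))

    kept = []
    smooth_scores, slopes, kurts = [], [], []
    for k in range(decomp.n_components):
        m = normalize_map(decomp.mixing[:, k])
        nb_avg = m[neighbors].mean(axis=1)
        smooth = float(np.corrcoef(m, nb_avg)[0, 1])
        # unimodality on the dominant-sign side: the shallow opposite-sign
        # rim a common-average reference adds around a focal map is not a
        # second mode
        is_peak = m >= m[neighbors].max(axis=1)
        n_peaks = int((is_peak & (m > 0.5 * m.max())).sum())
        slope = float(
            np.polyfit(np.log10(f[fit_band]), np.log10(psd[k][fit_band] + 1e-30), 1)[0]
        )
        kurt = float(scipy.stats.kurtosis(flat[k]))
        smooth_scores.append(smooth)
        slopes.append(slope)
        kurts.append(kurt)
        if (
            smooth >= smoothness_min
            and n_peaks <= max_peaks
            and slope <= slope_max
            and kurt <= kurtosis_max
        ):
            kept.append(k)
    decomp.scores = {
        "smoothness": np.array(smooth_scores),
        "spectral_slope": np.array(slopes),
        "kurtosis": np.array(kurts),
    }
    if not kept:
        log.warning("no component passed the brain-likeness screen")
    return kept


# ---------------------------------------------------------------------------
# K-means on scalp maps


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-map cluster id
    centroids: np.ndarray  # k x dim, unit-normalized
    objective: float  # total within-cluster squared Euclidean distance
    stability: dict[int, float] | None = None  # per candidate k, if selected


def _kmeans_once(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's algorithm with k-means++ init and farthest-point re-seeding."""
    n = X.shape[0]
    # k-means++ seeding
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(((X[:, None, :] - np.array(centers)[None]) ** 2).sum(-1), axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    C = np.array(centers)

    prev = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - C[None]) ** 2).sum(-1)
        labels = d2.argmin(axis=1)
        obj = d2[np.arange(n), labels].sum()
        for j in range(k):
            members = labels == j
            if members.any():
                C[j] = X[members].mean(axis=0)
            else:  # empty cluster: re-seed from the farthest point
                far = int(d2[np.arange(n), labels].argmax())
                C[j] = X[far]
        if prev - obj <= 1e-12 * max(prev, 1.0):
            break
        prev = obj
    d2 = ((X[:, None, :] - C[None]) ** 2).sum(-1)
    labels = d2.argmin(axis=1)
    obj = float(d2[np.arange(n), labels].sum())
    return labels, C, obj


def kmeans_scalp_maps(
    maps: np.ndarray, k: int, n_restarts: int = 10, seed: int = 0
) -> ClusterAssignment:
    """K-means under squared Euclidean distance d(x,c) = (x-c)(x-c)'.

    Maps are sign/norm-canonicalized first. The best of ``n_restarts``
    seeded runs is kept; the result does not depend on the input order
    because restarts are initialized on a canonically (lexicographically)
    ordered copy of the data. Reported centroids are unit-normalized; the
    objective refers to the raw (mean) centroids.
    """
    X = np.stack([normalize_map(m) for m in np.asarray(maps, dtype=float)])
    n = X.shape[0]
    if not 1 <= k <= n:
        raise InvalidParameterError(f"k={k} outside [1, {n}]")
    canon = np.lexsort(X.T[::-1])  # canonical row order
    Xc = X[canon]

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        labels_c, C, obj = _kmeans_once(Xc, k, rng)
        if best is None or obj < best[2] - 1e-12:
            best = (labels_c, C, obj)
    labels_c, C, obj = best
    labels = np.empty(n, dtype=int)
    labels[canon] = labels_c
    # relabel clusters deterministically by first occurrence
    remap, out = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    centroids = np.zeros((k, X.shape[1]))
    for old, new in remap.items():
        centroids[new] = C[old]
    for j in range(k):
        nrm = np.linalg.norm(centroids[j])
        if nrm > 0:
            centroids[j] = centroids[j] / nrm
    return ClusterAssignment(labels=out, centroids=centroids, objective=float(obj))


def _coassignment(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def stability_select_k(
    maps: np.ndarray,
    k_range: range | list[int],
    n_boot: int = 20,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    threshold: float = 0.85,
    n_restarts: int = 5,
) -> tuple[int, dict[int, float]]:
    """Bootstrap stability index over candidate cluster counts.

    For each k, pairs of random subsamples are clustered independently and
    scored by the Pearson correlation of their co-assignment matrices on
    the shared items; the index is the mean over ``n_boot`` pairs. The
    chosen k* is the largest k whose index exceeds ``threshold``, falling
    back (with a log message) to the argmax when none does.
    """
    X = np.stack([normalize_map(m) for m in np.asarray(maps, dtype=float)])
    n = X.shape[0]
    ks = list(k_range)
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise InvalidParameterError(f"k_range must lie within [2, {n - 1}]")
    m = max(int(round(subsample_fraction * n)), 3)
    rng = np.random.default_rng(seed)

    curve: dict[int, float] = {}
    for k in ks:
        scores = []
        for b in range(n_boot):
            ia = rng.choice(n, size=m, replace=False)
            ib = rng.choice(n, size=m, replace=False)
            la = kmeans_scalp_maps(X[ia], k, n_restarts=n_restarts, seed=seed * 1000 + b).labels
            lb = kmeans_scalp_maps(X[ib], k, n_restarts=n_restarts, seed=seed * 1000 + 500 + b).labels
            shared, pa, pb = np.intersect1d(ia, ib, return_indices=True)
            if shared.size < 3:
                continue
            ca = _coassignment(la[pa])[np.triu_indices(shared.size, 1)]
            cb = _coassignment(lb[pb])[np.triu_indices(shared.size, 1)]
            if ca.std() == 0 or cb.std() == 0:
                scores.append(1.0 if np.array_equal(ca, cb) else 0.0)
            else:
                scores.append(float(np.corrcoef(ca, cb)[0, 1]))
        curve[k] = float(np.mean(scores)) if scores else np.nan
    passing = [k for k in ks if curve[k] >= threshold]
    if passing:
        k_star = max(passing)
    else:
        k_star = max(curve, key=lambda k: (np.nan_to_num(curve[k], nan=-np.inf), -k))
        log.info("no k reached stability %.2f; falling back to argmax k=%d", threshold, k_star)
    return k_star, curve
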