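"""Permutation statistics for time-frequency and coupling panels.

Condition contrasts are dependent-sample t-maps across subjects, corrected
for multiple comparisons by sign-flip permutation with a weighted cluster
mass statistic: suprathreshold (|t| > cluster-forming threshold)
4-connected regions are scored by sum((|t| - thresh)^theta), and the
observed cluster masses are referred to the permutation distribution of
the maximum mass. Coupling statistics against an explicit null ensemble
are converted to Z scores with normal-tail p-values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.stats

from .containers import DegenerateInputError, InvalidParameterError

log = logging.getLogger(__name__)


def _t_from_diffs(d: np.ndarray, warn_zero_var: bool = False) -> np.ndarray:
    """Paired t across the first axis; zero-variance elements give t = 0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    var = d.var(axis=0, ddof=1)
    zero = var <= 0
    if warn_zero_var and zero.any():
        log.warning("%d zero-variance elements: t set to 0", int(zero.sum()))
    t = np.zeros_like(mean)
    np.divide(mean, np.sqrt(var / n), out=t, where=~zero)
    return t


def paired_t_map(panels_a: np.ndarray, panels_b: np.ndarray) -> np.ndarray:
    """Element-wise dependent-sample t statistic across subjects.

    ``panels_a``/``panels_b`` are (n_subjects, ...) with matching subjects.
    """
    a = np.asarray(panels_a, dtype=float)
    b = np.asarray(panels_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("panels_a and panels_b must have identical shape")
    if a.shape[0] < 2:
        raise InvalidParameterError("need at least 2 subjects")
    return _t_from_diffs(a - b, warn_zero_var=True)


@dataclass
class StatResult:
    """t-map, clusters, permutation p-values and the significance mask."""

    t_map: np.ndarray
    cluster_labels: np.ndarray
    cluster_masses: np.ndarray
    cluster_p: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    threshold: float
    n_permutations: int
    seed: int | None = None
    null_max_mass: np.ndarray = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return self.cluster_masses.size

    @property
    def min_p(self) -> float:
        return float(self.cluster_p.min()) if self.cluster_p.size else 1.0


def _cluster_masses(
    t: np.ndarray, thresh: float, theta: float, structure: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Label |t|-suprathreshold regions and compute weighted cluster masses."""
    supra = np.abs(t) > thresh
    labels, n = scipy.ndimage.label(supra, structure=structure)
    if n == 0:
        return labels, np.empty(0)
    excess = (np.abs(t) - thresh) ** theta
    masses = scipy.ndimage.sum_labels(excess, labels, index=np.arange(1, n + 1))
    return labels, np.atleast_1d(masses)


def perm_cluster_test(
    panels_a: np.ndarray,
    panels_b: np.ndarray,
    n_perm: int | str = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    mass_exponent: float = 1.0,
    seed: int = 0,
) -> StatResult:
    """Sign-flip permutation test with weighted-cluster-mass correction.

    Subject-wise condition differences are sign-flipped ``n_perm`` times
    (or exhaustively over all 2^n patterns with ``n_perm="all"``); clusters
    are 4-connected regions of |t| above the two-sided t-quantile at
    ``cluster_alpha``; cluster mass is sum((|t| - thresh)^theta) with
    ``theta = mass_exponent`` weighting height against extent. Cluster
    p-values come from the max-mass null with the (1 + count)/(1 + n_perm)
    convention (exhaustive mode counts the identity pattern instead).
    """
    a = np.asarray(panels_a, dtype=float)
    b = np.asarray(panels_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("panels_a and panels_b must have identical shape")
    d = a - b
    n = d.shape[0]
    if n < 2:
        raise InvalidParameterError("need at least 2 subjects")
    shape = d.shape[1:]
    if len(shape) != 2:
        raise InvalidParameterError("panels must be (subjects, freqs, times)")
    structure = scipy.ndimage.generate_binary_structure(2, 1)  # 4-connectivity

    thresh = float(scipy.stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n - 1))
    t_obs = _t_from_diffs(d)
    labels, masses = _cluster_masses(t_obs, thresh, mass_exponent, structure)

    exhaustive = n_perm == "all"
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        if 2.0 / 2**n > alpha:
            log.warning(
                "with %d subjects the smallest achievable p exceeds alpha=%.3g", n, alpha
            )
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(int(n_perm), n))

    # vectorized t-maps for all sign patterns: only the mean flips, the
    # second moment is sign-invariant
    dflat = d.reshape(n, -1)
    q = (dflat**2).mean(axis=0)
    null_max = np.empty(signs.shape[0])
    chunk = max(1, int(2e7 // max(dflat.shape[1], 1)))
    for s0 in range(0, signs.shape[0], chunk):
        S = signs[s0 : s0 + chunk]
        m = S @ dflat / n
        var = np.clip((q[None, :] - m**2) * n / (n - 1), 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(var > 0, m / np.sqrt(var / n), 0.0)
        for i, row in enumerate(t_perm):
            _, perm_masses = _cluster_masses(
                row.reshape(shape), thresh, mass_exponent, structure
            )
            null_max[s0 + i] = perm_masses.max() if perm_masses.size else 0.0

    if masses.size:
        # the identity flip must count: the vectorized null path accumulates
        # up to ~1e-7 relative error on near-degenerate t cells, while
        # distinct sign patterns change masses by O(1)
        tol = 1e-6 * np.abs(masses[:, None]) + 1e-12
        counts = (null_max[None, :] >= masses[:, None] - tol).sum(axis=1)
        if exhaustive:
            p = counts / signs.shape[0]
        else:
            p = (1.0 + counts) / (1.0 + signs.shape[0])
    else:
        p = np.empty(0)

    sig = np.zeros(shape, dtype=bool)
    for ci in np.flatnonzero(p <= alpha):
        sig |= labels == ci + 1
    return StatResult(
        t_map=t_obs,
        cluster_labels=labels,
        cluster_masses=masses,
        cluster_p=p,
        sig_mask=sig,
        alpha=alpha,
        threshold=thresh,
        n_permutations=signs.shape[0],
        seed=None if exhaustive else seed,
        null_max_mass=null_max,
    )


def z_against_null(
    observed: np.ndarray | float, null_ensemble: np.ndarray, two_sided: bool = True
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Z score of an observed statistic against a null ensemble, with the
    normal-tail p-value (two-sided by default)."""
    null = np.asarray(null_ensemble, dtype=float)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateInputError("null ensemble has zero variance")
    z = (np.asarray(observed, dtype=float) - mean) / sd
    if two_sided:
        p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    else:
        p = scipy.stats.norm.sf(z)
    if np.ndim(observed) == 0:
        return float(z), float(min(p, 1.0))
    return z, np.minimum(p, 1.0)


def earliness(
    sig_mask_a: np.ndarray,
    sig_mask_b: np.ndarray,
    times_a: np.ndarray,
    times_b: np.ndarray | None = None,
) -> float | None:
    """Lead of mask A's earliest significant time over mask B's, in seconds.

    Positive values mean A becomes significant earlier. Returns None (with
    a log message) when either mask is empty.
    """
    a = np.asarray(sig_mask_a, dtype=bool)
    b = np.asarray(sig_mask_b, dtype=bool)
    ta = np.asarray(times_a, dtype=float)
    tb = ta if times_b is None else np.asarray(times_b, dtype=float)
    cols_a = np.flatnonzero(a.any(axis=0))
    cols_b = np.flatnonzero(b.any(axis=0))
    if cols_a.size == 0 or cols_b.size == 0:
        log.info("earliness undefined: at least one significance mask is empty")
        return None
    return float(tb[cols_b[0]] - ta[cols_a[0]])
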