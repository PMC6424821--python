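"""Detection and tracking of neuronal co-activation assemblies.

The method follows the ICA-based assembly framework: spikes are counted in
25-ms bins and z-scored per neuron; the number of significant co-activation
patterns is the number of eigenvalues of the neuron correlation matrix
exceeding the Marcenko-Pastur bound ``lambda_max = (1 + sqrt(N/B))**2``
(N retained neurons, B bins); independent component analysis on the data
projected into the significant principal subspace yields one unit-norm
weight vector per pattern.  The activation strength of a pattern at time t
is the quadratic form

    A(t) = z(t)^T P z(t),      P = w w^T with diag(P) = 0,

of the Gaussian-smoothed, z-scored population rate, so only co-activations
of distinct neurons contribute.  Pattern activations are peaks of A(t)
above a threshold (default 5).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.decomposition import FastICA

from .core import PositionTrace, SpikeTrainSet, validate_interval

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_S = 0.025
#: Gaussian kernel SD for strength tracking: same variance as a 25-ms boxcar.
DEFAULT_KERNEL_SD_S = DEFAULT_BIN_WIDTH_S / np.sqrt(12.0)
DEFAULT_STEP_S = 0.001
R_THRES = 5.0


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------


@dataclass
class BinnedActivity:
    """Neurons x bins matrix of z-scored 25-ms spike counts.

    Rows with zero count variance (silent or perfectly regular neurons)
    are excluded before z-scoring; ``neuron_ids`` maps retained rows back
    to neuron ids and ``excluded_ids`` records the dropped ones.
    """

    Z: np.ndarray
    bin_width: float
    neuron_ids: list
    excluded_ids: list = field(default_factory=list)
    interval: tuple = (0.0, 0.0)

    @property
    def n_neurons(self) -> int:
        return self.Z.shape[0]

    @property
    def n_bins(self) -> int:
        return self.Z.shape[1]


def bin_and_zscore(
    spikes: SpikeTrainSet, interval, bin_width: float = DEFAULT_BIN_WIDTH_S
) -> BinnedActivity:
    """Count spikes in half-open bins ``[k*d, (k+1)*d)`` and z-score rows."""
    a, b = validate_interval(interval)
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.floor((b - a) / bin_width))
    if n_bins < 1:
        raise ValueError("interval shorter than one bin")
    edges = a + bin_width * np.arange(n_bins + 1)
    ids = spikes.neuron_ids
    counts = np.empty((len(ids), n_bins))
    for r, nid in enumerate(ids):
        counts[r] = np.histogram(spikes[nid], bins=edges)[0]
    sd = counts.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all neurons have zero count variance in the interval")
    excluded = [nid for nid, k in zip(ids, keep) if not k]
    if excluded:
        logger.info("excluding %d zero-variance neurons: %s", len(excluded), excluded)
    Z = (counts[keep] - counts[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return BinnedActivity(
        Z=Z,
        bin_width=bin_width,
        neuron_ids=[nid for nid, k in zip(ids, keep) if k],
        excluded_ids=excluded,
        interval=(a, b),
    )


# --------------------------------------------------------------------------
# pattern counting and extraction
# --------------------------------------------------------------------------


def marcenko_pastur_lambda_max(n_neurons: int, n_bins: int) -> float:
    """Upper Marcenko-Pastur eigenvalue bound for unit-variance data."""
    return (1.0 + np.sqrt(n_neurons / n_bins)) ** 2


def count_significant_patterns(binned: BinnedActivity) -> int:
    """Number of correlation-matrix eigenvalues above the MP threshold."""
    N, B = binned.n_neurons, binned.n_bins
    if B <= N:
        raise ValueError(
            f"need more bins than neurons for the Marcenko-Pastur bound "
            f"(N={N}, B={B})"
        )
    corr = binned.Z @ binned.Z.T / B
    evals = np.linalg.eigvalsh(corr)
    return int(np.count_nonzero(evals > marcenko_pastur_lambda_max(N, B)))


@dataclass
class AssemblyPattern:
    """Unit-norm weight vector over neurons, with its high-weight members.

    The sign convention fixes the largest-|w| entry positive; members are
    the neurons whose weight exceeds the vector mean by two SDs.
    """

    w: np.ndarray
    neuron_ids: list

    def __post_init__(self):
        w = np.asarray(self.w, float).ravel()
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ValueError("zero weight vector")
        w = w / nrm
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        self.w = w
        self.neuron_ids = [int(i) for i in self.neuron_ids]
        if len(self.neuron_ids) != w.size:
            raise ValueError("weight vector / neuron id length mismatch")

    @property
    def members(self) -> set:
        thr = self.w.mean() + 2.0 * self.w.std()
        return {nid for nid, wi in zip(self.neuron_ids, self.w) if wi > thr}

    def projector(self) -> np.ndarray:
        """Outer product of w with zeroed diagonal."""
        P = np.outer(self.w, self.w)
        np.fill_diagonal(P, 0.0)
        return P

    def aligned_to(self, neuron_ids) -> "AssemblyPattern":
        """Re-express on another neuron index space; absent neurons get
        weight 0, dropped ones are removed, and the vector is renormalized."""
        target = [int(i) for i in neuron_ids]
        cur = dict(zip(self.neuron_ids, self.w))
        w = np.array([cur.get(i, 0.0) for i in target])
        if np.linalg.norm(w) == 0:
            raise ValueError("pattern has no support on the target neuron set")
        return AssemblyPattern(w, target)


def extract_patterns(
    binned: BinnedActivity,
    n_patterns: int,
    seed: int = 0,
    max_restarts: int = 3,
) -> list[AssemblyPattern]:
    """ICA in the top-``n_patterns`` principal subspace of the binned data.

    Each independent component is back-projected to neuron space,
    unit-normalized and sign-fixed.  Deterministic under a fixed seed; on
    FastICA non-convergence the fit is retried with fresh derived seeds up
    to ``max_restarts`` times before raising.
    """
    N = binned.n_neurons
    if not 1 <= n_patterns <= N:
        raise ValueError(f"n_patterns must lie in [1, {N}]")
    Z = binned.Z
    B = binned.n_bins
    corr = Z @ Z.T / B
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:n_patterns]
    V = evecs[:, order]  # N x k principal directions
    proj = V.T @ Z  # k x B projected activity

    if n_patterns == 1:
        return [AssemblyPattern(V[:, 0], binned.neuron_ids)]

    last_err = None
    for attempt in range(max_restarts + 1):
        rs = seed + 1009 * attempt
        ica = FastICA(
            n_components=n_patterns,
            algorithm="deflation",
            whiten="unit-variance",
            random_state=rs,
            max_iter=1000,
            tol=1e-6,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                ica.fit(proj.T)
            except Exception as exc:  # numerical failure
                last_err = exc
                continue
            if any("did not converge" in str(w.message) for w in caught):
                last_err = RuntimeError("FastICA did not converge")
                logger.info("FastICA restart %d (seed %d)", attempt + 1, rs)
                continue
        mixing = ica.mixing_  # k x k: columns are component directions
        return [
            AssemblyPattern(V @ mixing[:, j], binned.neuron_ids)
            for j in range(n_patterns)
        ]
    raise RuntimeError(f"FastICA failed after {max_restarts} restarts: {last_err}")


# --------------------------------------------------------------------------
# activation strength
# --------------------------------------------------------------------------


@dataclass
class ActivationTrace:
    """Activation-strength time course A(t) of one assembly pattern."""

    times: np.ndarray
    strength: np.ndarray
    r_thres: float = R_THRES
    peaks: np.ndarray = field(default_factory=lambda: np.empty(0))


def _smoothed_zscored_rates(
    spikes: SpikeTrainSet, neuron_ids, interval, kernel_sd: float, step: float
):
    """Gaussian-smoothed spike rates on a uniform grid, z-scored per neuron.

    Returns ``(times, z, kept_mask)`` where rows of ``z`` follow
    ``neuron_ids``; zero-variance rows are flagged False in ``kept_mask``.
    """
    a, b = validate_interval(interval)
    n = int(np.floor((b - a) / step))
    edges = a + step * np.arange(n + 1)
    times = edges[:-1] + step / 2.0
    z = np.empty((len(neuron_ids), n))
    kept = np.ones(len(neuron_ids), bool)
    sigma_samples = kernel_sd / step
    for r, nid in enumerate(neuron_ids):
        counts = np.histogram(spikes[nid], bins=edges)[0].astype(float)
        sm = gaussian_filter1d(counts, sigma_samples, mode="constant")
        sd = sm.std()
        if sd == 0:
            kept[r] = False
            z[r] = 0.0
        else:
            z[r] = (sm - sm.mean()) / sd
    return times, z, kept


def activation_strength(
    pattern: AssemblyPattern,
    spikes: SpikeTrainSet,
    interval,
    kernel_sd: float = DEFAULT_KERNEL_SD_S,
    step: float = DEFAULT_STEP_S,
) -> ActivationTrace:
    """Track A(t) = z(t)^T P z(t) on a uniform grid.

    Each spike train is convolved with a Gaussian kernel (SD
    ``kernel_sd``), sampled every ``step`` seconds and z-scored over the
    interval.  Neurons whose smoothed trace has zero variance are removed
    from the pattern (weights renormalized, logged).
    """
    missing = set(pattern.neuron_ids) - set(spikes.neuron_ids)
    if missing:
        raise ValueError(f"pattern references neurons absent from spikes: {missing}")
    times, z, kept = _smoothed_zscored_rates(
        spikes, pattern.neuron_ids, interval, kernel_sd, step
    )
    w = pattern.w.copy()
    if not kept.all():
        dropped = [nid for nid, k in zip(pattern.neuron_ids, kept) if not k]
        logger.info("dropping zero-variance neurons from pattern: %s", dropped)
        w[~kept] = 0.0
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return ActivationTrace(times, np.zeros_like(times))
        w = w / nrm
    # A = (w.z)^2 - sum_i w_i^2 z_i^2  (zero-diagonal quadratic form)
    wz = w @ z
    diag = (w**2) @ (z**2)
    return ActivationTrace(times, wz**2 - diag)


def detect_activations(
    trace: ActivationTrace,
    r_thres: float = R_THRES,
    min_separation: float = DEFAULT_BIN_WIDTH_S,
) -> np.ndarray:
    """Peak times where A(t) exceeds ``r_thres`` at a local maximum,
    at least ``min_separation`` apart.  Updates ``trace.peaks``."""
    t, s = trace.times, trace.strength
    if t.size < 3:
        peaks = np.empty(0)
    else:
        step = t[1] - t[0]
        distance = max(1, int(round(min_separation / step)))
        idx, _ = find_peaks(s, distance=distance)
        idx = idx[s[idx] > r_thres]
        # a single boundary sample above threshold flanked by lower values
        for edge in (0, s.size - 1):
            nb = 1 if edge == 0 else s.size - 2
            if s[edge] > r_thres and s[edge] > s[nb] and (
                idx.size == 0 or np.abs(idx - edge).min() >= distance
            ):
                idx = np.sort(np.append(idx, edge))
        peaks = t[idx]
    trace.peaks = peaks
    trace.r_thres = r_thres
    return peaks


def assembly_map(
    peak_times,
    position: PositionTrace,
    spatial_bin_cm: float = 4.0,
):
    """Per-spatial-bin activation rate: peak count / occupancy seconds.

    Unvisited bins are NaN.  Returns ``(rate_map, x_edges, y_edges)``.
    """
    peak_times = np.asarray(peak_times, float)
    if peak_times.size and (
        peak_times.min() < position.t[0] or peak_times.max() > position.t[-1]
    ):
        raise ValueError("position trace does not cover all peak times")
    from .behavior import occupancy_map  # occupancy machinery lives there

    occ, xe, ye = occupancy_map(position, spatial_bin_cm)
    px, py = position.at(peak_times)
    counts = np.histogram2d(px, py, bins=(xe, ye))[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = counts / occ
    rate[occ <= 0] = np.nan
    return rate, xe, ye


# --------------------------------------------------------------------------
# cross-session comparison
# --------------------------------------------------------------------------


def similarity(a: AssemblyPattern, b: AssemblyPattern) -> float:
    """Absolute inner product of the two weight vectors, in [0, 1].

    Patterns from different sessions are intersected on their shared
    neuron ids and renormalized (logged) before the product.
    """
    if a.neuron_ids == b.neuron_ids:
        return float(abs(a.w @ b.w))
    shared = [i for i in a.neuron_ids if i in set(b.neuron_ids)]
    if not shared:
        raise ValueError("patterns share no neurons")
    if len(shared) < max(len(a.neuron_ids), len(b.neuron_ids)):
        logger.info(
            "similarity over %d shared neurons (of %d / %d)",
            len(shared),
            len(a.neuron_ids),
            len(b.neuron_ids),
        )
    return float(abs(a.aligned_to(shared).w @ b.aligned_to(shared).w))


def match_across_sessions(patterns_a, patterns_b):
    """Full pairwise similarity matrix and the optimal one-to-one matching.

    Returns ``(S, matching)`` where ``S[i, j] = similarity(a_i, b_j)`` and
    ``matching`` is a list of ``(i, j)`` index pairs maximizing total
    similarity (Hungarian assignment).
    """
    S = np.array(
        [[similarity(pa, pb) for pb in patterns_b] for pa in patterns_a]
    ).reshape(len(patterns_a), len(patterns_b))
    if S.size == 0:
        return S, []
    rows, cols = linear_sum_assignment(-S)
    return S, list(zip(rows.tolist(), cols.tolist()))
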