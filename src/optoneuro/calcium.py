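"""Calcium-imaging network analysis.

Pipeline: truncated-SVD movie denoising -> active-pixel selection by
fluorescence range -> spike detection on each pixel trace via the
instantaneous phase of the analytic signal -> per-pixel activation-time
maps referenced to the stimulation pulse -> Spearman connectivity matrices
and Gaussian-mixture decomposition of activation-time histograms.

Phase convention: the trace is smoothed with a centered moving average,
locally detrended, and the phase is the argument of its analytic signal,
wrapped to (-pi, pi]. Local minima of the wrapped phase mark the troughs
where calcium rises begin; minima are accepted as events when a
significant fluorescence rise follows, and the deepest-reaching event is
the stimulus-evoked one.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks, hilbert
from scipy.stats import binomtest, rankdata
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

from .types import (
    ActivationTimeMap,
    CalciumMovie,
    CorrelationMatrix,
    MixtureFit,
    PixelMask,
    SpikeCountMap,
    SpikeEventList,
)

DEFAULT_SMOOTH_WINDOW = 5  # frames, at 30-50 fps acquisition
DEFAULT_MIN_PROMINENCE = 0.5 * np.pi  # radians


class SVDDenoiser(BaseEstimator, TransformerMixin):
    """Truncated-SVD denoiser for fluorescence movies.

    Flattens the movie to a frames x pixels matrix, keeps the ``rank`` most
    dominant modes and reconstructs. ``rank="auto"`` picks the elbow of the
    singular-value spectrum (largest consecutive drop ratio).

    Attributes
    ----------
    singular_values_ : full singular-value spectrum, for inspection.
    rank_ : the rank actually used.
    """

    def __init__(self, rank: int | str = "auto"):
        self.rank = rank

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a frames x pixels matrix")
        self.mean_ = X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X - self.mean_, full_matrices=False)
        self.singular_values_ = s
        if self.rank == "auto":
            self.rank_ = _elbow_rank(s)
        else:
            r = int(self.rank)
            if r <= 0:
                raise ValueError("rank must be positive")
            if r > s.size:
                raise ValueError("rank exceeds min(frames, pixels)")
            self.rank_ = r
        self._U, self._s, self._Vt = U, s, Vt
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        r = self.rank_
        Xc = np.asarray(X, dtype=float) - self.mean_
        proj = Xc @ self._Vt[:r].T
        return proj @ self._Vt[:r] + self.mean_


def _elbow_rank(s: np.ndarray) -> int:
    """Elbow of the spectrum: largest ratio between consecutive values."""
    s = s[s > 1e-12 * s[0]] if s.size and s[0] > 0 else s
    if s.size <= 1:
        return max(int(s.size), 1)
    ratios = s[:-1] / s[1:]
    return int(np.argmax(ratios)) + 1


def svd_denoise(movie: CalciumMovie, rank: int | str = "auto") -> CalciumMovie:
    """Rank-truncated reconstruction of the frames x pixels movie matrix."""
    flat = movie.data.reshape(movie.n_frames, -1)
    den = SVDDenoiser(rank=rank).fit(flat)
    out = den.transform(flat).reshape(movie.data.shape)
    result = CalciumMovie(out, movie.frame_rate, movie.stim_times)
    result.singular_values = den.singular_values_
    result.rank = den.rank_
    return result


def active_pixel_mask(
    movie: CalciumMovie, range_threshold: float | str = "auto"
) -> PixelMask:
    """Keep pixels whose max-min fluorescence range reaches the threshold.

    ``"auto"`` applies Otsu's split to the range image.
    """
    rng_img = movie.data.max(axis=0) - movie.data.min(axis=0)
    if range_threshold == "auto":
        thr = float(threshold_otsu(rng_img)) if np.ptp(rng_img) > 0 else np.inf
    else:
        thr = float(range_threshold)
    return PixelMask(rng_img >= thr, thr)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; shrinking windows at the edges."""
    if window <= 1:
        return x.astype(float)
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


DEFAULT_DETREND_WINDOW = 11  # frames of local-baseline moving average
DEFAULT_MIN_SNR = 5.0  # fluorescence prominence over robust noise SD


def instantaneous_phase(
    trace: np.ndarray,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    detrend_window: int = DEFAULT_DETREND_WINDOW,
) -> np.ndarray:
    """Wrapped phase of the analytic signal of the smoothed, detrended trace.

    The local baseline (a ``detrend_window``-frame centered moving average)
    is subtracted before the Hilbert transform, so each transient rise is
    preceded by a well-defined trough and the wrapped phase, in (-pi, pi],
    attains a local minimum there.
    """
    sm = _moving_average(np.asarray(trace, dtype=float), smooth_window)
    return np.angle(hilbert(sm - _moving_average(sm, detrend_window)))


def _robust_noise_sd(trace: np.ndarray) -> float:
    """Noise SD from first differences, insensitive to slow transients."""
    if trace.size < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(trace))) / (0.6745 * np.sqrt(2)))


def phase_spike_detect(
    trace: np.ndarray,
    frame_rate: float,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    detrend_window: int = DEFAULT_DETREND_WINDOW,
    min_snr: float = DEFAULT_MIN_SNR,
) -> SpikeEventList:
    """Detect calcium events as prominent local minima of the phase signal.

    A candidate phase minimum becomes an event only when a significant
    fluorescence rise follows it: each smoothed-trace peak with prominence
    >= ``min_snr`` robust noise SDs claims the nearest preceding phase
    minimum with phase prominence >= ``min_prominence`` as its event time
    (the trough where the rise begins). Wrapped-phase prominences saturate
    near 2*pi regardless of amplitude, so the amplitude gate, not the phase
    prominence, separates transients from noise; the stimulus-evoked event
    is the one with the largest fluorescence prominence.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size <= smooth_window:
        raise ValueError("trace must be longer than smooth_window")
    empty = SpikeEventList(np.array([]), np.array([]), None, np.array([]))
    if np.ptp(trace) == 0:
        return empty
    sm = _moving_average(trace, smooth_window)
    phase = np.angle(hilbert(sm - _moving_average(sm, detrend_window)))
    sigma = max(_robust_noise_sd(trace), 1e-12 * np.ptp(trace))
    peaks, peak_props = find_peaks(sm, prominence=min_snr * sigma)
    mins, min_props = find_peaks(-phase, prominence=min_prominence)
    if peaks.size == 0 or mins.size == 0:
        return empty
    idx, proms, amps = [], [], []
    used: set[int] = set()
    for p, amp in zip(peaks, peak_props["prominences"]):
        prev = np.searchsorted(mins, p) - 1
        if prev < 0 or int(mins[prev]) in used:
            continue
        used.add(int(mins[prev]))
        idx.append(int(mins[prev]))
        proms.append(float(min_props["prominences"][prev]))
        amps.append(float(amp))
    if not idx:
        return empty
    order = np.argsort(idx)
    idx = np.asarray(idx)[order]
    amps = np.asarray(amps)[order]
    proms = np.asarray(proms)[order]
    return SpikeEventList(
        times=idx / frame_rate,
        prominences=proms,
        evoked_index=int(np.argmax(amps)),
        amplitudes=amps,
    )


def evoked_spike_time(
    trace: np.ndarray,
    frame_rate: float,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    detrend_window: int = DEFAULT_DETREND_WINDOW,
    min_snr: float = DEFAULT_MIN_SNR,
) -> float | None:
    """Time of the stimulus-evoked event: the deepest-reaching detected event.

    Returns None when no event passes the prominence and amplitude gates
    (the "no clear event" case).
    """
    events = phase_spike_detect(
        trace, frame_rate, smooth_window, min_prominence, detrend_window, min_snr
    )
    if events.evoked_index is None:
        return None
    return float(events.times[events.evoked_index])


def activation_map(
    movie: CalciumMovie,
    mask: PixelMask,
    stim_time: float,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    pre_stim_tolerance_frames: int = 2,
) -> ActivationTimeMap:
    """Per-pixel latency from the stimulus to the evoked event.

    Pixels outside the mask, without a clear event, or whose event precedes
    the stimulus are NaN; pre-stimulus rejections are counted. Latencies
    within ``pre_stim_tolerance_frames`` before the stimulus are clamped to
    zero rather than rejected (detection resolves onsets only to ~1 frame,
    so the stimulated cell itself would otherwise drop out).
    """
    if not (0 <= stim_time <= movie.duration):
        raise ValueError("stim_time must lie within the movie duration")
    tol = pre_stim_tolerance_frames / movie.frame_rate
    h, w = movie.frame_shape
    T = np.full((h, w), np.nan)
    n_pre = 0
    rows, cols = np.nonzero(mask.mask)
    for r, c in zip(rows, cols):
        t = evoked_spike_time(
            movie.data[:, r, c], movie.frame_rate, smooth_window, min_prominence
        )
        if t is None:
            continue
        lat = t - stim_time
        if lat < -tol:
            n_pre += 1
        else:
            T[r, c] = max(lat, 0.0)
    return ActivationTimeMap(T, "stimulation pulse", n_pre)


def spike_count_map(
    movie: CalciumMovie,
    mask: PixelMask,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> SpikeCountMap:
    """Per-pixel event counts; multi_mask flags pixels with > 1 event."""
    h, w = movie.frame_shape
    counts = np.zeros((h, w), dtype=int)
    rows, cols = np.nonzero(mask.mask)
    for r, c in zip(rows, cols):
        ev = phase_spike_detect(
            movie.data[:, r, c], movie.frame_rate, smooth_window, min_prominence
        )
        counts[r, c] = ev.times.size
    return SpikeCountMap(counts, counts > 1)


def spearman_matrix(traces: np.ndarray, labels: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Spearman rank correlations between ROI traces (rows).

    Constant traces yield NaN rows/columns rather than spurious zeros.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.shape[0] < 2 or traces.shape[1] < 3:
        raise ValueError("need >= 2 ROIs and >= 3 time points")
    ranks = rankdata(traces, axis=1)  # average ranks for ties
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    constant = np.ptp(traces, axis=1) == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    if labels is None:
        labels = [f"ROI{i}" for i in range(traces.shape[0])]
    return CorrelationMatrix(rho, labels)


class ActivationMixture(BaseEstimator):
    """Gaussian-mixture decomposition of activation-time histograms.

    Fits univariate mixtures by EM for every candidate component count and
    keeps the BIC-best model. Means are reported in ascending order.

    Attributes
    ----------
    k_ : selected component count
    means_, sds_, weights_ : mixture parameters sorted by mean
    bic_ : dict of candidate k -> BIC
    """

    def __init__(self, k_candidates=(1, 2, 3, 4, 5, 6), n_init: int = 10, random_state: int = 0):
        self.k_candidates = k_candidates
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        x = x[np.isfinite(x[:, 0])]
        ks = sorted(set(int(k) for k in self.k_candidates))
        if not ks:
            raise ValueError("k_candidates must be non-empty")
        if x.shape[0] < max(10, 2 * max(ks)):
            raise ValueError("need >= max(10, 2*max(k)) finite activation times")
        best, self.bic_ = None, {}
        for k in ks:
            gm = GaussianMixture(
                n_components=k,
                n_init=self.n_init,
                random_state=self.random_state,
                covariance_type="full",
            ).fit(x)
            self.bic_[k] = float(gm.bic(x))
            if best is None or self.bic_[k] < self.bic_[best[0]]:
                best = (k, gm)
        self.k_, gm = best
        order = np.argsort(gm.means_[:, 0])
        self.means_ = gm.means_[order, 0]
        self.sds_ = np.sqrt(gm.covariances_[order, 0, 0])
        self.weights_ = gm.weights_[order]
        return self

    def to_result(self) -> MixtureFit:
        return MixtureFit(self.k_, self.means_, self.sds_, self.weights_, self.bic_)


def fit_activation_mixture(
    times: np.ndarray,
    k_candidates=(1, 2, 3, 4, 5, 6),
    seed: int = 0,
) -> MixtureFit:
    """EM Gaussian mixtures over candidate k; BIC selects the model."""
    am = ActivationMixture(k_candidates=k_candidates, random_state=seed).fit(times)
    return am.to_result()


def responsive_fraction(
    n_active: int, n_total: int, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fraction of responsive cells with an exact binomial confidence interval."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_active <= n_total:
        raise ValueError("need 0 <= n_active <= n_total")
    ci = binomtest(n_active, n_total).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return n_active / n_total, (ci.low, ci.high)
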