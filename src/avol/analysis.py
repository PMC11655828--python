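"""Nonlinear-dynamics measurement battery for EEG-like signals.

Implements the standard toolbox used to characterise attractor dynamics
reconstructed from a scalar time series:

- delay embedding (Takens), with automatic delay (first minimum of the
  average mutual information) and dimension (false nearest neighbours),
- correlation dimension D2 by the Grassberger-Procaccia pair-counting
  algorithm with a Theiler window and automatic scaling-region selection,
- largest Lyapunov exponent by the Rosenstein nearest-neighbour
  divergence method,
- sample entropy,
- Hann-windowed spectrogram with canonical EEG band summaries,
- theta-gamma phase-amplitude coupling via the Hilbert mean vector
  length with a circular time-shift surrogate test.

All estimators report quality flags; a False flag means the returned
number should not be trusted (no scaling region, saturated divergence
curve, ...). Estimates are anchored by oracle tests on signals whose
dimension and exponent are known (limit cycle, Lorenz flow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert, get_window
from scipy.signal import ShortTimeFFT
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddedTrajectory",
    "ChaosMetrics",
    "PACResult",
    "BANDS",
    "average_mutual_information",
    "false_nearest_neighbors",
    "embed",
    "correlation_dimension",
    "lyapunov_largest",
    "sample_entropy",
    "spectrogram",
    "band_power",
    "dominant_frequency",
    "bandpass",
    "pac_mvl",
    "chaos_metrics",
]

# Canonical EEG bands (Hz). The gamma upper edge is capped well below
# typical Nyquist for 1 kHz sampling.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}


@dataclass
class EmbeddedTrajectory:
    """Delay-embedded point cloud.

    ``points`` has shape (N - (m-1)*lag, m); row k is
    (x[k], x[k+lag], ..., x[k+(m-1)*lag]).
    """

    points: np.ndarray
    m: int
    lag: int
    source_fs: float
    #: diagnostics from automatic parameter selection (e.g. whether the
    #: false-nearest-neighbour fraction ever dropped below threshold)
    auto: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != self.m:
            raise ValueError("points must be (n_points, m)")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def theiler_window(self) -> int:
        """Temporal-neighbour exclusion horizon (samples): lag * m."""
        return self.lag * self.m


@dataclass
class ChaosMetrics:
    """(D2, lambda1, sample entropy) for one signal, with quality flags."""

    d2: float
    lyap1: float
    entropy: float
    d2_reliable: bool = True
    lyap_r2: float = float("nan")
    lyap_reliable: bool = True
    entropy_capped: bool = False


@dataclass
class PACResult:
    """Phase-amplitude coupling strength and its surrogate significance."""

    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    mvl: float
    surrogate_p: float
    n_surrogates: int


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def average_mutual_information(x: np.ndarray, max_lag: int, n_bins: int = 16) -> np.ndarray:
    """AMI (nats) between x[t] and x[t+lag] for lag = 1..max_lag.

    Histogram estimator on equiprobable (quantile) bins; equal-width bins
    produce spurious ripples for strongly non-uniform amplitude
    distributions such as a pure sinusoid.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant signal: mutual information undefined")
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValueError("signal has too few distinct values for mutual information")
    n_bins = len(edges) - 1
    edges[-1] += 1e-12
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    ami = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        a, b = idx[:-lag], idx[lag:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        ami[lag - 1] = np.sum(joint[nz] * np.log(joint[nz] / (px[:, None] * py[None, :])[nz]))
    return ami


def _first_local_minimum(y: np.ndarray) -> int | None:
    for i in range(1, len(y) - 1):
        if y[i] < y[i - 1] and y[i] <= y[i + 1]:
            return i + 1  # lag is 1-based
    return None


def false_nearest_neighbors(
    x: np.ndarray,
    lag: int,
    m_max: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
) -> np.ndarray:
    """Fraction of false nearest neighbours for m = 1..m_max (Kennel test)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        n_pts = len(x) - m * lag  # need the (m+1)-th coordinate too
        if n_pts < 10:
            fractions[m - 1:] = np.nan
            return fractions
        pts = _delay_matrix(x, m, lag)[:n_pts]
        tree = cKDTree(pts)
        dist, nbr = tree.query(pts, k=2)
        d, j = dist[:, 1], nbr[:, 1]
        i = np.arange(n_pts)
        extra = np.abs(x[i + m * lag] - x[j + m * lag])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = extra / d
        d_next = np.sqrt(d**2 + extra**2)
        false = (ratio > rtol) | (d_next / sd > atol)
        # pairs closer than numerical resolution are revisits of the same
        # orbit point (periodic signals); they are true neighbours
        valid = d > 1e-8 * sd
        fractions[m - 1] = false[valid].mean() if valid.any() else 0.0
    return fractions


def _delay_matrix(x: np.ndarray, m: int, lag: int) -> np.ndarray:
    n = len(x) - (m - 1) * lag
    return np.column_stack([x[k * lag : k * lag + n] for k in range(m)])


def embed(
    x: np.ndarray,
    m: int | None = None,
    lag: int | None = None,
    fs: float = 1.0,
    m_max: int = 10,
    m_min: int = 2,
    fnn_threshold: float = 0.01,
) -> EmbeddedTrajectory:
    """Delay-embed a scalar series; lag/dimension chosen automatically if None.

    Automatic lag = first local minimum of the average mutual information
    (searched up to N/4); automatic m = smallest dimension with a false
    nearest neighbour fraction below ``fnn_threshold``, floored at
    ``m_min`` (a limit cycle needs at least a plane). Noise-free exactly
    periodic signals revisit orbit points exactly, which degenerates both
    automatic criteria; pass m and lag explicitly for such signals.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    auto: dict = {}
    if lag is None:
        max_lag = max(2, n // 4)
        ami = average_mutual_information(x, max_lag)
        lag = _first_local_minimum(ami)
        if lag is None:
            raise ValueError(
                "no AMI minimum within N/4; pass lag explicitly"
            )
        auto["lag_from_ami"] = True
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if m is None:
        fnn = false_nearest_neighbors(x, lag, m_max=m_max)
        below = np.where(fnn < fnn_threshold)[0]
        converged = bool(below.size)
        m = int(below[0]) + 1 if converged else m_max
        m = max(m, m_min)
        auto["fnn_converged"] = converged
    if n <= (m - 1) * lag + 10:
        raise ValueError(f"series too short for m={m}, lag={lag} (N={n})")
    return EmbeddedTrajectory(points=_delay_matrix(x, m, lag), m=m, lag=lag,
                              source_fs=fs, auto=auto)


# ---------------------------------------------------------------------------
# Correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def correlation_integral(
    traj: EmbeddedTrajectory,
    radii: np.ndarray,
    max_points: int = 4000,
    theiler: int | None = None,
) -> tuple[np.ndarray, int]:
    """C(r): fraction of point pairs (temporal separation > Theiler window)
    with Euclidean distance below r, at each radius.

    Returns (C, n_pairs) where n_pairs is the number of admissible pairs.
    """
    pts = traj.points
    if theiler is None:
        theiler = traj.theiler_window
    n = pts.shape[0]
    stride = max(1, int(np.ceil(n / max_points)))
    sub = np.arange(0, n, stride)
    pts_s = pts[sub]
    m = len(sub)
    theiler_s = max(1, int(np.ceil(theiler / stride)))
    counts = np.zeros(len(radii), dtype=np.int64)
    n_pairs = 0
    chunk = max(1, int(2e7 // max(m * pts.shape[1], 1)))
    r_sorted = np.asarray(radii)
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        block = pts_s[start:stop]
        d2 = ((block[:, None, :] - pts_s[None, :, :]) ** 2).sum(axis=-1)
        ii = np.arange(start, stop)[:, None]
        jj = np.arange(m)[None, :]
        mask = (jj - ii) > theiler_s  # each pair once, exclude temporal neighbours
        d = np.sqrt(d2[mask])
        n_pairs += d.size
        counts += np.searchsorted(np.sort(d), r_sorted, side="right")
    if n_pairs == 0:
        raise ValueError("no admissible pairs: series too short for Theiler window")
    return counts / n_pairs, n_pairs


def correlation_dimension(
    traj: EmbeddedTrajectory,
    n_radii: int = 50,
    max_points: int = 4000,
    min_region: int = 6,
    slope_sd_frac: float = 0.10,
    r2_min: float = 0.98,
    min_count: int = 30,
    r_frac_max: float = 0.35,
) -> tuple[float, dict]:
    """Grassberger-Procaccia correlation dimension with automatic scaling region.

    C(r) is evaluated on ~3 decades of log-spaced radii below the
    attractor diameter. Local slopes of log C vs log r (central
    differences) are scanned for the longest contiguous run (at least
    ``min_region`` radii, restricted to radii with >= ``min_count``
    pairs, C <= 0.5 and r below ``r_frac_max`` of the attractor
    diameter -- the macroscopic scales reflect the attractor's gross
    shape, not its dimension) whose slopes vary by less than
    ``slope_sd_frac`` of their mean; D2 is the least-squares slope over
    that run. Returns (d2, quality) where quality carries ``reliable``,
    the fit ``r2``, and the region bounds. No admissible flat run at
    the required fit quality leaves the estimate flagged unreliable.
    """
    pts = traj.points
    if pts.shape[0] < 100:
        raise ValueError("need at least 100 embedded points")
    # Upper radius from a sampled distance distribution; lower radius three
    # decades down, trimmed later by the pair-count floor.
    rng = np.random.default_rng(0)
    k = min(400, pts.shape[0])
    sample = pts[rng.choice(pts.shape[0], size=k, replace=False)]
    dists = np.sqrt(((sample[:, None, :] - sample[None, :, :]) ** 2).sum(-1))
    pos = dists[dists > 0]
    if pos.size == 0:
        raise ValueError("all embedded points coincide")
    r_hi = float(np.quantile(pos, 0.95))
    radii = np.geomspace(1e-3 * r_hi, r_hi, n_radii)
    c, n_pairs = correlation_integral(traj, radii, max_points=max_points)

    valid = (c * n_pairs >= min_count) & (c <= 0.5) & (radii <= r_frac_max * r_hi)
    quality: dict = {"reliable": False, "r2": np.nan, "region": None,
                     "radii": radii, "c": c}
    if valid.sum() < min_region + 2:
        return float("nan"), quality
    logr, logc = np.log(radii[valid]), np.log(c[valid])

    # central-difference local slopes (less count noise than adjacent pairs)
    slopes = (logc[2:] - logc[:-2]) / (logr[2:] - logr[:-2])
    nn = len(slopes)
    best = None
    for i in range(nn):
        for j in range(i + min_region - 1, nn):
            w = slopes[i : j + 1]
            mu = w.mean()
            if mu <= 0:
                continue
            if w.std() <= slope_sd_frac * mu:
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    fallback = best is None
    if fallback:
        if nn < min_region:
            return float("nan"), quality
        sds = np.array([
            slopes[i : i + min_region].std()
            / max(abs(slopes[i : i + min_region].mean()), 1e-12)
            for i in range(nn - min_region + 1)
        ])
        i = int(np.argmin(sds))
        best = (i, i + min_region - 1)

    i, j = best
    # slope index k spans logr[k] .. logr[k+2]; fit over the full span
    xs, ys = logr[i : j + 3], logc[i : j + 3]
    coef = np.polyfit(xs, ys, 1)
    resid = ys - np.polyval(coef, xs)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    d2 = float(coef[0])
    ok = (not fallback) and (r2 >= r2_min)
    quality.update(reliable=bool(ok), r2=float(r2),
                   region=(float(np.exp(xs[0])), float(np.exp(xs[-1]))))
    return d2, quality


# ---------------------------------------------------------------------------
# Largest Lyapunov exponent (Rosenstein)
# ---------------------------------------------------------------------------

def _mean_period_samples(x: np.ndarray, fs: float) -> int:
    """Dominant-frequency period in samples (>= 1); used for neighbour exclusion."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    spec[0] = 0.0
    if spec.max() == 0:
        return 1
    f_dom = freqs[np.argmax(spec)]
    if f_dom <= 0:
        return 1
    # a near-DC peak would inflate the exclusion horizon past the data
    return int(np.clip(round(fs / f_dom), 1, max(1, len(x) // 10)))


def lyapunov_largest(
    traj: EmbeddedTrajectory,
    k_max: int | None = None,
    fit_fraction: float = 0.8,
    min_fit: int = 5,
) -> tuple[float, dict]:
    """Largest Lyapunov exponent by the Rosenstein method.

    For every point, the nearest neighbour outside the mean-period
    exclusion horizon is tracked for ``k_max`` steps; the mean log
    divergence curve y(k) is fit over its initial linear segment (from
    k=1 up to where y reaches ``fit_fraction`` of its rise toward
    saturation). Returns (lambda1 in nats per second of source time,
    quality dict with the fit R2 and a ``reliable`` flag).

    A noise-dominated series saturates immediately; that is flagged,
    not silently reported.
    """
    pts = traj.points
    n = pts.shape[0]
    if n < 200:
        raise ValueError("need at least 200 embedded points")
    scalar = pts[:, 0]
    period = _mean_period_samples(scalar, traj.source_fs)
    exclude = max(period, traj.theiler_window, 1)
    if k_max is None:
        k_max = min(max(3 * period, 50), n // 4)

    usable = n - k_max
    if usable <= exclude + 10:
        raise ValueError("series too short for the requested divergence horizon")
    tree = cKDTree(pts[:usable])
    # reference subset keeps the O(n_ref * k_max) tracking affordable
    n_ref = min(usable, 1500)
    ref = np.linspace(0, usable - 1, n_ref).astype(int)
    k_query = min(usable, 40)
    dist, nbr = tree.query(pts[ref], k=k_query)
    sep = np.abs(nbr - ref[:, None])
    admissible = (sep > exclude) & (dist > 0)
    first = np.argmax(admissible, axis=1)
    rows = np.arange(n_ref)
    has = admissible[rows, first]
    i_pts = ref[has]
    j_pts = nbr[has, first[has]]

    ks = np.arange(1, k_max + 1)
    y = np.empty(k_max)
    for ki, k in enumerate(ks):
        d = np.linalg.norm(pts[i_pts + k] - pts[j_pts + k], axis=1)
        good = d > 0
        y[ki] = np.mean(np.log(d[good])) if good.any() else np.nan
    y0 = np.mean(np.log(dist[rows[has], first[has]]))
    rise = np.nanmax(y) - y0
    quality: dict = {"reliable": False, "r2": np.nan, "k_fit": None, "curve": y}
    if not np.isfinite(rise) or rise <= 0:
        return 0.0, quality
    # end of the initial linear segment
    target = y0 + fit_fraction * rise
    above = np.where(y >= target)[0]
    k_fit = int(above[0]) + 1 if above.size else k_max
    k_fit = max(k_fit, min_fit)
    k_fit = min(k_fit, k_max)
    xs = ks[:k_fit] / traj.source_fs
    ys = y[:k_fit]
    coef = np.polyfit(xs, ys, 1)
    resid = ys - np.polyval(coef, xs)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    lam = float(coef[0])
    # immediate saturation: most of the rise happens within the first few steps
    saturated = (y[min(3, k_max - 1)] - y0) > 0.8 * rise
    quality.update(reliable=bool((r2 > 0.9) and not saturated), r2=float(r2), k_fit=k_fit)
    return lam, quality


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

_SAMPEN_CAP = 12.0  # reported when no template pair matches at length m+1


def sample_entropy(
    x: np.ndarray,
    m: int = 2,
    r: float = 0.2,
    max_points: int = 3000,
) -> tuple[float, bool]:
    """Sample entropy SampEn(m, r*SD) with Chebyshev distance.

    Returns (value, capped). ``capped`` is True when no matches exist at
    length m+1 and the capped sentinel is returned instead of infinity.
    Long series are strided down to ``max_points`` for the O(N^2) count.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 50:
        raise ValueError("need at least 50 samples")
    if n > max_points:
        stride = int(np.ceil(n / max_points))
        x = x[::stride]
        n = len(x)
    sd = x.std()
    if sd == 0:
        return 0.0, False
    tol = r * sd

    def _count(mm: int) -> int:
        templ = _delay_matrix(x, mm, 1)
        k = templ.shape[0]
        total = 0
        chunk = max(1, int(2e7 // (k * mm)))
        for s in range(0, k, chunk):
            e = min(s + chunk, k)
            d = np.abs(templ[s:e, None, :] - templ[None, :, :]).max(axis=-1)
            ii = np.arange(s, e)[:, None]
            jj = np.arange(k)[None, :]
            total += int(((d <= tol) & (jj > ii)).sum())
        return total

    b = _count(m)
    a = _count(m + 1)
    if b == 0:
        return _SAMPEN_CAP, True
    if a == 0:
        return _SAMPEN_CAP, True
    return float(-np.log(a / b)), False


# ---------------------------------------------------------------------------
# Spectral analysis
# ---------------------------------------------------------------------------

def spectrogram(
    x: np.ndarray,
    fs: float,
    window_ms: float = 500.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann-windowed short-time Fourier power.

    Returns (freqs_hz, times_s, power) with power shape (n_freqs, n_times).
    """
    nperseg = int(round(window_ms / 1000.0 * fs))
    if nperseg > len(x):
        raise ValueError("window longer than signal")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    hop = max(1, int(round(nperseg * (1 - overlap))))
    win = get_window("hann", nperseg)
    stft = ShortTimeFFT(win, hop=hop, fs=fs, scale_to="psd")
    S = stft.stft(np.asarray(x, dtype=float))
    power = np.abs(S) ** 2
    freqs = stft.f
    times = stft.t(len(x))
    return freqs, times, power


def band_power(x: np.ndarray, fs: float, bands: dict | None = None) -> dict[str, float]:
    """Mean Welch-periodogram power per EEG band."""
    from scipy.signal import welch

    bands = bands or BANDS
    nperseg = min(len(x), int(fs))
    f, pxx = welch(np.asarray(x, float) - np.mean(x), fs=fs, nperseg=nperseg)
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f < hi)
        out[name] = float(pxx[sel].mean()) if sel.any() else 0.0
    return out


def dominant_frequency(x: np.ndarray, fs: float, f_min: float = 1.0,
                       f_max: float | None = None) -> float:
    """Peak frequency of the Welch periodogram within [f_min, f_max]."""
    from scipy.signal import welch

    x = np.asarray(x, float) - np.mean(x)
    nperseg = min(len(x), int(4 * fs))
    f, pxx = welch(x, fs=fs, nperseg=nperseg)
    hi = f_max if f_max is not None else fs / 2
    sel = (f >= f_min) & (f <= hi)
    if not sel.any() or pxx[sel].max() == 0:
        return 0.0
    return float(f[sel][np.argmax(pxx[sel])])


# ---------------------------------------------------------------------------
# Phase-amplitude coupling
# ---------------------------------------------------------------------------

def bandpass(x: np.ndarray, fs: float, band: tuple[float, float],
             cycles: float = 3.0) -> np.ndarray:
    """Zero-phase FIR band-pass; filter length = ``cycles`` of the low edge."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} invalid for fs={fs}")
    numtaps = int(round(cycles * fs / lo))
    # cap the filter just under filtfilt's padding limit so zero-phase
    # filtering of short epochs remains possible (rolloff degrades
    # gracefully there; full-length windows keep the 3-cycle filter)
    numtaps = min(numtaps, (len(x) - 1) // 3 - 1)
    numtaps += (numtaps + 1) % 2  # odd length
    numtaps = max(numtaps, 11)
    if 3 * numtaps >= len(x):
        raise ValueError("signal too short for the requested filter order")
    taps = firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return filtfilt(taps, [1.0], np.asarray(x, dtype=float))


def pac_mvl(
    x: np.ndarray,
    fs: float,
    phase_band: tuple[float, float] = (4.0, 8.0),
    amp_band: tuple[float, float] = (30.0, 80.0),
    n_surrogates: int = 200,
    seed: int = 0,
    x_amp: np.ndarray | None = None,
) -> PACResult:
    """Phase-amplitude coupling by the Hilbert mean vector length.

    The slow band's Hilbert phase and the fast band's Hilbert amplitude
    give mvl = |<A e^{i phi}>| / <A>, normalised to [0, 1]. Significance
    comes from circular time-shift surrogates of the amplitude series
    (shift at least one phase cycle), p = (1 + #{surr >= obs}) / (1 + n).

    ``x_amp`` optionally supplies a second channel carrying the fast
    rhythm (phase still taken from ``x``).
    """
    if phase_band[1] > amp_band[0]:
        raise ValueError(f"bands overlap: {phase_band} vs {amp_band}")
    x = np.asarray(x, dtype=float)
    n = len(x)
    min_len = int(np.ceil(10 * fs / phase_band[0]))
    if n < min_len:
        raise ValueError(f"need >= 10 cycles of the phase band ({min_len} samples)")
    slow = bandpass(x, fs, phase_band)
    fast_src = x if x_amp is None else np.asarray(x_amp, dtype=float)
    fast = bandpass(fast_src, fs, amp_band)
    phase = np.angle(hilbert(slow))
    amp = np.abs(hilbert(fast))

    def _mvl(a: np.ndarray) -> float:
        denom = a.sum()
        if denom == 0:
            return 0.0
        return float(np.abs(np.sum(a * np.exp(1j * phase))) / denom)

    obs = _mvl(amp)
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        min_shift = int(fs / phase_band[0])
        shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
        null = np.array([_mvl(np.roll(amp, s)) for s in shifts])
        p = (1.0 + np.sum(null >= obs)) / (1.0 + n_surrogates)
    else:
        p = float("nan")
    return PACResult(phase_band=phase_band, amp_band=amp_band,
                     mvl=obs, surrogate_p=float(p), n_surrogates=n_surrogates)


# ---------------------------------------------------------------------------
# Convenience: the full (D2, lambda1, SampEn) battery on one channel
# ---------------------------------------------------------------------------

def chaos_metrics(
    x: np.ndarray,
    fs: float,
    m: int | None = None,
    lag: int | None = None,
) -> ChaosMetrics:
    """Embed a channel and compute the three attractor measures.

    When the automatic embedding dimension never satisfied the
    false-nearest-neighbour criterion (noise-like data has no finite
    embedding dimension), the correlation dimension is flagged
    unreliable regardless of the fit quality.
    """
    traj = embed(x, m=m, lag=lag, fs=fs)
    d2, d2q = correlation_dimension(traj)
    lam, lamq = lyapunov_largest(traj)
    ent, capped = sample_entropy(x)
    d2_ok = d2q["reliable"] and traj.auto.get("fnn_converged", True)
    return ChaosMetrics(
        d2=d2,
        lyap1=lam,
        entropy=ent,
        d2_reliable=d2_ok,
        lyap_r2=lamq["r2"],
        lyap_reliable=lamq["reliable"],
        entropy_capped=capped,
    )
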