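import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avol.analysis import (
    average_mutual_information,
    bandpass,
    chaos_metrics,
    correlation_dimension,
    dominant_frequency,
    embed,
    lyapunov_largest,
    pac_mvl,
    sample_entropy,
    spectrogram,
)
from avol.fixtures import FixtureSpec, generate_fixture


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

class TestEmbed:
    @given(st.integers(50, 400), st.integers(1, 5), st.integers(1, 10))
    @settings(max_examples=50, deadline=None)
    def test_point_count_formula(self, n, m, lag):
        if n <= (m - 1) * lag + 10:
            return
        x = np.sin(np.arange(n) * 0.3) + 0.01 * np.cos(np.arange(n) * 1.7)
        traj = embed(x, m=m, lag=lag)
        assert traj.n_points == n - (m - 1) * lag

    def test_auto_lag_matches_bruteforce_ami_minimum(self):
        """Auto lag = first local minimum of AMI, cross-checked against a
        brute-force histogram AMI computed independently here."""
        ts = generate_fixture(FixtureSpec("sine", n=4000, fs=1000.0, seed=2,
                                          params={"f": 10.0, "noise_sd": 0.2}))
        x = ts["sine"]
        traj = embed(x, fs=1000.0)

        def brute_ami(x, lag, bins=16):
            edges = np.quantile(x, np.linspace(0, 1, bins + 1))
            edges[-1] += 1e-12
            a = np.clip(np.digitize(x[:-lag], edges) - 1, 0, bins - 1)
            b = np.clip(np.digitize(x[lag:], edges) - 1, 0, bins - 1)
            joint, _, _ = np.histogram2d(a, b, bins=[np.arange(bins + 1)] * 2)
            joint /= joint.sum()
            px, py = joint.sum(1), joint.sum(0)
            nz = joint > 0
            return np.sum(joint[nz] * np.log(joint[nz] /
                                             np.outer(px, py)[nz]))

        ami = [brute_ami(x, lag) for lag in range(1, 60)]
        first_min = next(i + 1 for i in range(1, len(ami) - 1)
                         if ami[i] < ami[i - 1] and ami[i] <= ami[i + 1])
        assert abs(traj.lag - first_min) <= 2
        # sanity: a fraction of the 100-sample period, well below N/4
        assert 5 <= traj.lag <= 50

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            embed(np.ones(500))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            embed(np.sin(np.arange(30) * 0.7), m=5, lag=6)


# ---------------------------------------------------------------------------
# correlation dimension
# ---------------------------------------------------------------------------

class TestCorrelationDimension:
    def test_sine_limit_cycle_is_one_dimensional(self):
        ts = generate_fixture(FixtureSpec("sine", n=4000, fs=1000.0,
                                          params={"f": 9.7}))
        traj = embed(ts["sine"], m=2, lag=26, fs=1000.0)
        d2, q = correlation_dimension(traj)
        assert q["reliable"]
        assert d2 == pytest.approx(1.0, abs=0.1)

    def test_lorenz_matches_bruteforce_pair_count(self):
        """GP estimate vs an independent O(N^2) pair count at fixed radii
        with least-squares slope (the textbook value is ~2.05)."""
        ts = generate_fixture(FixtureSpec("lorenz", n=20000, fs=100.0))
        traj = embed(ts["x"], fs=100.0)
        d2, q = correlation_dimension(traj)
        assert q["reliable"]
        assert d2 == pytest.approx(2.05, abs=0.15)

        # independent oracle: brute-force pair count on a subsample
        pts = traj.points[::8]
        w = traj.theiler_window
        n = len(pts)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = (jj - ii) > max(1, w // 8)
        dist = d[mask]
        radii = np.geomspace(0.5, 8.0, 30)
        c = np.array([(dist <= r).mean() for r in radii])
        ok = c > 0
        slope = np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0]
        assert d2 == pytest.approx(slope, abs=0.3)

    def test_amplitude_scaling_invariance(self):
        ts = generate_fixture(FixtureSpec("lorenz", n=8000, fs=100.0))
        t1 = embed(ts["x"], m=4, lag=15, fs=100.0)
        t2 = embed(5.0 * ts["x"], m=4, lag=15, fs=100.0)
        d2a, _ = correlation_dimension(t1)
        d2b, _ = correlation_dimension(t2)
        assert abs(d2a - d2b) <= 0.05

    def test_time_reversal_invariance(self):
        ts = generate_fixture(FixtureSpec("lorenz", n=8000, fs=100.0))
        fwd = embed(ts["x"], m=4, lag=15, fs=100.0)
        rev = embed(ts["x"][::-1].copy(), m=4, lag=15, fs=100.0)
        d2f, _ = correlation_dimension(fwd)
        d2r, _ = correlation_dimension(rev)
        assert abs(d2f - d2r) <= 0.2


# ---------------------------------------------------------------------------
# Lyapunov
# ---------------------------------------------------------------------------

class TestLyapunov:
    def test_periodic_signal_non_positive(self):
        ts = generate_fixture(FixtureSpec("sine", n=4000, fs=1000.0,
                                          params={"f": 9.7}))
        traj = embed(ts["sine"], m=2, lag=26, fs=1000.0)
        lam, _ = lyapunov_largest(traj)
        assert lam <= 0.05

    def test_lorenz_matches_benettin_oracle(self):
        """Rosenstein estimate vs a two-trajectory renormalisation
        (Benettin) on the known ODE; the standard value is ~0.9/time."""
        lam_ref = _benettin_lorenz()
        assert lam_ref == pytest.approx(0.9, abs=0.15)

        ts = generate_fixture(FixtureSpec("lorenz", n=20000, fs=100.0))
        traj = embed(ts["x"], fs=100.0)
        lam, q = lyapunov_largest(traj)
        assert q["reliable"]
        assert lam == pytest.approx(lam_ref, abs=0.2)

    def test_noise_flagged_unreliable(self):
        ts = generate_fixture(FixtureSpec("white_noise", n=4000, seed=5))
        traj = embed(ts["noise"], fs=1000.0)
        _, q = lyapunov_largest(traj)
        assert not q["reliable"]


def _benettin_lorenz(d0: float = 1e-8, dt: float = 0.01, n: int = 30000) -> float:
    def f(s):
        x, y, z = s
        return np.array([10.0 * (y - x), x * (28.0 - z) - y,
                         x * y - 8.0 / 3.0 * z])

    def rk4(s, h):
        k1 = f(s)
        k2 = f(s + 0.5 * h * k1)
        k3 = f(s + 0.5 * h * k2)
        k4 = f(s + h * k3)
        return s + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    a = np.array([1.0, 1.0, 1.0])
    for _ in range(2000):  # transient
        a = rk4(a, dt)
    b = a + np.array([d0, 0.0, 0.0])
    acc = 0.0
    for _ in range(n):
        a = rk4(a, dt)
        b = rk4(b, dt)
        d = np.linalg.norm(b - a)
        acc += np.log(d / d0)
        b = a + (b - a) * (d0 / d)
    return acc / (n * dt)


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

class TestSampleEntropy:
    def test_constant_signal_zero(self):
        val, capped = sample_entropy(np.ones(600))
        assert val == 0.0 and not capped

    def test_noise_exceeds_sine(self):
        """White noise is always more entropic than a clean oscillation."""
        t = np.arange(1500) / 1000.0
        sine = np.sin(2 * np.pi * 10 * t)
        se_sine, _ = sample_entropy(sine)
        rng = np.random.default_rng(0)
        for k in range(25):
            se_noise, _ = sample_entropy(rng.normal(size=1500))
            assert se_noise > se_sine

    def test_capped_sentinel_flagged(self):
        # a strictly monotone ramp has no m+1 template matches at small r
        val, capped = sample_entropy(np.linspace(0, 1, 400), r=1e-6)
        assert capped and val > 0


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

class TestSpectral:
    def test_pure_tone_peak(self):
        t = np.arange(4000) / 1000.0
        x = np.cos(2 * np.pi * 40.0 * t)
        f, _, p = spectrogram(x, 1000.0, window_ms=500)
        peak = f[np.argmax(p.mean(axis=1))]
        assert abs(peak - 40.0) <= 2.0
        assert dominant_frequency(x, 1000.0) == pytest.approx(40.0, abs=1.0)

    def test_silence_all_zero(self):
        _, _, p = spectrogram(np.zeros(2000), 1000.0, window_ms=250)
        assert np.all(p == 0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(100), 1000.0, window_ms=500)


# ---------------------------------------------------------------------------
# phase-amplitude coupling
# ---------------------------------------------------------------------------

class TestPAC:
    def test_modulated_gamma_detected_and_matches_direct_mvl(self):
        """Burst-modulated gamma: significant coupling, and the mvl agrees
        with a direct evaluation from the known phase and envelope."""
        spec = FixtureSpec("theta_modulated_gamma", n=5000, fs=1000.0, seed=1,
                           params={"mod": "burst"})
        ts = generate_fixture(spec)
        res = pac_mvl(ts["pac"], 1000.0, (4, 8), (30, 80), seed=1)
        assert res.mvl > 0.5
        assert res.surrogate_p < 0.01

        # direct-construction oracle: a von Mises envelope exp(k cos phi)
        # has true mvl = I1(k)/I0(k); the band-limited estimate cannot
        # exceed the true locking and retains most of it
        from scipy.special import i0, i1
        kappa = 2.5
        true_mvl = i1(kappa) / i0(kappa)
        assert res.mvl <= true_mvl + 0.05
        assert res.mvl >= 0.6 * true_mvl

    def test_uncoupled_bands_not_significant(self):
        ts = generate_fixture(FixtureSpec("white_noise", n=5000, seed=7))
        res = pac_mvl(ts["noise"], 1000.0, (4, 8), (30, 80), seed=7)
        assert res.surrogate_p > 0.05

    def test_band_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pac_mvl(np.random.default_rng(0).normal(size=4000), 1000.0,
                    (4, 35), (30, 80))

    def test_mvl_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=3000)
            res = pac_mvl(x, 1000.0, (4, 8), (30, 80), n_surrogates=20, seed=0)
            assert 0.0 <= res.mvl <= 1.0

    def test_surrogate_p_uniform_under_null(self):
        """p-values from the time-shift null are ~uniform on [0,1]."""
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        ps = []
        for k in range(120):
            x = rng.normal(size=3000)
            res = pac_mvl(x, 1000.0, (4, 8), (30, 80), n_surrogates=99, seed=k)
            ps.append(res.surrogate_p)
        stat = kstest(ps, "uniform")
        assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# combined battery
# ---------------------------------------------------------------------------

def test_white_noise_raises_flags():
    ts = generate_fixture(FixtureSpec("white_noise", n=4000, seed=3))
    cm = chaos_metrics(ts["noise"], 1000.0)
    assert not cm.d2_reliable
    assert not cm.lyap_reliable


def test_bandpass_confines_power():
    rng = np.random.default_rng(0)
    x = rng.normal(size=8000)
    y = bandpass(x, 1000.0, (4.0, 8.0))
    spec = np.abs(np.fft.rfft(y))
    freqs = np.fft.rfftfreq(len(y), 1 / 1000.0)
    inband = spec[(freqs >= 4) & (freqs <= 8)].mean()
    stop = spec[(freqs > 16) | ((freqs < 2) & (freqs > 0))].mean()
    assert inband / stop > 10  # > 20 dB
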