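"""The intentional-control protocol: attentional gating, iterated
salience/expectancy competition, and the early readiness potential.

One protocol run is a sequence of fixed-duration epochs ("iterations").
Step I presents external and endogenous input to BA9, whose
correlation gate selects the processing mode: deliberate (feedback
loop engaged, the full iteration count) or arbitrary (a single
feed-forward pass). In each deliberate iteration, the ACC theta
carrier and per-assembly salience drives shape BA10's goal
competition (Step II); the winning goals drive the associated action
assemblies in BA46 under the expectancy-weighted ACC feedforward
balance (Step III); Hebbian consolidation and the salience/inhibition
re-weighting close the loop between iterations. BA10 and BA9 output
accumulates in the pre-SMA as the negative-going early readiness
potential (Step IV readout).

Across iterations, the enhanced assembly's drive rises and the
effective feed-forward inhibition grows; the tracked BA46 assembly's
reconstructed attractor collapses from a high-dimensional chaotic
state into a theta-entrained gamma oscillation, which is quantified
per iteration by correlation dimension, largest Lyapunov exponent and
sample entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .analysis import ChaosMetrics, chaos_metrics, dominant_frequency, pac_mvl
from .brain import (
    BrainModel,
    GateDecision,
    acc_ba46_feedforward,
    ba9_gate,
    carrier_signal,
    salience_compete,
)
from .network import StimulusSpec, simulate
from .timeseries import TimeSeries

__all__ = [
    "ProtocolConfig",
    "IterationRecord",
    "IterationTrace",
    "RPTrace",
    "run_protocol",
    "extract_rp",
    "classify_pathway",
]


@dataclass
class ProtocolConfig:
    """Settings of one protocol run.

    The salience schedule realises the competition dynamics: every
    assembly starts at ``salience_init`` drive; after each iteration
    the enhanced assembly's drive is multiplied by ``salience_up`` and
    the suppressed assemblies' by ``salience_down`` (clipped to
    [salience_min, salience_max]), while the effective feed-forward
    inhibition of BA10/BA46 grows by ``inhibition_step`` per iteration
    -- the stabilisation mechanism that converts chaotic activity into
    a low-dimensional oscillation.
    """

    n_iterations: int = 12
    iteration_duration: float = 2500.0  # ms
    gate_threshold: float = 0.3
    gate_window_ms: float = 500.0
    rp_smoothing: float = 600.0  # ms
    awareness_threshold: float = 1.0
    seed: int = 0
    transient_fraction: float = 0.2
    stimulus_mode: str = "correlated"  # correlated | uncorrelated | zero
    carrier_amplitude: float = 0.5
    salience_init: float = 0.7
    salience_up: float = 1.125
    salience_down: float = 0.85
    salience_min: float = 0.15
    salience_max: float = 1.9
    inhibition_step: float = 0.06
    #: BA10 -> BA46 coupling: diffuse while the goal competition is open,
    #: focused once it has resolved (irrelevant afferents are suppressed)
    ba10_coupling_early: float = 0.15
    ba10_coupling: float = 0.04
    replay_band: tuple[float, float] = (9.0, 28.0)
    learning: bool = True
    rp_w_ba10: float = 1.0
    rp_w_ba9: float = 0.5
    #: pre-SMA afferent synapses consolidate with use (saturating Hebbian);
    #: the growing projection strength is what turns sustained assembly
    #: activity into the negative-going RP build-up
    rp_w_init: float = 0.3
    rp_w_max: float = 1.0
    rp_eta: float = 0.15

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.stimulus_mode not in ("correlated", "uncorrelated", "zero"):
            raise ValueError(f"unknown stimulus_mode {self.stimulus_mode!r}")
        if self.rp_smoothing <= 0:
            raise ValueError("rp_smoothing must be positive")


@dataclass
class IterationRecord:
    """Everything measured in one iteration."""

    index: int
    metrics: ChaosMetrics
    dominant_freq_ba10: float
    dominant_freq_ba46: float
    pac_mvl: float
    salience: dict[str, float]
    multipliers: dict[str, float]
    ba46_signals: dict[str, np.ndarray]
    ba10_signals: dict[str, np.ndarray]


@dataclass
class IterationTrace:
    """Per-iteration records plus run-level context."""

    records: list[IterationRecord]
    fs: float
    gate: GateDecision | None
    mode: str  # deliberate | arbitrary
    tracked_assembly: str
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def metric_series(self, name: str) -> np.ndarray:
        return np.array([getattr(r.metrics, name) for r in self.records])


@dataclass
class RPTrace:
    """Early readiness potential: smoothed accumulated pre-SMA drive."""

    time_ms: np.ndarray
    amplitude: np.ndarray  # negative-going
    threshold_crossing: float | None
    spearman_rho: float

    def __post_init__(self) -> None:
        if self.amplitude.size and abs(self.amplitude[0]) > 1e-9:
            raise ValueError("RP must start at 0")


def extract_rp(presma_drive: TimeSeries, smoothing: float,
               awareness_threshold: float = np.inf,
               baseline: float | None = None) -> RPTrace:
    """Exponential-moving-average RP from the summed pre-SMA afferent drive.

    The drive (channel ``drive``) is referenced to ``baseline`` (default:
    its initial value), smoothed by a first-order EMA with time constant
    ``smoothing`` ms, and sign-flipped so the build-up is negative-going
    by the EEG convention. The Spearman rank correlation of amplitude vs
    time quantifies the monotone trend; a threshold crossing is reported
    at the first time |amplitude| exceeds ``awareness_threshold``.
    """
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    drive = presma_drive["drive"]
    t = presma_drive.time_ms
    dt = 1000.0 / presma_drive.fs
    if baseline is None:
        baseline = float(drive[0])
    x = drive - baseline
    alpha = 1.0 - np.exp(-dt / smoothing)
    ema = np.empty_like(x)
    ema[0] = acc = 0.0  # the build-up starts at rest
    for i in range(1, x.size):
        acc += alpha * (x[i] - acc)
        ema[i] = acc
    amplitude = -ema
    crossing = None
    above = np.flatnonzero(np.abs(amplitude) > awareness_threshold)
    if above.size:
        crossing = float(t[above[0]])
    # trend of the build-up magnitude (the negative-going convention is a
    # sign flip; the monotone statistic is about |RP| growing)
    if np.allclose(amplitude, amplitude[0]):
        rho = 0.0
    else:
        rho = float(spearmanr(t, np.abs(amplitude)).statistic)
    return RPTrace(time_ms=t, amplitude=amplitude,
                   threshold_crossing=crossing, spearman_rho=rho)


def classify_pathway(gate: GateDecision) -> str:
    """Deliberate (feedback iterations) iff the gate disinhibited BA9."""
    return "deliberate" if gate.pathway == "a_disinhibit" else "arbitrary"


def _scale_ff_inhibition(state, base_cols: np.ndarray, factor: float) -> None:
    """Set FF->E weights to ``factor`` times their built value."""
    e = state.slices["exc"]
    ff = state.slices["ff"]
    state.W[e, ff] = base_cols * factor
    state.refresh_weights()


def _interp_stim(trace: np.ndarray, fs: float, scale: float,
                 targets: np.ndarray,
                 band: tuple[float, float] | None = None) -> StimulusSpec:
    """Stimulus whose waveform replays a recorded (normalised) trace.

    ``band`` keeps only that frequency range of the replay -- the
    alpha/beta window carries the assembly-specific pattern content
    between the theta carrier (delivered separately) and the gamma
    resonance of the target loop.
    """
    trace = np.asarray(trace, dtype=float)
    if band is not None:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(3, band, btype="bandpass", fs=fs, output="sos")
        trace = sosfiltfilt(sos, trace)
    sd = trace.std()
    wave = (trace - trace.mean()) / sd * scale if sd > 0 else np.zeros_like(trace)

    def waveform(t_ms: float, _w=wave, _fs=fs) -> float:
        idx = int(t_ms * _fs / 1000.0) % _w.size  # epochs replay the trace
        return float(_w[idx])

    return StimulusSpec(target_units=targets, waveform=waveform, label="internal")


def run_protocol(brain: BrainModel, cfg: ProtocolConfig) -> tuple[IterationTrace, RPTrace]:
    """Execute Steps I-IV and measure the attractor trajectory.

    Deterministic given ``cfg.seed``. A divergent simulation aborts
    with the offending iteration index in the exception message.
    """
    fs = 1000.0
    dur = cfg.iteration_duration
    zero = cfg.stimulus_mode == "zero"
    carrier_amp = 0.0 if zero else cfg.carrier_amplitude
    n_trans = int(cfg.transient_fraction * dur * fs / 1000.0)
    assemblies = brain.assemblies
    names = sorted(assemblies)
    expectancy = {n: w for n, w in zip(names, brain.config.expectancy)}
    tracked = max(expectancy, key=expectancy.get)

    # --- endogenous baseline: ACC carrier and BA9 integration (stationary,
    # simulated once per run) -------------------------------------------
    acc = brain.areas["ACC"].copy()
    acc_ts = simulate(acc, duration=dur, seed=_seed(cfg.seed, 1), fs_out=fs)
    acc_eeg = acc_ts["eeg"]

    ext_sig, int_sig = _gate_signals(acc_eeg, fs, cfg)
    gate = None
    mode = "deliberate"
    if not zero:
        w = int(cfg.gate_window_ms * fs / 1000.0)
        gate = ba9_gate(ext_sig[:w], int_sig[:w], fs, cfg.gate_threshold)
        mode = classify_pathway(gate)

    ba9 = brain.areas["BA9"].copy()
    ba9_stims = []
    if not zero:
        ba9_stims.append(carrier_signal(acc_eeg, fs, amplitude=carrier_amp))
        ba9_stims.append(_interp_stim(ext_sig, fs, 0.3, np.arange(100)))
    ba9_ts = simulate(ba9, ba9_stims, duration=dur, seed=_seed(cfg.seed, 2), fs_out=fs)

    # --- iterated competition ------------------------------------------
    ba10 = brain.areas["BA10"].copy()
    ba46 = brain.areas["BA46"].copy()
    e10, ff10 = ba10.slices["exc"], ba10.slices["ff"]
    e46, ff46 = ba46.slices["exc"], ba46.slices["ff"]
    base10 = ba10.W[e10, ff10].copy()
    base46 = ba46.W[e46, ff46].copy()

    n_iter = cfg.n_iterations if mode == "deliberate" else 1
    salience = {n: (0.0 if zero else cfg.salience_init) for n in names}
    records: list[IterationRecord] = []
    drive_chunks: list[np.ndarray] = []
    # pre-SMA projection strengths, consolidated between epochs
    w_presma = cfg.rp_w_init
    amp_ref: float | None = None
    amp9_mean = float(np.abs(ba9_ts["eeg"] - ba9_ts["eeg"].mean()).mean())

    for k in range(1, n_iter + 1):
        inh = 1.0 + cfg.inhibition_step * (k - 1)
        _scale_ff_inhibition(ba10, base10, inh)
        _scale_ff_inhibition(ba46, base46, inh)

        # Step II: goal competition in BA10
        stims10 = []
        if carrier_amp > 0:
            stims10.append(carrier_signal(acc_eeg, fs, amplitude=carrier_amp))
        for n in names:
            lvl = salience[n]
            if lvl > 0:
                stims10.append(StimulusSpec(assemblies[n],
                                            (lambda t, v=lvl: v), "internal"))
        try:
            ts10 = simulate(ba10, stims10, duration=dur, learning=cfg.learning,
                            seed=_seed(cfg.seed, 10 + k), fs_out=fs,
                            record_groups=assemblies, learn_interval_ms=5.0)
        except RuntimeError as exc:
            raise RuntimeError(f"BA10 diverged in iteration {k}: {exc}") from exc

        # Step III: expectancy-weighted action competition in BA46
        stims46 = []
        if carrier_amp > 0:
            stims46.append(carrier_signal(acc_eeg, fs, amplitude=carrier_amp))
        e_max = expectancy[tracked]
        levels = {n: expectancy[n] / e_max * salience[n] for n in names}
        if any(v > 0 for v in levels.values()):
            exc_stim, ff_stim = acc_ba46_feedforward(assemblies, levels)
            stims46 += [exc_stim, ff_stim]
        if cfg.ba10_coupling > 0 and not zero:
            # interpolate from diffuse to focused as the winner's salience
            # approaches its ceiling
            frac = (cfg.salience_max - salience[tracked]) \
                / max(cfg.salience_max - cfg.salience_init, 1e-9)
            scale = cfg.ba10_coupling + (cfg.ba10_coupling_early - cfg.ba10_coupling) \
                * float(np.clip(frac, 0.0, 1.0))
            for n in names:
                stims46.append(_interp_stim(ts10[n], fs, scale, assemblies[n],
                                            band=cfg.replay_band))
        try:
            ts46 = simulate(ba46, stims46, duration=dur, learning=cfg.learning,
                            seed=_seed(cfg.seed, 100 + k), fs_out=fs,
                            record_groups=assemblies, learn_interval_ms=5.0)
        except RuntimeError as exc:
            raise RuntimeError(f"BA46 diverged in iteration {k}: {exc}") from exc

        # measurements on the stationary segment
        # measurements target the goal/action-related (tracked) assembly
        # signals, as in the per-pattern spectrogram convention
        sig = ts46[tracked][n_trans:]
        metrics = _metrics_or_nan(sig, fs)
        f10 = dominant_frequency(ts10[tracked][n_trans:], fs, f_min=2.0)
        f46 = dominant_frequency(sig, fs, f_min=2.0)
        # PAC and competition use the full epoch (the phase band needs
        # >= 10 slow cycles; the transient barely affects coupling).
        # Epochs too short for the coupling measure fall back to the
        # expectancy bias alone.
        if carrier_amp > 0:
            try:
                pac = pac_mvl(acc_eeg, fs, (4.0, 8.0), (30.0, 80.0),
                              n_surrogates=0, x_amp=ts46[tracked]).mvl
            except ValueError:
                pac = float("nan")
        else:
            pac = 0.0

        try:
            mult = salience_compete({n: ts10[n] for n in names},
                                    acc_eeg * (1 if carrier_amp else 0), fs,
                                    seed=_seed(cfg.seed, 200 + k),
                                    weights=expectancy)
        except ValueError:
            mult = {n: (cfg.salience_up if n == tracked else cfg.salience_down)
                    for n in names}
            if zero:
                mult = {n: 1.0 for n in names}
        records.append(IterationRecord(
            index=k, metrics=metrics, dominant_freq_ba10=f10,
            dominant_freq_ba46=f46, pac_mvl=pac,
            salience=dict(salience), multipliers=mult,
            ba46_signals={n: ts46[n] for n in names},
            ba10_signals={n: ts10[n] for n in names},
        ))

        # pre-SMA afferent drive: oscillatory output of the two direct
        # pathways, scaled by the consolidating projection strength (the
        # conscious-intention threshold is tied to the synaptic strength
        # of the pre-SMA afferents, which grow with use)
        amp10 = np.abs(ts10[tracked] - ts10[tracked].mean())
        amp9 = np.abs(ba9_ts["eeg"] - ba9_ts["eeg"].mean())
        drive_chunks.append(w_presma * (cfg.rp_w_ba10 * amp10 + cfg.rp_w_ba9 * amp9))
        a_now = float(amp10.mean()) + cfg.rp_w_ba9 * amp9_mean
        if amp_ref is None:
            amp_ref = max(a_now, 1e-9)
        if not zero:
            w_presma += cfg.rp_eta * (a_now / amp_ref) * (cfg.rp_w_max - w_presma)

        # close the loop: salience re-weighting (expectancy breaks ties);
        # without stimuli there is nothing to re-weight
        if not zero:
            for n in names:
                m = mult[n]
                if m == 1.0 and len(set(mult.values())) == 1:
                    m = cfg.salience_up if n == tracked else cfg.salience_down
                salience[n] = float(np.clip(salience[n] * m,
                                            cfg.salience_min, cfg.salience_max))

    drive = np.concatenate(drive_chunks)
    presma = TimeSeries(fs=fs, channels={"drive": drive},
                        meta={"seed": cfg.seed, "mode": mode})
    baseline = float(drive[: max(1, n_trans)].mean())
    rp = extract_rp(presma, cfg.rp_smoothing, cfg.awareness_threshold,
                    baseline=baseline)

    trace = IterationTrace(records=records, fs=fs, gate=gate, mode=mode,
                           tracked_assembly=tracked, seed=cfg.seed)
    return trace, rp


def _seed(base: int, k: int) -> int:
    return (base * 1009 + k) % (2**31 - 1)


def _gate_signals(acc_eeg: np.ndarray, fs: float,
                  cfg: ProtocolConfig) -> tuple[np.ndarray, np.ndarray]:
    """External and internal gate streams for the configured mode."""
    rng = np.random.default_rng(_seed(cfg.seed, 3))
    internal = acc_eeg
    if cfg.stimulus_mode == "uncorrelated":
        external = rng.normal(0.0, 1.0, acc_eeg.size)
    else:  # correlated (also used, unread, in zero mode)
        external = acc_eeg + 0.3 * acc_eeg.std() * rng.normal(0.0, 1.0, acc_eeg.size)
    return external, internal


def _metrics_or_nan(sig: np.ndarray, fs: float) -> ChaosMetrics:
    try:
        return chaos_metrics(sig, fs)
    except ValueError:
        return ChaosMetrics(d2=float("nan"), lyap1=float("nan"),
                            entropy=float("nan"), d2_reliable=False,
                            lyap_reliable=False)
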