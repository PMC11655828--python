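"""Five-area circuit of intentional control: ACC, BA9, BA10, BA46, pre-SMA.

The anterior cingulate cortex (ACC) is the source of endogenous
signals: a theta-band "carrier" conveying interoceptive information, a
"salience" bias over goal assemblies in BA10, and an expectancy-scaled
feedforward drive onto BA46 that contacts the excitatory AND the
feed-forward inhibitory layer simultaneously (the balance that moves
BA46 into the gamma band). BA9 integrates external with endogenous
input and gates the processing mode: correlated streams open the
deliberate (feedback-looped) pathway by disinhibiting BA9 pyramidal
cells, uncorrelated streams close it by driving feed-forward
inhibition. The pre-SMA is a passive accumulator of BA10/BA9 output
whose smoothed, negative-going build-up is the model's early readiness
potential.

ACC and BA9 use theta-dominant area parameters (weak fast-inhibition
loop, slow feedback inhibition); BA10 and BA46 carry a strong fast
E<->FF loop whose drive level moves them from low-frequency activity
into ~45 Hz gamma. Goal/action assemblies are vertical strips of the
excitatory grid, giving each assembly its own local E<->FF loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import bandpass, pac_mvl
from .network import AreaParams, NetworkState, StimulusSpec, build_area, step
from .timeseries import TimeSeries

__all__ = [
    "AREAS",
    "Projection",
    "GateDecision",
    "BrainConfig",
    "BrainModel",
    "theta_area_params",
    "gamma_area_params",
    "assembly_indices",
    "build_brain",
    "train_assemblies",
    "ba9_gate",
    "carrier_signal",
    "salience_compete",
    "acc_ba46_feedforward",
    "simulate_brain",
]

AREAS = ("ACC", "BA9", "BA10", "BA46", "preSMA")

#: layers a long-range projection may terminate on (never FB-inhibitory,
#: so no cross-area I->I coupling can arise)
_ALLOWED_TARGET_LAYERS = ("excitatory", "ff_inhibitory")


@dataclass(frozen=True)
class Projection:
    """One long-range excitatory pathway between areas.

    Long-range axons are excitatory; inhibition is only ever exerted
    through the target area's local interneurons, which is why
    ``target_layer`` may name the FF-inhibitory layer but never the
    FB-inhibitory one.
    """

    source: str
    target: str
    target_layer: str = "excitatory"
    weight_scale: float = 0.1
    delay: float = 5.0  # ms

    def __post_init__(self) -> None:
        if self.source not in AREAS or self.target not in AREAS:
            raise ValueError(f"unknown area in projection {self.source}->{self.target}")
        if self.target_layer not in _ALLOWED_TARGET_LAYERS:
            raise ValueError(
                f"projection may not terminate on layer {self.target_layer!r}"
            )
        if self.weight_scale < 0:
            raise ValueError("weight_scale must be >= 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass(frozen=True)
class GateDecision:
    """Outcome of the BA9 correlation gate."""

    correlation: float
    threshold: float
    pathway: str  # 'a_disinhibit' | 'b_suppress'

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.correlation <= 1.0 + 1e-9:
            raise ValueError("correlation outside [-1, 1]")
        if self.pathway not in ("a_disinhibit", "b_suppress"):
            raise ValueError(f"unknown pathway {self.pathway!r}")


def theta_area_params(**over) -> AreaParams:
    """Parameters of a theta-dominant area (ACC, BA9): slow feedback
    inhibition paces a ~4-8 Hz relaxation oscillation; the fast
    feed-forward loop is disengaged."""
    base = dict(
        tau_fb=100.0, w_ei_fb=0.00015, w_ei_ff=0.0, w_ie_ff=0.0,
        tonic_drive=0.7, noise_sd=0.03,
    )
    base.update(over)
    return AreaParams(**base)


def gamma_area_params(**over) -> AreaParams:
    """Parameters of a gamma-capable area (BA10, BA46): the delayed
    E<->FF loop crosses into ~45 Hz gamma once the excitatory drive to
    an assembly exceeds roughly 1.5 potential units/ms."""
    base = dict(
        tau_fb=100.0, w_ei_fb=0.00015, w_ei_ff=0.018, w_ie_ff=0.15,
        tonic_drive=1.0, noise_sd=0.0225, eta=1e-6,
    )
    base.update(over)
    return AreaParams(**base)


def assembly_indices(n_assemblies: int = 3, width: int = 3, n_exc: int = 100,
                     side: int = 10) -> dict[str, np.ndarray]:
    """Vertical-strip assemblies on the excitatory grid.

    Assembly k occupies columns [k*width, (k+1)*width); remaining
    columns are unassigned background.
    """
    if n_assemblies * width > side:
        raise ValueError("assemblies exceed the grid width")
    out = {}
    for k in range(n_assemblies):
        cols = set(range(k * width, (k + 1) * width))
        out[f"A{k}"] = np.array([i for i in range(n_exc) if i % side in cols])
    return out


@dataclass
class BrainConfig:
    """Complete wiring + protocol-independent parameters of the circuit."""

    #: the five regions of the circuit; all must be present
    areas: tuple[str, ...] = AREAS
    n_assemblies: int = 3
    assembly_width: int = 3
    gate_threshold: float = 0.3
    gate_window_ms: float = 500.0
    carrier_band: tuple[float, float] = (4.0, 8.0)
    #: exogenous expectancy weights per assembly (OFC is outside the model)
    expectancy: tuple[float, ...] = (1.0, 0.6, 0.4)
    seed: int = 0
    dt: float = 0.1
    area_params: dict = field(default_factory=dict)  # per-area AreaParams overrides
    projections: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.expectancy) != self.n_assemblies:
            raise ValueError("expectancy must have one weight per assembly")
        if not self.projections:
            self.projections = default_projections()


def default_projections() -> list[Projection]:
    """The pathway set of the circuit diagram: ACC to all three LPFC
    subregions, bidirectional LPFC coupling, both pre-SMA afferents,
    and the ACC feedforward-inhibition branch onto BA46."""
    return [
        Projection("ACC", "BA9", "excitatory", 0.5, 5.0),
        Projection("ACC", "BA10", "excitatory", 0.5, 5.0),
        Projection("ACC", "BA46", "excitatory", 0.3, 5.0),
        Projection("ACC", "BA46", "ff_inhibitory", 0.3, 5.0),
        Projection("BA9", "BA10", "excitatory", 0.1, 3.0),
        Projection("BA10", "BA9", "excitatory", 0.1, 3.0),
        Projection("BA10", "BA46", "excitatory", 0.2, 3.0),
        Projection("BA46", "BA10", "excitatory", 0.1, 3.0),
        Projection("BA9", "BA46", "excitatory", 0.05, 3.0),
        Projection("BA46", "BA9", "excitatory", 0.05, 3.0),
        Projection("BA10", "preSMA", "excitatory", 1.0, 5.0),
        Projection("BA9", "preSMA", "excitatory", 0.5, 5.0),
    ]


@dataclass
class BrainModel:
    """Built circuit: four simulated areas, a passive pre-SMA, projections."""

    config: BrainConfig
    areas: dict[str, NetworkState]
    projections: list[Projection]
    assemblies: dict[str, np.ndarray]

    def area_params(self, name: str) -> AreaParams:
        return self.areas[name].params


def build_brain(config: BrainConfig | None = None, seed: int | None = None) -> BrainModel:
    """Wire the five-area circuit; deterministic given the seed.

    Raises on a configuration that omits one of the five areas or wires
    a projection onto a forbidden layer.
    """
    config = config or BrainConfig()
    seed = config.seed if seed is None else seed
    missing_areas = set(AREAS) - set(config.areas)
    if missing_areas:
        raise ValueError(f"configuration omits required areas: {sorted(missing_areas)}")
    param_map = {
        "ACC": theta_area_params(),
        "BA9": theta_area_params(),
        # BA10's excitation arrives as the per-assembly salience drive;
        # a high tonic floor would push all assemblies into gamma at once
        "BA10": gamma_area_params(tonic_drive=0.55),
        "BA46": gamma_area_params(),
    }
    for name, override in config.area_params.items():
        if name == "preSMA":
            continue
        if name not in param_map:
            raise ValueError(f"unknown area {name!r} in area_params")
        param_map[name] = override if isinstance(override, AreaParams) \
            else replace(param_map[name], **override)

    needed = {p.source for p in config.projections} | {p.target for p in config.projections}
    missing = (set(AREAS) - {"preSMA"}) - set(param_map)
    if missing:
        raise ValueError(f"missing areas: {sorted(missing)}")
    unknown = needed - set(AREAS)
    if unknown:
        raise ValueError(f"projections reference unknown areas: {sorted(unknown)}")

    max_delay = max((p.delay for p in config.projections), default=0.0)
    areas = {
        name: build_area(params, seed=seed + i, dt=config.dt, history_ms=max_delay)
        for i, (name, params) in enumerate(sorted(param_map.items()))
    }
    assemblies = assembly_indices(config.n_assemblies, config.assembly_width)
    return BrainModel(config=config, areas=areas,
                      projections=list(config.projections), assemblies=assemblies)


def train_assemblies(brain: BrainModel, areas: tuple[str, ...] = ("BA10", "BA46"),
                     duration_ms: float = 300.0, drive: float = 1.5,
                     eta: float = 1e-4, seed: int = 0) -> BrainModel:
    """Load long-term memories: consolidate within-assembly coupling.

    Each assembly of the named areas is stimulated in isolation while
    Hebbian learning runs, strengthening its internal excitatory
    synapses (toward w_max) relative to cross-assembly ones. The built
    connectivity already supports assembly competition; this optional
    pass deepens the stored patterns. Mutates the brain's area states.
    """
    from .network import simulate as _simulate

    for name in areas:
        state = brain.areas[name]
        for k, (_aname, idx) in enumerate(sorted(brain.assemblies.items())):
            stim = StimulusSpec(idx, (lambda t, v=drive: v), "internal")
            _simulate(state, [stim], duration=duration_ms, learning=True,
                      seed=(seed * 131 + k) % (2**31 - 1),
                      learn_interval_ms=5.0, eta=eta)
            # restore quiescence between patterns
            state.u[:] = 0.0
    return brain


# ---------------------------------------------------------------------------
# BA9 gate
# ---------------------------------------------------------------------------

def ba9_gate(external: np.ndarray, internal: np.ndarray, fs: float,
             threshold: float = 0.3,
             band: tuple[float, float] = (4.0, 8.0)) -> GateDecision:
    """Decide the processing pathway from external/internal correlation.

    Both signals are band-limited to the carrier band (a light
    zero-phase Butterworth, usable on the short 500 ms gate window),
    their Hilbert envelopes Pearson-correlated over the window.
    Correlation at or above the threshold opens pathway (a): net
    disinhibition of BA9 pyramidal cells (the ACC->CR->CB chain
    collapsed to its positive net effect). Below threshold, pathway
    (b): direct drive of the inhibitory interneurons, suppressing the
    external stream. The boundary case resolves to (a).
    """
    from scipy.signal import butter, hilbert, sosfiltfilt

    external = np.asarray(external, dtype=float)
    internal = np.asarray(internal, dtype=float)
    if external.shape != internal.shape:
        raise ValueError("gate windows must have equal length")
    if np.std(external) == 0 or np.std(internal) == 0:
        raise ValueError("zero-variance input: gate correlation undefined")
    sos = butter(3, band, btype="bandpass", fs=fs, output="sos")
    env_e = np.abs(hilbert(sosfiltfilt(sos, external)))
    env_i = np.abs(hilbert(sosfiltfilt(sos, internal)))
    if np.std(env_e) == 0 or np.std(env_i) == 0:
        raise ValueError("zero-variance envelope: gate correlation undefined")
    r = float(np.corrcoef(env_e, env_i)[0, 1])
    pathway = "a_disinhibit" if r >= threshold else "b_suppress"
    return GateDecision(correlation=r, threshold=threshold, pathway=pathway)


# ---------------------------------------------------------------------------
# Carrier signal
# ---------------------------------------------------------------------------

def carrier_signal(acc_eeg: np.ndarray, fs: float,
                   band: tuple[float, float] = (4.0, 8.0),
                   amplitude: float = 0.5,
                   target_units: np.ndarray | None = None) -> StimulusSpec:
    """Package the theta-band ACC output as an internal stimulus.

    The ACC readout is band-passed to the carrier band and normalised
    to a constant envelope (divided by its Hilbert envelope): the
    carrier conveys the endogenous theta PHASE, at a fixed drive
    amplitude ``amplitude``. Without this normalisation the waxing and
    waning of the theta envelope would modulate the downstream drive by
    a factor of ~3 and dominate the competition. The waveform indexes
    the trace by time, so the stimulus can drive a downstream epoch of
    the same duration.
    """
    from scipy.signal import hilbert

    acc_eeg = np.asarray(acc_eeg, dtype=float)
    lo = band[0]
    min_len = int(np.ceil(3 * fs / lo))
    if acc_eeg.size < min_len:
        raise ValueError(
            f"window shorter than 3 cycles of {lo} Hz ({min_len} samples needed)"
        )
    filt = bandpass(acc_eeg, fs, band)
    env = np.abs(hilbert(filt))
    if env.max() == 0:
        wave = filt
    else:
        env = np.maximum(env, 0.1 * np.median(env[env > 0]) if (env > 0).any() else 1.0)
        wave = filt / env * amplitude
    if target_units is None:
        target_units = np.arange(100)

    def waveform(t_ms: float, _w=wave, _fs=fs) -> float:
        # wrap: a persistent area's clock keeps running across epochs,
        # and each epoch replays the same endogenous carrier
        idx = int(t_ms * _fs / 1000.0) % _w.size
        return float(_w[idx])

    return StimulusSpec(target_units=target_units, waveform=waveform,
                        label="internal")


# ---------------------------------------------------------------------------
# Salience competition
# ---------------------------------------------------------------------------

def salience_compete(
    assembly_signals: dict[str, np.ndarray],
    carrier: np.ndarray,
    fs: float,
    phase_band: tuple[float, float] = (4.0, 8.0),
    amp_band: tuple[float, float] = (30.0, 80.0),
    up: float = 1.12,
    down: float = 0.88,
    seed: int = 0,
    weights: dict[str, float] | None = None,
    min_coupling: float = 0.12,
) -> dict[str, float]:
    """Gain multipliers from carrier-phase / assembly-gamma coupling.

    Each assembly's theta-gamma coupling to the carrier is measured by
    the mean vector length (carrier supplies the phase, the assembly
    signal the amplitude), optionally scaled by an exogenous relevance
    weight (the expectancy bias the salience signal conveys).
    The best-coupled assembly is enhanced (multiplier ``up`` > 1), all
    others suppressed (``down`` < 1): the relevant pattern is enhanced
    and the irrelevant ones suppressed. A silent carrier or
    indistinguishable couplings leave every multiplier at 1.
    """
    if not assembly_signals:
        raise ValueError("no assemblies to compete")
    if np.std(carrier) == 0:
        return {name: 1.0 for name in assembly_signals}
    scores = {}
    for name, sig in assembly_signals.items():
        res = pac_mvl(carrier, fs, phase_band, amp_band,
                      n_surrogates=0, seed=seed, x_amp=np.asarray(sig, float))
        scores[name] = res.mvl * (weights.get(name, 1.0) if weights else 1.0)
    vals = np.array(list(scores.values()))
    if np.allclose(vals, vals[0], atol=1e-12):
        return {name: 1.0 for name in assembly_signals}
    raw_max = max(s / (weights.get(n, 1.0) if weights else 1.0)
                  for n, s in scores.items())
    if raw_max < min_coupling:
        # couplings below the noise floor carry no information; the
        # expectancy bias decides (goal-directedness), or nothing does
        if not weights:
            return {name: 1.0 for name in assembly_signals}
        best = max(scores, key=lambda n: weights.get(n, 1.0))
    else:
        best = max(scores, key=scores.get)
    return {name: (up if name == best else down) for name in scores}


# ---------------------------------------------------------------------------
# ACC -> BA46 feedforward drive
# ---------------------------------------------------------------------------

def acc_ba46_feedforward(
    assemblies: dict[str, np.ndarray],
    levels: dict[str, float],
    ff_fraction: float = 0.08,
    n_exc: int = 100,
    n_ff: int = 25,
) -> tuple[StimulusSpec, StimulusSpec]:
    """Simultaneous excitatory + FF-inhibitory drive onto BA46.

    ``levels`` gives each assembly's drive amplitude (potential
    units/ms), typically expectancy weight x current salience. The
    FF-inhibitory layer receives ``ff_fraction`` of the mean excitatory
    drive uniformly -- the excitation/inhibition balance that keeps
    strong drive oscillating in the gamma band rather than saturating.
    Zero levels everywhere yield identically zero stimuli.
    """
    if set(levels) != set(assemblies):
        raise ValueError("levels must name exactly the assemblies")
    drive_e = np.zeros(n_exc)
    for name, idx in assemblies.items():
        drive_e[idx] = levels[name]

    exc_stim = StimulusSpec(
        target_units=np.arange(n_exc),
        waveform=lambda t, d=drive_e: d,
        label="internal",
    )
    ff_level = ff_fraction * float(drive_e.mean())
    ff_stim = StimulusSpec(
        target_units=np.arange(n_ff),
        waveform=lambda t, v=ff_level: v,
        label="internal",
        layer="ff_inhibitory",
    )
    return exc_stim, ff_stim


# ---------------------------------------------------------------------------
# Fully coupled multi-area simulation
# ---------------------------------------------------------------------------

def simulate_brain(
    brain: BrainModel,
    duration: float,
    stimuli: dict[str, list[StimulusSpec]] | None = None,
    seed: int = 0,
    fs_out: float = 1000.0,
) -> dict[str, TimeSeries]:
    """Step all four simulated areas together with projection coupling.

    Projections deliver the source area's delayed excitatory-layer mean
    gain, scaled by ``weight_scale``, onto the target layer (uniformly).
    The pre-SMA channel is the accumulated afferent drive from its two
    projections. Returns one TimeSeries per area.
    """
    cfg = brain.config
    dt = cfg.dt
    stimuli = stimuli or {}
    rngs = {name: np.random.default_rng((seed, i))
            for i, name in enumerate(sorted(brain.areas))}
    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(1000.0 / (fs_out * dt))))
    n_rec = n_steps // rec_every
    rec = {name: np.empty(n_rec) for name in brain.areas}
    rec["preSMA"] = np.empty(n_rec)
    presma_drive = 0.0

    sim_projs = []
    for p in brain.projections:
        lag = int(round(p.delay / dt))
        sim_projs.append((p, lag))

    k = 0
    for i in range(n_steps):
        inputs: dict[str, np.ndarray] = {}
        presma_step = 0.0
        for p, lag in sim_projs:
            src = brain.areas[p.source]
            g_src = src.delayed_gain(lag)
            e = src.slices["exc"]
            val = p.weight_scale * float(g_src[e].mean())
            if p.target == "preSMA":
                presma_step += val
                continue
            tgt = brain.areas[p.target]
            vec = inputs.setdefault(p.target, np.zeros(tgt.params.n_total))
            layer = "exc" if p.target_layer == "excitatory" else "ff"
            vec[tgt.slices[layer]] += val
        presma_drive = presma_step
        for name in sorted(brain.areas):
            st = brain.areas[name]
            step(st, stimuli.get(name, []), dt, rngs[name],
                 external_input=inputs.get(name))
        if (i + 1) % rec_every == 0 and k < n_rec:
            for name, st in brain.areas.items():
                rec[name][k] = st.u[st.slices["exc"]].mean()
            rec["preSMA"][k] = presma_drive
            k += 1

    meta = {"seed": seed, "dt": dt, "duration_ms": duration}
    return {name: TimeSeries(fs=fs_out, channels={"eeg": rec[name][:k]}, meta=dict(meta))
            for name in rec}
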