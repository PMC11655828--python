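"""Single cortical area: three-layer attractor network with delay ODEs.

One area lumps a six-layer cortical column into three layers: a 10x10
grid of excitatory units (pyramidal-cell populations) flanked by a 5x5
layer of fast feed-forward inhibitory units and a 5x5 layer of slow
feedback inhibitory units. Units are non-spiking; the state variable is
the mean membrane potential u_i, evolving as

    du_i/dt = -u_i / tau_i + sum_j w_ij g_j(u_j(t - delta_ij)) + I_i(t) + xi(t)

with the Freeman sigmoid gain g(u) = C Q (1 - exp(-exp(u)/Q)), additive
Gaussian white noise xi, and conduction delays delta_ij held in a ring
buffer of past gain values. Connectivity: extensive distance-decaying
E->E coupling, local E<->I coupling, no I->I connections, and afferent
input only onto the excitatory layer. Excitatory-source weights are
plastic under a saturating Hebbian rule

    dw_ij = eta * g_i(u_i(t)) * g_j(u_j(t - delta_ij)) * (w_max - w_ij).

Integration is explicit Euler-Maruyama at fixed dt; all delays must be
integer multiples of dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "GainParams",
    "AreaParams",
    "StimulusSpec",
    "NetworkState",
    "gain",
    "build_area",
    "step",
    "hebbian_update",
    "simulate",
]


@dataclass(frozen=True)
class GainParams:
    """Freeman gain parameters: arousal/excitability Q and scale C."""

    Q: float = 1.0
    C: float = 1.0

    def __post_init__(self) -> None:
        if not (self.Q > 0 and self.C > 0):
            raise ValueError(f"Q and C must be positive, got Q={self.Q}, C={self.C}")


def gain(u, p: GainParams):
    """Freeman input-output gain g(u) = C*Q*(1 - exp(-exp(u)/Q)).

    Strictly increasing in u, bounded in (0, C*Q). Accepts scalars or
    arrays; non-finite input raises.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite membrane potential passed to gain()")
    return p.C * p.Q * (-np.expm1(-np.exp(u) / p.Q))


@dataclass(frozen=True)
class AreaParams:
    """Parameters of one three-layer area.

    Time constants and delays are in ms; noise_sd is in potential units
    per sqrt(ms). ``w_*`` are weight scales for each connection class;
    ``lambda_ee`` is the E->E distance-decay length and ``radius_local``
    the E<->I neighbourhood radius, both in grid units (the excitatory
    grid has unit spacing). ``delay_*`` must be integer multiples of the
    integration step at build/integration time.
    """

    n_exc: int = 100
    n_ff_inh: int = 25
    n_fb_inh: int = 25
    tau_exc: float = 10.0
    tau_ff: float = 5.0
    tau_fb: float = 80.0
    gain_exc: GainParams = field(default_factory=lambda: GainParams(5.0, 1.0))
    gain_ff: GainParams = field(default_factory=lambda: GainParams(5.0, 1.0))
    gain_fb: GainParams = field(default_factory=lambda: GainParams(5.0, 1.0))
    noise_sd: float = 0.05
    # connection-class weight scales (signs applied internally).
    # The slow feedback integrator (tau_fb) multiplies its input by
    # tau_fb, so w_ei_fb must be small to keep u_fb in the sensitive
    # range of the gain; the defaults put the area in a theta-band
    # relaxation oscillation under tonic drive.
    w_ee: float = 0.008
    w_ei_ff: float = 0.012   # E -> feed-forward inhibitory
    w_ei_fb: float = 0.0002  # E -> feedback inhibitory
    w_ie_ff: float = 0.15    # FF inhibitory -> E (applied negative)
    w_ie_fb: float = 0.07    # FB inhibitory -> E (applied negative)
    lambda_ee: float = 2.0
    radius_local: float = 3.0
    weight_jitter: float = 0.1
    # tonic arousal drive to the excitatory layer (potential units / ms)
    tonic_drive: float = 1.0
    # conduction delays per connection class (ms)
    delay_ee: float = 1.0
    delay_ei: float = 1.5
    delay_ie: float = 1.5
    w_max: float = 0.02
    eta: float = 0.0

    def __post_init__(self) -> None:
        if min(self.tau_exc, self.tau_ff, self.tau_fb) <= 0:
            raise ValueError("membrane time constants must be positive")
        if min(self.delay_ee, self.delay_ei, self.delay_ie) < 0:
            raise ValueError("delays must be non-negative")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if not 0 <= self.eta <= 1:
            raise ValueError("eta must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for s in (self.n_exc, self.n_ff_inh, self.n_fb_inh):
            if s < 1:
                raise ValueError("population sizes must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_ff_inh + self.n_fb_inh


@dataclass
class StimulusSpec:
    """Afferent drive onto one layer of an area.

    ``waveform`` maps time (ms) to drive (potential units / ms); it may
    return a scalar (same drive to every target) or an array over
    ``target_units``. ``target_units`` index within the addressed layer.
    External (sensory) afferents contact only the excitatory layer;
    internal long-range drives may additionally contact the
    feed-forward inhibitory layer (that is how feedforward inhibition
    between areas is exerted), never the feedback layer.
    """

    target_units: np.ndarray
    waveform: object  # callable t_ms -> float | ndarray
    label: str = "external"
    onset: float = 0.0
    offset: float = float("inf")
    layer: str = "excitatory"

    def __post_init__(self) -> None:
        self.target_units = np.atleast_1d(np.asarray(self.target_units, dtype=int))
        if self.label not in ("external", "internal"):
            raise ValueError("label must be 'external' or 'internal'")
        if self.offset < self.onset:
            raise ValueError("offset before onset")
        if self.layer not in ("excitatory", "ff_inhibitory"):
            raise ValueError("stimuli may target 'excitatory' or 'ff_inhibitory' only")
        if self.label == "external" and self.layer != "excitatory":
            raise ValueError("external afferents contact only the excitatory layer")

    def drive_at(self, t_ms: float, n_layer: int) -> np.ndarray | None:
        if not (self.onset <= t_ms < self.offset):
            return None
        if np.any(self.target_units >= n_layer) or np.any(self.target_units < 0):
            raise ValueError("stimulus targets outside the addressed layer")
        v = self.waveform(t_ms)
        out = np.zeros(n_layer)
        out[self.target_units] = v
        return out


class NetworkState:
    """Evolving state of one area: potentials, weights, gain history.

    Unit ordering: excitatory [0, n_exc), feed-forward inhibitory,
    feedback inhibitory. ``W[i, j]`` is the weight of the connection
    j -> i (inhibitory sources carry negative weights); ``delay_steps``
    holds the per-connection conduction delay in integration steps and
    ``history`` the ring buffer of past gain values g_j(u_j).
    """

    def __init__(self, params: AreaParams, W: np.ndarray, delay_steps: np.ndarray,
                 dt: float, seed: int, min_history_steps: int = 0):
        self.params = params
        self.W = W
        self.delay_steps = delay_steps
        self.dt = dt
        self.seed = seed
        n = params.n_total
        self.t = 0.0
        self.u = np.zeros(n)
        self.max_lag = max(int(delay_steps.max()), int(min_history_steps))
        self.history = np.zeros((self.max_lag + 1, n))
        self._head = 0  # row holding g at current time
        self._rebuild_delay_groups()
        self._gain_vec = np.empty(n)
        sl = self.slices
        self._gain_params = [
            (sl["exc"], params.gain_exc),
            (sl["ff"], params.gain_ff),
            (sl["fb"], params.gain_fb),
        ]
        # per-population leak and noise vectors
        self.tau = np.empty(n)
        self.tau[sl["exc"]] = params.tau_exc
        self.tau[sl["ff"]] = params.tau_ff
        self.tau[sl["fb"]] = params.tau_fb
        # plastic connections: E -> E structural links. Learning serves
        # assembly formation among pyramidal populations; E -> I scales
        # are treated as fixed cytoarchitectural parameters so that the
        # interneuron operating points stay calibrated.
        self.plastic = np.zeros_like(W, dtype=bool)
        self.plastic[sl["exc"], sl["exc"]] = W[sl["exc"], sl["exc"]] > 0
        # external gain modulation of the excitatory drive (salience control)
        self.exc_drive_gain = 1.0
        self.inh_gain = 1.0

    @property
    def slices(self) -> dict:
        p = self.params
        return {
            "exc": slice(0, p.n_exc),
            "ff": slice(p.n_exc, p.n_exc + p.n_ff_inh),
            "fb": slice(p.n_exc + p.n_ff_inh, p.n_total),
        }

    def _rebuild_delay_groups(self) -> None:
        self._lags = np.unique(self.delay_steps[self.W != 0]) if np.any(self.W) else np.array([0])
        self._W_by_lag = []
        for lag in self._lags:
            Wl = np.where(self.delay_steps == lag, self.W, 0.0)
            self._W_by_lag.append(Wl)

    def refresh_weights(self) -> None:
        """Re-split W by delay after any weight change."""
        self._rebuild_delay_groups()

    def compute_gain(self, u: np.ndarray | None = None) -> np.ndarray:
        u = self.u if u is None else u
        g = self._gain_vec
        for sl, gp in self._gain_params:
            g[sl] = gain(u[sl], gp)
        return g

    def delayed_gain(self, lag: int) -> np.ndarray:
        """g(u(t - lag*dt)) from the ring buffer."""
        if lag > self.max_lag:
            raise ValueError("requested lag exceeds history depth")
        return self.history[(self._head - lag) % (self.max_lag + 1)]

    def push_gain(self, g: np.ndarray) -> None:
        self._head = (self._head + 1) % (self.max_lag + 1)
        self.history[self._head] = g

    def copy(self) -> "NetworkState":
        new = NetworkState.__new__(NetworkState)
        new.__dict__.update({k: (v.copy() if isinstance(v, np.ndarray) else v)
                             for k, v in self.__dict__.items()
                             if k not in ("_W_by_lag", "_lags", "_gain_params")})
        new._gain_params = [(sl, gp) for sl, gp in self._gain_params]
        new._rebuild_delay_groups()
        return new


def _grid_coords(n: int, spacing: float) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack([xs.ravel(), ys.ravel()])[:n].astype(float)
    pts *= spacing
    # centre every layer on the same footprint
    pts -= pts.mean(axis=0)
    return pts


def _steps(delay_ms: float, dt: float) -> int:
    steps = delay_ms / dt
    rounded = round(steps)
    if abs(steps - rounded) > 1e-9:
        raise ValueError(f"delay {delay_ms} ms is not an integer multiple of dt={dt} ms")
    return int(rounded)


def build_area(params: AreaParams, seed: int, dt: float = 0.1,
               history_ms: float = 0.0) -> NetworkState:
    """Construct a three-layer area with its structural connectivity.

    Deterministic given ``seed`` (weight jitter is the only randomness).
    ``history_ms`` deepens the gain ring buffer beyond the area's own
    delays so longer inter-area conduction delays can be served.
    Raises at setup if any configured delay is not an integer multiple
    of ``dt``.
    """
    rng = np.random.default_rng(seed)
    p = params
    n = p.n_total
    e = slice(0, p.n_exc)
    ff = slice(p.n_exc, p.n_exc + p.n_ff_inh)
    fb = slice(p.n_exc + p.n_ff_inh, n)

    # common footprint: E grid has unit spacing, inhibitory grids are coarser
    pos = np.zeros((n, 2))
    pos[e] = _grid_coords(p.n_exc, 1.0)
    side_e = int(np.ceil(np.sqrt(p.n_exc)))
    side_i = int(np.ceil(np.sqrt(p.n_ff_inh)))
    spacing_i = side_e / side_i
    pos[ff] = _grid_coords(p.n_ff_inh, spacing_i)
    pos[fb] = _grid_coords(p.n_fb_inh, spacing_i)

    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)

    W = np.zeros((n, n))
    # E -> E: extensive, distance-decaying, no self-connection
    W[e, e] = p.w_ee * np.exp(-d[e, e] / p.lambda_ee)
    np.fill_diagonal(W[e, e], 0.0)
    # E <-> I: local neighbourhood
    local = d <= p.radius_local
    W[ff, e] = np.where(local[ff, e], p.w_ei_ff, 0.0)
    W[fb, e] = np.where(local[fb, e], p.w_ei_fb, 0.0)
    W[e, ff] = np.where(local[e, ff], -p.w_ie_ff, 0.0)
    W[e, fb] = np.where(local[e, fb], -p.w_ie_fb, 0.0)
    # no I -> I (left zero by construction)

    if p.weight_jitter > 0:
        jitter = 1.0 + p.weight_jitter * rng.standard_normal(W.shape)
        W *= np.clip(jitter, 0.0, None)
    # plastic (excitatory-source) weights start inside [0, w_max]
    W[:, e] = np.clip(W[:, e], 0.0, p.w_max)

    delay_steps = np.zeros((n, n), dtype=np.int64)
    delay_steps[e, e] = _steps(p.delay_ee, dt)
    for tgt, src in ((ff, e), (fb, e)):
        delay_steps[tgt, src] = _steps(p.delay_ei, dt)
    for tgt, src in ((e, ff), (e, fb)):
        delay_steps[tgt, src] = _steps(p.delay_ie, dt)

    return NetworkState(params=p, W=W, delay_steps=delay_steps, dt=dt, seed=seed,
                        min_history_steps=_steps(history_ms, dt) if history_ms else 0)


def step(state: NetworkState, stimuli: list[StimulusSpec], dt: float,
         rng: np.random.Generator | None = None,
         external_input: np.ndarray | None = None,
         noise_row: np.ndarray | None = None) -> NetworkState:
    """Advance the area by one Euler-Maruyama step of the delay ODE.

    ``external_input`` optionally adds a precomputed drive vector over
    all units (inter-area projections, or stimulus drive pre-sampled on
    the step grid); ``noise_row`` supplies pre-drawn standard normals
    for this step (drawn from ``rng`` otherwise). Mutates ``state`` in
    place and returns it.

    Raises RuntimeError naming the first offending unit if any potential
    turns non-finite.
    """
    p = state.params
    if abs(dt - state.dt) > 1e-12:
        raise ValueError("dt differs from the dt the area was built with")
    u = state.u
    # recurrent drive from delayed gains
    drive = np.zeros_like(u)
    for lag, Wl in zip(state._lags, state._W_by_lag):
        drive += Wl @ state.delayed_gain(int(lag))
    e = state.slices["exc"]
    if state.exc_drive_gain != 1.0:
        drive[e] *= state.exc_drive_gain
    if state.inh_gain != 1.0:
        neg = drive[e] < 0
        # inhibitory modulation acts on the net inhibitory component
        drive_e = drive[e]
        drive_e[neg] *= state.inh_gain
        drive[e] = drive_e
    if p.tonic_drive != 0.0:
        drive[e] += p.tonic_drive
    ff = state.slices["ff"]
    for stim in stimuli:
        if stim.layer == "excitatory":
            s = stim.drive_at(state.t, p.n_exc)
            if s is not None:
                drive[e] += s
        else:
            s = stim.drive_at(state.t, p.n_ff_inh)
            if s is not None:
                drive[ff] += s
    if external_input is not None:
        drive += external_input

    du = (-u / state.tau + drive) * dt
    if p.noise_sd > 0:
        z = noise_row if noise_row is not None else rng.standard_normal(u.size)
        du += p.noise_sd * np.sqrt(dt) * z
    u += du
    state.t += dt
    if not np.all(np.isfinite(u)):
        bad = int(np.flatnonzero(~np.isfinite(u))[0])
        raise RuntimeError(f"non-finite potential at unit {bad}, t={state.t:.3f} ms")
    state.push_gain(state.compute_gain().copy())
    return state


def hebbian_update(state: NetworkState, eta: float | None = None) -> NetworkState:
    """Apply one saturating Hebbian increment to all plastic connections.

    dw_ij = eta * g_i(u_i(t)) * g_j(u_j(t - delta_ij)) * (w_max - w_ij),
    restricted to excitatory-source structural connections; the rule's
    (w_max - w) factor makes clamping unnecessary. Weights stay in
    [0, w_max] exactly. Mutates in place.
    """
    p = state.params
    if eta is None:
        eta = p.eta
    if eta == 0:
        return state
    g_now = state.compute_gain().copy()
    W = state.W
    for lag, _ in zip(state._lags, state._W_by_lag):
        g_del = state.delayed_gain(int(lag))
        sel = state.plastic & (state.delay_steps == lag)
        if not sel.any():
            continue
        # capped at 1 so a large discrete increment cannot overshoot the
        # w_max fixed point the continuous rule converges to
        factor = np.minimum(eta * np.outer(g_now, g_del), 1.0)
        dw = factor * (p.w_max - W)
        W[sel] += dw[sel]
    state.refresh_weights()
    return state


def _sample_stimuli(state: NetworkState, stimuli: list[StimulusSpec],
                    n_steps: int, dt: float) -> np.ndarray | None:
    """Evaluate all stimulus waveforms on the step-time grid.

    Returns an (n_steps, n_total) drive array, or None when there are no
    stimuli. Honors each stimulus's onset/offset window and target layer.
    """
    if not stimuli:
        return None
    p = state.params
    out = np.zeros((n_steps, p.n_total))
    t0 = state.t
    times = t0 + np.arange(n_steps) * dt
    for stim in stimuli:
        if stim.layer == "excitatory":
            offset, n_layer = 0, p.n_exc
        else:
            offset, n_layer = p.n_exc, p.n_ff_inh
        if np.any(stim.target_units >= n_layer) or np.any(stim.target_units < 0):
            raise ValueError("stimulus targets outside the addressed layer")
        cols = offset + stim.target_units
        active = (times >= stim.onset) & (times < stim.offset)
        for i in np.flatnonzero(active):
            out[i, cols] += stim.waveform(times[i])
    return out


def simulate(
    state: NetworkState,
    stimuli: list[StimulusSpec] | None = None,
    duration: float = 1000.0,
    dt: float = 0.1,
    learning: bool = False,
    seed: int = 0,
    fs_out: float = 1000.0,
    record_units: bool = False,
    record_groups: Mapping[str, np.ndarray] | None = None,
    learn_interval_ms: float = 1.0,
    eta: float | None = None,
) -> TimeSeries:
    """Drive one area for ``duration`` ms and record its EEG-like readout.

    The recorded channel ``eeg`` is the mean excitatory-layer potential;
    ``record_units`` adds one channel per unit and ``record_groups`` one
    channel per named index set (mean potential over the set, e.g. a
    cell assembly). When ``learning`` is on, Hebbian consolidation runs
    every ``learn_interval_ms`` with the learning rate scaled by the
    elapsed interval (eta is per ms), making the accumulated weight
    change step-size robust.
    """
    stimuli = stimuli or []
    if duration < dt:
        raise ValueError("duration must be >= dt")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(1000.0 / (fs_out * dt))))
    n_rec = n_steps // rec_every
    e = state.slices["exc"]
    eeg = np.empty(n_rec)
    units = np.empty((n_rec, state.params.n_total)) if record_units else None
    groups = {name: (np.asarray(idx, dtype=int), np.empty(n_rec))
              for name, idx in (record_groups or {}).items()}
    learn_every = max(1, int(round(learn_interval_ms / dt)))
    eta_eff = (state.params.eta if eta is None else eta) * learn_interval_ms

    # pre-sample stimulus drive and noise on the step grid: waveforms are
    # evaluated once per step here instead of inside the hot loop
    stim_drive = _sample_stimuli(state, stimuli, n_steps, dt)
    noise = (rng.standard_normal((n_steps, state.params.n_total))
             if state.params.noise_sd > 0 else None)

    k = 0
    for i in range(n_steps):
        step(state, (), dt, rng,
             external_input=None if stim_drive is None else stim_drive[i],
             noise_row=None if noise is None else noise[i])
        if learning and (i + 1) % learn_every == 0:
            hebbian_update(state, eta=eta_eff)
        if (i + 1) % rec_every == 0 and k < n_rec:
            eeg[k] = state.u[e].mean()
            if record_units:
                units[k] = state.u
            for idx, buf in groups.values():
                buf[k] = state.u[idx].mean()
            k += 1
    channels = {"eeg": eeg[:k]}
    for name, (idx, buf) in groups.items():
        channels[name] = buf[:k]
    if record_units:
        for j in range(state.params.n_total):
            channels[f"u{j}"] = units[:k, j]
    return TimeSeries(fs=fs_out, channels=channels,
                      meta={"seed": seed, "dt": dt, "duration_ms": duration})
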