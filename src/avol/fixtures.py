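"""Benchmark signal generators for oracle-testing the analysis battery.

Each generator produces a fully reproducible :class:`~avol.timeseries.TimeSeries`
from a :class:`FixtureSpec`. The chaotic systems (Lorenz, Roessler) are the
standard test beds for correlation-dimension and Lyapunov estimators; the
theta-modulated gamma signal is the canonical positive control for
phase-amplitude coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .timeseries import TimeSeries

__all__ = ["FixtureSpec", "generate_fixture", "KINDS"]

KINDS = (
    "sine",
    "white_noise",
    "lorenz",
    "rossler",
    "theta_modulated_gamma",
    "ar_colored_noise",
)


@dataclass
class FixtureSpec:
    """Recipe for one benchmark signal.

    ``params`` are per-kind; unknown keys raise. Defaults:

    - sine: f=10 Hz, amplitude=1, phase=0, noise_sd=0
    - white_noise: sd=1
    - lorenz: sigma=10, rho=28, beta=8/3, dt_model=0.01 (model time per
      sample), transient=10 model-time units; channel is x
    - rossler: a=0.2, b=0.2, c=5.7, dt_model=0.05, transient=50; channel x
    - theta_modulated_gamma: f_phase=6, f_amp=40, depth=1.0, noise_sd=0.05,
      slow_amplitude=1.0 (the theta carrier itself is present in the
      signal, as it is in a cortical field potential), mod="cosine"
      (envelope 1 + depth*cos) or "burst" (envelope exp(kappa*cos),
      gamma bursts locked to the theta peak; kappa=2.5)
    - ar_colored_noise: phi=0.95, sd=1 (AR(1))
    """

    kind: str
    n: int
    fs: float = 1000.0
    seed: int = 0
    params: dict = field(default_factory=dict)


_DEFAULTS = {
    "sine": {"f": 10.0, "amplitude": 1.0, "phase": 0.0, "noise_sd": 0.0},
    "white_noise": {"sd": 1.0},
    "lorenz": {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0, "dt_model": 0.01,
               "transient": 10.0, "x0": (1.0, 1.0, 1.0)},
    "rossler": {"a": 0.2, "b": 0.2, "c": 5.7, "dt_model": 0.05,
                "transient": 50.0, "x0": (1.0, 1.0, 1.0)},
    "theta_modulated_gamma": {"f_phase": 6.0, "f_amp": 40.0, "depth": 1.0,
                              "noise_sd": 0.05, "slow_amplitude": 1.0,
                              "mod": "cosine", "kappa": 2.5,
                              "phase_jitter": 2.0},
    "ar_colored_noise": {"phi": 0.95, "sd": 1.0},
}


def generate_fixture(spec: FixtureSpec) -> TimeSeries:
    """Generate the benchmark signal described by ``spec``.

    Deterministic given (kind, params, n, fs, seed). Chaotic flows are
    integrated with adaptive RK45 (tight tolerances) and the transient
    is discarded before sampling.
    """
    if spec.kind not in KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; choose from {KINDS}")
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    p = dict(_DEFAULTS[spec.kind])
    unknown = set(spec.params) - set(p)
    if unknown:
        raise ValueError(f"unknown params for {spec.kind}: {sorted(unknown)}")
    p.update(spec.params)
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n) / spec.fs

    if spec.kind == "sine":
        x = p["amplitude"] * np.sin(2 * np.pi * p["f"] * t + p["phase"])
        if p["noise_sd"] > 0:
            x = x + rng.normal(0.0, p["noise_sd"], spec.n)
        channels = {"sine": x}
    elif spec.kind == "white_noise":
        channels = {"noise": rng.normal(0.0, p["sd"], spec.n)}
    elif spec.kind in ("lorenz", "rossler"):
        channels = _chaotic_flow(spec.kind, p, spec.n)
    elif spec.kind == "theta_modulated_gamma":
        # slow-phase random walk: a rigidly periodic modulation is
        # invariant under circular time shifts, which would void the
        # surrogate null; real carriers drift.
        dphi = rng.normal(0.0, p["phase_jitter"] / np.sqrt(spec.fs), spec.n)
        phi = 2 * np.pi * p["f_phase"] * t + np.cumsum(dphi)
        theta = np.cos(phi)
        if p["mod"] == "cosine":
            env = 1.0 + p["depth"] * theta
        elif p["mod"] == "burst":
            env = np.exp(p["kappa"] * theta) / np.exp(p["kappa"])
        else:
            raise ValueError(f"unknown modulation {p['mod']!r}")
        x = p["slow_amplitude"] * theta + env * np.cos(2 * np.pi * p["f_amp"] * t)
        x = x + rng.normal(0.0, p["noise_sd"], spec.n)
        channels = {"pac": x}
    elif spec.kind == "ar_colored_noise":
        eps = rng.normal(0.0, p["sd"], spec.n)
        x = np.empty(spec.n)
        acc = 0.0
        for i in range(spec.n):
            acc = p["phi"] * acc + eps[i]
            x[i] = acc
        channels = {"ar1": x}

    meta = {"kind": spec.kind, "seed": spec.seed, **{k: v for k, v in p.items() if k != "x0"}}
    return TimeSeries(fs=spec.fs, channels=channels, meta=meta)


def _chaotic_flow(kind: str, p: dict, n: int) -> dict[str, np.ndarray]:
    if kind == "lorenz":
        def rhs(t, s):
            x, y, z = s
            return [p["sigma"] * (y - x), x * (p["rho"] - z) - y, x * y - p["beta"] * z]
    else:
        def rhs(t, s):
            x, y, z = s
            return [-y - z, x + p["a"] * y, p["b"] + z * (x - p["c"])]

    dt = p["dt_model"]
    t_end = p["transient"] + n * dt
    t_eval = p["transient"] + np.arange(n) * dt
    sol = solve_ivp(rhs, (0.0, t_end), p["x0"], t_eval=t_eval,
                    rtol=1e-9, atol=1e-9, method="RK45", max_step=dt)
    if not sol.success:
        raise RuntimeError(f"{kind} integration failed: {sol.message}")
    return {"x": sol.y[0], "y": sol.y[1], "z": sol.y[2]}
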