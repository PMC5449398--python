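"""Chaotic-system simulators and time-series loaders.

Every analysis in this package starts from a uniformly sampled scalar
measurement of a dynamical system.  This module provides the built-in
generators for the canonical test systems (Lorenz, Rössler, double
pendulum, and a stochastically driven dynamo stand-in) together with a
loader for user-supplied CSV/TSV time series.

Deterministic systems are integrated with a classical fixed-step RK4
scheme so that the sample spacing of the output matches the Hankel-matrix
sampling exactly; the stochastic dynamo uses a seeded Euler–Maruyama
scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "SystemSpec",
    "Trajectory",
    "simulate_system",
    "load_timeseries",
    "save_timeseries",
    "DEFAULT_PARAMS",
]


@dataclass(frozen=True, eq=False)
class TimeSeries:
    """A uniformly sampled scalar measurement x(t).

    Parameters
    ----------
    values : ndarray
        Measurement samples, all finite, length >= 2.
    dt : float
        Sample interval (time units per sample), > 0.
    t0 : float
        Time stamp of the first sample.
    name : str
        Label used in serialization headers and plots.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    name: str = "x"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("time series must be 1-D with length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    def window(self, t_start: float, t_end: float) -> "TimeSeries":
        """Sub-series covering [t_start, t_end] (inclusive, snapped to samples)."""
        i0 = max(0, int(round((t_start - self.t0) / self.dt)))
        i1 = min(len(self) - 1, int(round((t_end - self.t0) / self.dt)))
        if i1 - i0 < 1:
            raise ValueError("window too short")
        return replace(self, values=self.values[i0 : i1 + 1], t0=self.t0 + i0 * self.dt)


_LORENZ = {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0}
_ROSSLER = {"a": 0.2, "b": 0.2, "c": 5.7}
_PENDULUM = {"m1": 1.0, "m2": 1.0, "l1": 1.0, "l2": 1.0, "g": 9.81}
_DYNAMO = {"alpha": 1.0}

DEFAULT_PARAMS = {
    "lorenz": _LORENZ,
    "rossler": _ROSSLER,
    "double_pendulum": _PENDULUM,
    "dynamo": _DYNAMO,
}

_DEFAULT_IC = {
    "lorenz": (-8.0, 8.0, 27.0),
    "rossler": (1.0, 1.0, 0.0),
    "double_pendulum": (math.pi / 2, math.pi / 2, 0.0, 0.0),
    "dynamo": (1.0,),
}

# index of the observed channel in the state vector
_OBSERVED = {"lorenz": 0, "rossler": 0, "double_pendulum": 0, "dynamo": 0}


@dataclass(frozen=True)
class SystemSpec:
    """Named dynamical system plus parameters, initial state and noise level."""

    name: str
    params: dict = None
    initial_state: tuple = None
    noise_level: float = 0.0
    seed: int = 0
    observed: int = None

    def __post_init__(self):
        if self.name not in DEFAULT_PARAMS:
            raise ValueError(
                f"unknown system {self.name!r}; choose from {sorted(DEFAULT_PARAMS)}"
            )
        params = dict(DEFAULT_PARAMS[self.name])
        if self.params:
            unknown = set(self.params) - set(params)
            if unknown:
                raise ValueError(f"unknown parameters for {self.name}: {sorted(unknown)}")
            params.update(self.params)
        object.__setattr__(self, "params", params)
        ic = self.initial_state if self.initial_state is not None else _DEFAULT_IC[self.name]
        ic = tuple(float(v) for v in ic)
        if len(ic) != len(_DEFAULT_IC[self.name]):
            raise ValueError(f"{self.name} needs a state of length {len(_DEFAULT_IC[self.name])}")
        object.__setattr__(self, "initial_state", ic)
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.noise_level > 0 and self.name != "dynamo":
            raise ValueError("only the dynamo system is stochastic (noise_level > 0)")
        obs = self.observed if self.observed is not None else _OBSERVED[self.name]
        object.__setattr__(self, "observed", int(obs))


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Full multichannel state history plus the observed scalar channel."""

    states: np.ndarray  # (n_samples, n_dim)
    dt: float
    t0: float
    spec: SystemSpec
    observed: TimeSeries


def _lorenz_rhs(s, p):
    x, y, z = s
    return (
        p["sigma"] * (y - x),
        x * (p["rho"] - z) - y,
        x * y - p["beta"] * z,
    )


def _rossler_rhs(s, p):
    x, y, z = s
    return (-y - z, x + p["a"] * y, p["b"] + z * (x - p["c"]))


def _pendulum_rhs(s, p):
    # Frictionless planar double pendulum, state (th1, th2, w1, w2),
    # equations in angular-acceleration form for point masses on rigid rods.
    th1, th2, w1, w2 = s
    m1, m2, l1, l2, g = p["m1"], p["m2"], p["l1"], p["l2"], p["g"]
    d = th1 - th2
    cd = math.cos(d)
    sd = math.sin(d)
    den = m1 + m2 * sd * sd
    a1 = (
        -m2 * l1 * w1 * w1 * sd * cd
        - m2 * l2 * w2 * w2 * sd
        - (m1 + m2) * g * math.sin(th1)
        + m2 * g * math.sin(th2) * cd
    ) / (l1 * den)
    a2 = (
        (m1 + m2) * l1 * w1 * w1 * sd
        + m2 * l2 * w2 * w2 * sd * cd
        + (m1 + m2) * g * (math.sin(th1) * cd - math.sin(th2))
    ) / (l2 * den)
    return (w1, w2, a1, a2)


_RHS = {"lorenz": _lorenz_rhs, "rossler": _rossler_rhs, "double_pendulum": _pendulum_rhs}


def pendulum_energy(states: np.ndarray, params: dict = None) -> np.ndarray:
    """Total mechanical energy of the double pendulum along a trajectory."""
    p = dict(_PENDULUM)
    if params:
        p.update(params)
    th1, th2, w1, w2 = states.T
    m1, m2, l1, l2, g = p["m1"], p["m2"], p["l1"], p["l2"], p["g"]
    v1sq = (l1 * w1) ** 2
    v2sq = (l1 * w1) ** 2 + (l2 * w2) ** 2 + 2 * l1 * l2 * w1 * w2 * np.cos(th1 - th2)
    kinetic = 0.5 * m1 * v1sq + 0.5 * m2 * v2sq
    potential = -(m1 + m2) * g * l1 * np.cos(th1) - m2 * g * l2 * np.cos(th2)
    return kinetic + potential


def _integrate_rk4(rhs, params, state, dt, n_steps, check_every=1000):
    """Classical fixed-step RK4 on a tuple state; returns (n_steps+1, dim) array."""
    dim = len(state)
    out = np.empty((n_steps + 1, dim))
    out[0] = state
    s = state
    h = dt
    for k in range(n_steps):
        k1 = rhs(s, params)
        k2 = rhs(tuple(s[i] + 0.5 * h * k1[i] for i in range(dim)), params)
        k3 = rhs(tuple(s[i] + 0.5 * h * k2[i] for i in range(dim)), params)
        k4 = rhs(tuple(s[i] + h * k3[i] for i in range(dim)), params)
        s = tuple(
            s[i] + h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) for i in range(dim)
        )
        out[k + 1] = s
        if (k + 1) % check_every == 0 and not all(map(math.isfinite, s)):
            raise FloatingPointError(
                f"state blew up at t = {(k + 1) * dt:.6g} during integration"
            )
    if not np.all(np.isfinite(out)):
        bad = np.argmax(~np.all(np.isfinite(out), axis=1))
        raise FloatingPointError(f"state blew up at t = {bad * dt:.6g} during integration")
    return out


def _integrate_dynamo(spec: SystemSpec, dt: float, n_steps: int) -> np.ndarray:
    """Euler–Maruyama for the double-well Langevin dynamo stand-in.

    dx = (alpha*x - x^3) dt + noise_level dW.  This is a synthetic stand-in
    for a turbulently driven magnetic-field-reversal model: the field
    amplitude x sits in one of two wells (polarities) and noise drives the
    rare reversals.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = spec.params["alpha"]
    x = np.empty(n_steps + 1)
    x[0] = spec.initial_state[0]
    noise = spec.noise_level * math.sqrt(dt) * rng.standard_normal(n_steps)
    for k in range(n_steps):
        xi = x[k]
        x[k + 1] = xi + dt * (alpha * xi - xi**3) + noise[k]
    if not np.all(np.isfinite(x)):
        bad = np.argmax(~np.isfinite(x))
        raise FloatingPointError(f"state blew up at t = {bad * dt:.6g} during integration")
    return x[:, None]


def simulate_system(
    spec: SystemSpec | str,
    dt: float,
    duration: float,
    transient: float = 0.0,
) -> Trajectory:
    """Integrate a named system and extract its observed scalar channel.

    Parameters
    ----------
    spec : SystemSpec or str
        System definition; a bare name uses default parameters.
    dt : float
        Integration and output time step.
    duration : float
        Length of the returned trajectory in time units; the output has
        ``floor(duration/dt) + 1`` samples.
    transient : float
        Initial stretch of the solution discarded before recording, so the
        returned trajectory starts on (or near) the attractor.  t0 of the
        returned series is 0 regardless.
    """
    if isinstance(spec, str):
        spec = SystemSpec(spec)
    if not dt > 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    n_keep = int(math.floor(duration / dt))
    n_skip = int(round(transient / dt))
    n_total = n_keep + n_skip
    if spec.name == "dynamo":
        states = _integrate_dynamo(spec, dt, n_total)
    else:
        states = _integrate_rk4(_RHS[spec.name], spec.params, spec.initial_state, dt, n_total)
    states = states[n_skip:]
    observed = TimeSeries(
        values=states[:, spec.observed].copy(), dt=dt, t0=0.0, name=spec.name
    )
    return Trajectory(states=states, dt=dt, t0=0.0, spec=spec, observed=observed)


def load_timeseries(path, dt_override: float = None, name: str = None) -> TimeSeries:
    """Load a scalar time series from a one- or two-column CSV/TSV file.

    A single column is interpreted as values (requires ``dt_override``);
    two columns are interpreted as (time, value) with the sample interval
    inferred from the time column, which must be uniform to 1e-6 relative.
    Lines starting with '#' are comments; a non-numeric first row is
    treated as a header.
    """
    import io
    from pathlib import Path as _Path

    lines = [
        ln
        for ln in _Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no data rows")
    df = pd.read_csv(
        io.StringIO("\n".join(lines)),
        sep=r"[,\t;]\s*|\s+",
        engine="python",
        header=None,
    )
    # drop a header row if the first row is non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise ValueError(f"{path}: non-numeric rows present")
    if df.shape[1] == 1:
        if dt_override is None:
            raise ValueError(f"{path}: single-column file requires dt_override")
        values = df.iloc[:, 0].to_numpy(float)
        dt, t0 = float(dt_override), 0.0
    elif df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(float)
        values = df.iloc[:, 1].to_numpy(float)
        steps = np.diff(t)
        if dt_override is not None:
            dt = float(dt_override)
        else:
            dt = float(np.median(steps))
            if dt <= 0 or np.max(np.abs(steps - dt)) > 1e-6 * max(abs(dt), 1e-300):
                raise ValueError(f"{path}: non-uniform sampling in time column")
        t0 = float(t[0])
    else:
        raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return TimeSeries(values=values, dt=dt, t0=t0, name=name)


def save_timeseries(series: TimeSeries, path) -> None:
    """Write a two-column (time,value) CSV; round-trips through load_timeseries."""
    df = pd.DataFrame({"time": series.times, "value": series.values})
    df.to_csv(path, index=False, float_format="%.17g")
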