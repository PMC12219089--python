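"""Synthetic time-series generators with known dynamical regimes.

Chua's oscillator is the workhorse: a three-variable piecewise-linear
circuit model in the classic dimensionless form

    dx/dt = alpha * (y - x - h(x))
    dy/dt = x - y + z
    dz/dt = -beta * y

with the piecewise-linear diode characteristic
``h(x) = m1*x + (m0 - m1)*(|x+1| - |x-1|)/2``.  With alpha = 15.6,
m0 = -8/7, m1 = -5/7 the system moves through periodic and chaotic
regimes as beta varies over [30, 32].  Integration is fixed-step
4th-order Runge-Kutta; the retained signal is x(t) sampled at unit
time intervals after a discarded transient, matching the convention of
analysing x(t) at t = 1, 2, ....

The logistic map, pure tones and white noise provide cheap labelled
cohorts so the full pipeline is testable end to end without any
external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .embedding import TimeSeries

__all__ = [
    "ChuaParams",
    "chua_nonlinearity",
    "simulate_chua",
    "simulate_logistic",
    "make_labeled_cohort",
]


@dataclass(frozen=True)
class ChuaParams:
    """Parameters for the Chua oscillator simulation.

    ``dt`` is the integrator step, ``sample_interval`` the spacing of
    retained samples (an integer multiple of dt), ``transient`` the
    initial stretch of trajectory discarded before sampling — all in
    the model's dimensionless time units.
    """

    alpha: float = 15.6
    beta: float = 30.0
    m0: float = -8.0 / 7.0
    m1: float = -5.0 / 7.0
    dt: float = 0.01
    sample_interval: float = 1.0
    transient: float = 500.0
    initial_state: Tuple[float, float, float] = (0.1, 0.0, 0.0)
    n_samples: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        ratio = self.sample_interval / self.dt
        if self.sample_interval < self.dt or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"sample_interval ({self.sample_interval}) must be an integer "
                f"multiple of dt ({self.dt})"
            )
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")


def chua_nonlinearity(x: float, m0: float, m1: float):
    """Piecewise-linear diode characteristic h(x).

    ``h(x) = m1*x + (m0 - m1) * (|x + 1| - |x - 1|) / 2``: slope m0 in
    the inner region |x| <= 1, slope m1 outside.  Odd: h(-x) = -h(x).
    """
    x = np.asarray(x, dtype=float)
    out = m1 * x + 0.5 * (m0 - m1) * (np.abs(x + 1.0) - np.abs(x - 1.0))
    return out if out.ndim else float(out)


def _chua_rhs(state: np.ndarray, p: ChuaParams) -> np.ndarray:
    x, y, z = state
    return np.array(
        [
            p.alpha * (y - x - chua_nonlinearity(x, p.m0, p.m1)),
            x - y + z,
            -p.beta * y,
        ]
    )


class ChuaInstabilityError(RuntimeError):
    pass


def simulate_chua(params: ChuaParams) -> TimeSeries:
    """Integrate the Chua oscillator and return sampled x(t).

    Fixed-step RK4 at step ``params.dt``; the first ``params.transient``
    time units are discarded and ``params.n_samples`` values of x are
    retained at ``params.sample_interval`` spacing (the state at the end
    of the transient is sample 1).  Deterministic given params.

    Raises
    ------
    ChuaInstabilityError
        If the trajectory diverges (any |state component| > 1e6),
        naming the integration step.
    """
    p = params
    stride = int(round(p.sample_interval / p.dt))
    n_transient = int(round(p.transient / p.dt))
    n_steps = n_transient + (p.n_samples - 1) * stride
    state = np.array(p.initial_state, dtype=float)
    samples = np.empty(p.n_samples, dtype=float)
    sample_idx = 0
    for step in range(n_steps + 1):
        if step >= n_transient and (step - n_transient) % stride == 0:
            samples[sample_idx] = state[0]
            sample_idx += 1
            if sample_idx == p.n_samples:
                break
        k1 = _chua_rhs(state, p)
        k2 = _chua_rhs(state + 0.5 * p.dt * k1, p)
        k3 = _chua_rhs(state + 0.5 * p.dt * k2, p)
        k4 = _chua_rhs(state + p.dt * k3, p)
        state = state + (p.dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.any(np.abs(state) > 1e6):
            raise ChuaInstabilityError(
                f"Chua trajectory diverged at t={step * p.dt:.2f} "
                f"(beta={p.beta}, dt={p.dt}); reduce dt"
            )
    return TimeSeries(samples, label=None, id=f"chua-beta{p.beta:g}")


def simulate_logistic(r: float, x0: float, n: int) -> TimeSeries:
    """Iterate the logistic map x <- r*x*(1-x) from x0, returning n values.

    x0 must lie strictly inside (0, 1).  At r = 4 the map is chaotic on
    (0, 1); r < 3 converges to the fixed point 1 - 1/r.
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError(f"x0 must lie in (0, 1), got {x0}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out = np.empty(n, dtype=float)
    x = float(x0)
    for i in range(n):
        out[i] = x
        x = r * x * (1.0 - x)
    return TimeSeries(out, id=f"logistic-r{r:g}")


_GENERATORS = {"sine", "logistic", "noise"}


def make_labeled_cohort(
    sizes: Dict[str, int],
    length: int = 200,
    seed: int = 0,
    sine_period: float = 20.0,
    sine_noise: float = 0.05,
) -> List[TimeSeries]:
    """Reproducible labelled cohort of synthetic series.

    Generators: ``sine`` — unit-amplitude tone of the given period with
    small additive Gaussian noise (sd ``sine_noise``) and a random
    phase; ``logistic`` — chaotic logistic map (r = 4) from a random
    initial point; ``noise`` — standard white Gaussian noise.  The
    label of each series is the generator name.  Bitwise reproducible
    for a fixed seed.
    """
    unknown = set(sizes) - _GENERATORS
    if unknown:
        raise ValueError(f"unknown generator(s) {sorted(unknown)}; available: {sorted(_GENERATORS)}")
    if any(n < 1 for n in sizes.values()):
        raise ValueError("cohort sizes must be >= 1")
    rng = np.random.default_rng(seed)
    cohort: List[TimeSeries] = []
    t = np.arange(length, dtype=float)
    for name in sorted(sizes):
        for i in range(sizes[name]):
            sid = f"{name}-{i:03d}"
            if name == "sine":
                phase = rng.uniform(0.0, 2.0 * np.pi)
                values = np.sin(2.0 * np.pi * t / sine_period + phase)
                if sine_noise > 0:
                    values = values + rng.normal(0.0, sine_noise, size=length)
                cohort.append(TimeSeries(values, label="sine", id=sid))
            elif name == "logistic":
                x0 = rng.uniform(0.05, 0.95)
                ts = simulate_logistic(4.0, x0, length)
                cohort.append(TimeSeries(ts.values, label="logistic", id=sid))
            else:  # noise
                cohort.append(
                    TimeSeries(rng.normal(0.0, 1.0, size=length), label="noise", id=sid)
                )
    return cohort
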