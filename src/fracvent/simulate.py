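"""Time-domain simulation of fractional-order systems (Grünwald–Letnikov).

The fractional derivative of order alpha is discretized on a uniform
grid with step dt by the Grünwald–Letnikov difference

    D^alpha x(t_k) ~ dt^(-alpha) * sum_{j=0..k} w_j x_{k-j},
    w_0 = 1,  w_j = w_{j-1} * (1 - (alpha+1)/j),

whose weights are the alternating binomial coefficients of (1-z)^alpha.
For null initial conditions (the only case simulated here) this scheme
is consistent with the Caputo and Riemann–Liouville derivatives and
converges at first order in dt.  The default update is semi-implicit —
each step solves (I - dt^alpha A) x_k = dt^alpha B u_k - sum_{j>=1} w_j
x_{k-j} — which remains stable for the stiff ladder spectra; the
explicit variant is kept for testing.

Breath cycles: the reference is a square flow profile (constant setpoint
during inspiration, zero during expiration, sampled left-closed so a
cycle start belongs to inspiration).  During expiration the ventilator
switch connects the airway to ambient pressure: the plant input is
forced to zero while the plant keeps evolving (passive outflow) and the
observer is fed the applied (zero) input.  The leaky-integrator states
are by default held during expiration and released at the next
inspiration; letting them integrate the passive outflow ("track") or
leak freely ("leak") are available variants — with an error gain
1 + K_r of order 500, "track" winds the integrators up against the
expiratory flow and ruins the next breath.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .control import ControllerGains
from .model import FractionalStateModel

__all__ = [
    "GlConfig",
    "VentilationProfile",
    "SimulationTrace",
    "SimulationDivergedError",
    "gl_coefficients",
    "simulate_lti_fractional",
    "reference_signal",
    "simulate_closed_loop",
]

_BLOWUP_NORM = 1e12


class SimulationDivergedError(RuntimeError):
    """State norm overflow during time stepping (unstable configuration)."""


@dataclass(frozen=True)
class GlConfig:
    """Discretization settings for the Grünwald–Letnikov stepper."""

    dt: float = 1e-3  # step, s
    t_end: float = 11.25  # horizon, s (three 16/min breath periods)
    memory: int | str = "full"  # history length in steps, or "full"
    scheme: str = "implicit"  # "implicit" (default) or "explicit"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_end < self.dt:
            raise ValueError(f"t_end must be >= dt, got {self.t_end}")
        if self.memory != "full":
            if not (isinstance(self.memory, (int, np.integer)) and self.memory >= 1):
                raise ValueError(f"memory must be 'full' or an integer >= 1, got {self.memory!r}")
        if self.scheme not in ("implicit", "explicit"):
            raise ValueError(f"scheme must be 'implicit' or 'explicit', got {self.scheme!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def memory_steps(self, n_steps: int) -> int:
        return n_steps if self.memory == "full" else min(int(self.memory), n_steps)


@dataclass(frozen=True)
class VentilationProfile:
    """Square-wave flow reference for intermittent positive-pressure ventilation."""

    rate: float = 16.0  # breath cycles per minute
    ie_ratio: tuple[float, float] = (1.0, 2.0)  # inspiration : expiration
    flow_setpoint: float = 0.48  # l/s (480 ml/s)
    n_cycles: int = 3

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if not (self.ie_ratio[0] > 0 and self.ie_ratio[1] > 0):
            raise ValueError(f"both I:E terms must be > 0, got {self.ie_ratio}")
        if self.flow_setpoint < 0:
            raise ValueError(f"flow_setpoint must be >= 0, got {self.flow_setpoint}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")

    @property
    def period(self) -> float:
        """Breath period, s."""
        return 60.0 / self.rate

    @property
    def t_inspiration(self) -> float:
        """Inspiration duration within one period, s."""
        i, e = self.ie_ratio
        return self.period * i / (i + e)

    @property
    def t_total(self) -> float:
        return self.n_cycles * self.period


@dataclass(frozen=True)
class SimulationTrace:
    """Sampled closed-loop ventilation run."""

    time: np.ndarray  # s
    flow: np.ndarray  # delivered flow y, l/s
    pressure: np.ndarray  # applied airway pressure u, kPa (0 in expiration)
    reference: np.ndarray  # flow reference v, l/s
    phase: np.ndarray  # bool, True = inspiration
    states: np.ndarray | None = None  # optional [x; x_hat; w1; w2] history

    def __post_init__(self) -> None:
        lengths = {len(self.time), len(self.flow), len(self.pressure),
                   len(self.reference), len(self.phase)}
        if len(lengths) != 1:
            raise ValueError("all trace arrays must have the same length")
        if np.any(self.pressure[~self.phase] != 0.0):
            raise ValueError("pressure must be identically zero on expiration samples")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.time,
                "v": self.reference,
                "y": self.flow,
                "u": self.pressure,
                "phase": np.where(self.phase, "inspiration", "expiration"),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def gl_coefficients(alpha: float, n_steps: int) -> np.ndarray:
    """Grünwald–Letnikov weights w_0..w_{n_steps} for order ``alpha``."""
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must lie in (0, 2), got {alpha}")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    w = np.empty(n_steps + 1)
    w[0] = 1.0
    for k in range(1, n_steps + 1):
        w[k] = w[k - 1] * (1.0 - (alpha + 1.0) / k)
    return w


def _history_sum(weights: np.ndarray, states: np.ndarray, k: int, mem: int) -> np.ndarray:
    """sum_{j=1..min(k, mem)} w_j x_{k-j} over the stored trajectory."""
    kk = min(k, mem)
    stop = k - 1 - kk
    window = states[k - 1: (stop if stop >= 0 else None): -1]
    return weights[1: kk + 1] @ window


def simulate_lti_fractional(
    model: FractionalStateModel,
    input_fn: Callable[[float], float | np.ndarray],
    glcfg: GlConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate D^a x = A x + B u(t) from null initial conditions.

    Returns (time, states, outputs) with states of shape (n_steps+1, n)
    and outputs of shape (n_steps+1, q).
    """
    n = model.n_states
    n_steps = glcfg.n_steps
    mem = glcfg.memory_steps(n_steps)
    w = gl_coefficients(model.alpha, mem)
    dt = glcfg.dt
    ha = dt**model.alpha
    t = np.arange(n_steps + 1) * dt
    u = np.stack([np.atleast_1d(np.asarray(input_fn(ti), dtype=float)) for ti in t])
    x = np.zeros((n_steps + 1, n))
    implicit = glcfg.scheme == "implicit"
    if implicit:
        lu = lu_factor(np.eye(n) - ha * model.a)
    for k in range(1, n_steps + 1):
        hist = _history_sum(w, x, k, mem)
        if implicit:
            rhs = ha * (model.b @ u[k]) - hist
            x[k] = lu_solve(lu, rhs)
        else:
            x[k] = ha * (model.a @ x[k - 1] + model.b @ u[k - 1]) - hist
        if not np.all(np.isfinite(x[k])) or np.linalg.norm(x[k]) > _BLOWUP_NORM:
            raise SimulationDivergedError(
                f"state norm overflow at step {k} (t = {k * dt:.6g} s)"
            )
    y = x @ model.c.T + u @ model.d.T
    return t, x, y


def reference_signal(profile: VentilationProfile, t: float | np.ndarray) -> float | np.ndarray:
    """Flow reference v(t): setpoint during inspiration, 0 during expiration.

    Phase boundaries are left-closed: t exactly at a cycle start is
    inspiration.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    insp = (t_arr % profile.period) < profile.t_inspiration
    v = np.where(insp, profile.flow_setpoint, 0.0)
    return float(v) if np.isscalar(t) or t_arr.ndim == 0 else v


def _mode_matrices(
    model: FractionalStateModel, gains: ControllerGains, applied: bool
):
    """Dynamics of z = [x; x_hat; w1; w2] with the controller output applied or not."""
    n = model.n_states
    nz = 2 * n + 2
    a, b, c, d = model.a, model.b, model.c, model.d
    l_gain = gains.l_gain
    eps1, eps2 = gains.eps_pair
    onekr = 1.0 + gains.k_r
    ku = np.zeros((1, nz))  # controller command as a map of z
    ku[0, n: 2 * n] = -gains.k_x
    ku[0, 2 * n] = -gains.k_w1
    ku[0, 2 * n + 1] = -gains.k_w2
    ua = ku if applied else np.zeros((1, nz))
    az = np.zeros((nz, nz))
    bz = np.zeros((nz, 1))
    az[:n, :n] = a
    az[:n, :] += b @ ua
    # observer innovation L(y - y_hat) = L C (x - x_hat); D-terms cancel
    az[n: 2 * n, n: 2 * n] = a - l_gain @ c
    az[n: 2 * n, :n] += l_gain @ c
    az[n: 2 * n, :] += b @ ua
    az[2 * n, :n] = (-onekr * c).ravel()
    az[2 * n, :] += (-onekr * d @ ua).ravel()
    az[2 * n, 2 * n] += -eps1
    bz[2 * n, 0] = onekr
    az[2 * n + 1, 2 * n] = 1.0
    az[2 * n + 1, 2 * n + 1] = -eps2
    cy = np.zeros((1, nz))
    cy[0, :n] = c.ravel()
    cy += d @ ua
    return az, bz, cy, ku


def simulate_closed_loop(
    model: FractionalStateModel,
    gains: ControllerGains,
    profile: VentilationProfile,
    glcfg: GlConfig | None = None,
    expiration: str = "freeze",
    keep_states: bool = False,
) -> SimulationTrace:
    """Breath-cycle simulation of the full output-feedback loop.

    All states (plant, observer, integrators) start from null initial
    conditions.  During inspiration the plant receives the controller
    output and v equals the flow setpoint; during expiration the plant
    input is forced to zero (passive outflow) and v = 0.  ``expiration``
    selects the integrator handling while the switch is open: "freeze"
    (default — hold w1, w2), "track" (keep integrating the measured
    flow), or "leak" (pure leakage decay).
    """
    if expiration not in ("freeze", "track", "leak"):
        raise ValueError(f"unknown expiration mode {expiration!r}")
    if glcfg is None:
        glcfg = GlConfig(t_end=profile.t_total)
    n = model.n_states
    nz = 2 * n + 2
    n_steps = glcfg.n_steps
    mem = glcfg.memory_steps(n_steps)
    w = gl_coefficients(model.alpha, mem)
    dt = glcfg.dt
    ha = dt**model.alpha
    a_in, b_in, cy_in, ku = _mode_matrices(model, gains, applied=True)
    a_ex, b_ex, cy_ex, _ = _mode_matrices(model, gains, applied=False)
    if expiration == "leak":
        eps1, _ = gains.eps_pair
        a_ex = a_ex.copy()
        a_ex[2 * n, :] = 0.0
        a_ex[2 * n, 2 * n] = -eps1
        b_ex = b_ex.copy()
        b_ex[2 * n, 0] = 0.0
    implicit = glcfg.scheme == "implicit"
    if implicit:
        lu_in = lu_factor(np.eye(nz) - ha * a_in)
        lu_ex = lu_factor(np.eye(nz) - ha * a_ex)
    t = np.arange(n_steps + 1) * dt
    insp = (t % profile.period) < profile.t_inspiration
    v = np.where(insp, profile.flow_setpoint, 0.0)
    z = np.zeros((n_steps + 1, nz))
    y = np.zeros(n_steps + 1)
    u = np.zeros(n_steps + 1)
    for k in range(1, n_steps + 1):
        hist = _history_sum(w, z, k, mem)
        if implicit:
            rhs = ha * (b_in if insp[k] else b_ex)[:, 0] * v[k] - hist
            z[k] = lu_solve(lu_in if insp[k] else lu_ex, rhs)
        else:
            az, bz = (a_in, b_in) if insp[k - 1] else (a_ex, b_ex)
            z[k] = ha * (az @ z[k - 1] + bz[:, 0] * v[k - 1]) - hist
        if not insp[k] and expiration == "freeze":
            z[k, 2 * n:] = z[k - 1, 2 * n:]
        if not np.all(np.isfinite(z[k])) or np.linalg.norm(z[k]) > _BLOWUP_NORM:
            raise SimulationDivergedError(
                f"state norm overflow at step {k} (t = {k * dt:.6g} s)"
            )
        if insp[k]:
            y[k] = (cy_in @ z[k])[0]
            u[k] = (ku @ z[k])[0]
        else:
            y[k] = (cy_ex @ z[k])[0]
    return SimulationTrace(
        time=t,
        flow=y,
        pressure=u,
        reference=v,
        phase=insp,
        states=z if keep_states else None,
    )
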