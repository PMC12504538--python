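"""Fractional-order pseudo-state-space container.

A commensurate fractional-order LTI system

    D^alpha x(t) = A x(t) + B u(t)
    y(t)         = C x(t) + D u(t)

with a single differentiation order ``alpha`` in (0, 2) applied to every
pseudo-state.  The vector x is a *pseudo*-state: the true state of a
fractional system is infinite-dimensional (it lives inside the fractional
integrators), so x determines the future only together with the past
history of the trajectory.  With null initial conditions — the only case
handled in this package — the Caputo, Riemann–Liouville and
Grünwald–Letnikov readings of D^alpha coincide and the transfer matrix is

    H(s) = C (s^alpha I - A)^{-1} B + D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import numpy.typing as npt


def _as_2d(name: str, m: npt.ArrayLike) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(m, dtype=float))
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class FractionalStateModel:
    """(A, B, C, D, alpha) pseudo-state-space model of commensurate order."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        a = _as_2d("a", self.a)
        b = _as_2d("b", self.b)
        c = _as_2d("c", self.c)
        d = _as_2d("d", self.d)
        if a.shape[0] != a.shape[1]:
            raise ValueError(f"a must be square, got {a.shape}")
        n = a.shape[0]
        if b.shape[0] != n:
            raise ValueError(f"b has {b.shape[0]} rows, expected {n}")
        if c.shape[1] != n:
            raise ValueError(f"c has {c.shape[1]} columns, expected {n}")
        if d.shape != (c.shape[0], b.shape[1]):
            raise ValueError(
                f"d has shape {d.shape}, expected {(c.shape[0], b.shape[1])}"
            )
        if not 0.0 < float(self.alpha) < 2.0:
            raise ValueError(f"alpha must lie in (0, 2), got {self.alpha}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "alpha", float(self.alpha))

    @property
    def n_states(self) -> int:
        return self.a.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.b.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.c.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of A (the poles of H in the s^alpha variable)."""
        return np.linalg.eigvals(self.a)

    def transfer(self, s_alpha: complex) -> np.ndarray:
        """Evaluate C (z I - A)^{-1} B + D at z = s^alpha (z given directly)."""
        n = self.n_states
        try:
            x = np.linalg.solve(s_alpha * np.eye(n) - self.a, self.b)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"resolvent singular at s^alpha = {s_alpha}"
            ) from exc
        return self.c @ x + self.d

    def frequency_point(self, omega: float) -> np.ndarray:
        """H(j*omega) using the principal branch of (j*omega)^alpha, omega >= 0."""
        if omega < 0:
            raise ValueError("omega must be >= 0; use conjugate symmetry for omega < 0")
        z = (1j * omega) ** self.alpha if omega > 0 else 0.0
        return self.transfer(z)

    def to_csv(self, directory: str | Path, prefix: str = "model") -> None:
        """Write A, B, C, D to ``<prefix>_{A,B,C,D}.csv`` in ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, mat in (("A", self.a), ("B", self.b), ("C", self.c), ("D", self.d)):
            np.savetxt(directory / f"{prefix}_{name}.csv", mat, delimiter=",")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "a": self.a.tolist(),
                "b": self.b.tolist(),
                "c": self.c.tolist(),
                "d": self.d.tolist(),
            }
        )


@dataclass(frozen=True)
class ClosedLoopSystem(FractionalStateModel):
    """Augmented closed loop with state ordering [x; w1; w2; x_err].

    ``x`` is the plant pseudo-state, ``w1``/``w2`` the two leaky-integrator
    states and ``x_err = x - x_hat`` the observer estimation error.  The
    input is the flow reference v and the output the delivered flow y.
    """

    state_labels: tuple[str, ...] = field(default=("x", "w1", "w2", "x_err"))
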