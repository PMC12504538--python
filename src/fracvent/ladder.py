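"""RC-ladder electrical analogue of the human respiratory tree.

The healthy human airway tree is approximated as 24 dichotomously
bifurcating generations.  Each generation m contributes a series
resistance R_m (airway resistance, kPa·s/l) and a shunt constant-phase
element — a "fractional capacitor" with impedance 1/(C_m s^alpha) —
representing the viscoelastic tissue compliance.  Because the flow
splits in two at every bifurcation, the per-generation values follow

    R_m = R*_m / 2^(m-1),      C_m = 2^(m-1) C*_m,

where the single-branch values R*_m, C*_m obey a two-block geometric
recursion: a factor pair (2.476, 0.577) for the conducting airways
(transitions m = 1..13) and (2.334, 0.613) for the acinar region
(transitions m = 14..23).  The root values R_UA, C_UA describe the upper
airways up to the trachea and were identified from forced-oscillation
data; the nominal set used throughout is

    R_UA = 0.2834 kPa·s/l,  C_UA = 0.0950 l·s^(alpha-1)/kPa,  alpha = 1.55.

Kirchhoff's laws on the ladder give the tridiagonal pseudo-state model
with the node pressures x_m as pseudo-states, the applied airway
pressure u as input, and the tracheal flow y = i_0 = (u - x_1)/R_1 as
output.  Generation indices are 1-based in all documentation and
reports; storage is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import json
import numpy as np

from .model import FractionalStateModel

__all__ = [
    "LadderParameters",
    "LadderNetwork",
    "build_ladder",
    "assemble_pseudo_state_space",
    "ladder_admittance",
    "scale_network",
    "nominal_parameters",
]

#: Block boundary of the recursion: the (2.476, 0.577) factor pair applies
#: to transitions m = 1..13, the (2.334, 0.613) pair to m = 14..23.
EARLY_BLOCK_END = 13


@dataclass(frozen=True)
class LadderParameters:
    """Root values and recursion factors of the respiratory-tree ladder."""

    r_ua: float = 0.2834  # upper-airway resistance, kPa*s/l
    c_ua: float = 0.0950  # upper-airway pseudo-capacitance, l*s^(alpha-1)/kPa
    alpha: float = 1.55  # fractional order of the tissue CPEs
    n_stages: int = 24  # airway generations
    ratio_r_early: float = 2.476
    ratio_c_early: float = 0.577
    ratio_r_late: float = 2.334
    ratio_c_late: float = 0.613
    early_block_end: int = EARLY_BLOCK_END

    def __post_init__(self) -> None:
        for name in ("r_ua", "c_ua", "ratio_r_early", "ratio_c_early",
                     "ratio_r_late", "ratio_c_late"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.alpha < 2.0:
            raise ValueError(f"alpha must lie in (0, 2), got {self.alpha}")
        if self.n_stages < 2:
            raise ValueError(f"n_stages must be >= 2, got {self.n_stages}")
        if self.early_block_end < 1:
            raise ValueError(
                f"early_block_end must be >= 1, got {self.early_block_end}"
            )


@dataclass(frozen=True)
class LadderNetwork:
    """Per-generation resistances and pseudo-capacitances (0-based storage)."""

    resistances: np.ndarray  # R_m, kPa*s/l
    capacitances: np.ndarray  # C_m, pseudo-capacitance units

    def __post_init__(self) -> None:
        r = np.asarray(self.resistances, dtype=float)
        c = np.asarray(self.capacitances, dtype=float)
        if r.ndim != 1 or c.ndim != 1 or r.shape != c.shape:
            raise ValueError("resistances and capacitances must be 1-D and equal length")
        if not (np.all(r > 0) and np.all(c > 0)):
            raise ValueError("all ladder entries must be strictly positive")
        object.__setattr__(self, "resistances", r)
        object.__setattr__(self, "capacitances", c)

    @property
    def n_stages(self) -> int:
        return self.resistances.size

    def to_json(self, alpha: float | None = None) -> str:
        """Per-generation table (1-based index m) as a JSON string."""
        rows = [
            {"generation": m + 1, "R": float(r), "C": float(c)}
            for m, (r, c) in enumerate(zip(self.resistances, self.capacitances))
        ]
        payload: dict = {"generations": rows}
        if alpha is not None:
            payload["alpha"] = alpha
        return json.dumps(payload, indent=2)


def nominal_parameters(**overrides) -> LadderParameters:
    """The nominal forced-oscillation parameter set (overridable per field)."""
    return replace(LadderParameters(), **overrides)


def build_ladder(params: LadderParameters) -> LadderNetwork:
    """Expand the two-block recursion into per-generation R_m, C_m values.

    The m-th generation (1-based) has R_m = R*_m / 2^(m-1) and
    C_m = 2^(m-1) C*_m with R*_1 = R_UA, C*_1 = C_UA.
    """
    n = params.n_stages
    r = np.empty(n)
    c = np.empty(n)
    r_star, c_star = params.r_ua, params.c_ua
    r[0], c[0] = r_star, c_star
    for m in range(1, n):  # transition from generation m to m+1 (1-based m)
        if m <= params.early_block_end:
            r_star *= params.ratio_r_early
            c_star *= params.ratio_c_early
        else:
            r_star *= params.ratio_r_late
            c_star *= params.ratio_c_late
        r[m] = r_star / 2.0**m
        c[m] = 2.0**m * c_star
    return LadderNetwork(resistances=r, capacitances=c)


def assemble_pseudo_state_space(
    network: LadderNetwork, alpha: float
) -> FractionalStateModel:
    """Kirchhoff nodal equations of the ladder as a tridiagonal (A, B, C, D).

    Row m balances the CPE current of node m against the branch currents
    i_{m-1} - i_m, with i_m = (x_m - x_{m+1})/R_{m+1}; the last node has no
    outgoing branch.  Consequently rows 2..N of A sum to zero and row 1
    sums to -1/(R_1 C_1) = -B_1: a constant input settles to x = u*1 with
    zero flow (the admittance zero at s = 0).
    """
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must lie in (0, 2), got {alpha}")
    r = network.resistances
    c = network.capacitances
    n = network.n_stages
    a = np.zeros((n, n))
    for i in range(n):  # 0-based node index
        a[i, i] = -1.0 / (r[i] * c[i])
        if i + 1 < n:
            a[i, i] -= 1.0 / (r[i + 1] * c[i])
            a[i, i + 1] = 1.0 / (r[i + 1] * c[i])
        if i > 0:
            a[i, i - 1] = 1.0 / (r[i] * c[i])
    b = np.zeros((n, 1))
    b[0, 0] = 1.0 / (r[0] * c[0])
    cmat = np.zeros((1, n))
    cmat[0, 0] = -1.0 / r[0]
    d = np.array([[1.0 / r[0]]])
    return FractionalStateModel(a=a, b=b, c=cmat, d=d, alpha=alpha)


def ladder_admittance(model: FractionalStateModel, omega: float) -> complex:
    """Input admittance Y(j*omega) = C ((j*omega)^alpha I - A)^{-1} B + D.

    Principal branch, omega >= 0; at omega = 0 this is C (-A)^{-1} B + D,
    which vanishes for any valid ladder (flow is zero at DC).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    return complex(model.frequency_point(omega)[0, 0])


def scale_network(
    network: LadderNetwork, rho_r: float, rho_c: float
) -> LadderNetwork:
    """Multiply every R_m by rho_r and every C_m by rho_c.

    All entries are linear in (R_UA, C_UA), so this is exactly a
    perturbation of the root parameters: the assembled matrices obey
    A -> A/(rho_r*rho_c), B -> B/(rho_r*rho_c), C -> C/rho_r, D -> D/rho_r.
    """
    if not rho_r > 0:
        raise ValueError(f"rho_r must be > 0, got {rho_r}")
    if not rho_c > 0:
        raise ValueError(f"rho_c must be > 0, got {rho_c}")
    return LadderNetwork(
        resistances=network.resistances * rho_r,
        capacitances=network.capacitances * rho_c,
    )
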