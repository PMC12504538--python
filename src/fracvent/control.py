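"""Output-feedback architecture: observer, double leaky integrator, closed loop.

The controller measures only the tracheal flow y and applies the airway
pressure u.  Its parts:

* a Luenberger pseudo-state observer
  D^a x_hat = A x_hat + B u + L (y - y_hat),  y_hat = C x_hat + D u;
* a double *leaky* fractional integrator driven by the tracking error,
  D^a w1 = (1 + K_r)(v - y) - eps*w1,  D^a w2 = w1 - eps*w2.
  Pure integrators would cancel the plant's admittance zero at s = 0 and
  destabilize the loop; the small leakage eps trades exact steady-state
  tracking for stability;
* the feedback law u = -K_x x_hat - K_w1 w1 - K_w2 w2.

In the coordinates [x; w1; w2; x_err] with x_err = x - x_hat, the nominal
closed loop is block upper-triangular, so its spectrum separates into the
observer spectrum eig(A - L C) and the state-feedback spectrum
eig(A_xwr - B_xwr K_xw) of the augmented plant

    A_xwr = [[A, 0, 0], [-(1+K_r) C, -eps I, 0], [0, I, -eps I]],
    B_xwr = [B; -(1+K_r) D; 0],      K_xw = [K_x, K_w1, K_w2].

The perturbed assembly keeps the gains at their nominal values but runs
the physical plant with perturbed matrices (Abar, Bbar, Cbar, Dbar);
the observer-mismatch terms then couple the error block back to the
plant block through Gamma = B + L (Dbar - D).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .lmi import (
    LmiFeasibility,
    synthesize_observer_gain,
    synthesize_state_feedback,
)
from .model import ClosedLoopSystem, FractionalStateModel
from .regions import SectorDiskRegion, max_sector_angle

__all__ = [
    "ControllerGains",
    "AugmentedPlant",
    "build_augmented_plant",
    "design_gains",
    "assemble_closed_loop",
    "assemble_perturbed_closed_loop",
    "printed_gains_fixture",
]


@dataclass(frozen=True)
class ControllerGains:
    """All adjustable gains of the output-feedback law.

    ``epsilon`` may be a scalar (the default tuning, one leakage constant
    for both integrators) or a pair (eps1, eps2).
    """

    k_x: np.ndarray  # 1 x n
    k_w1: float
    k_w2: float
    k_r: float
    l_gain: np.ndarray  # n x 1
    epsilon: float | tuple[float, float]

    def __post_init__(self) -> None:
        k_x = np.atleast_2d(np.asarray(self.k_x, dtype=float))
        l_gain = np.asarray(self.l_gain, dtype=float).reshape(-1, 1)
        if k_x.shape[0] != 1:
            raise ValueError(f"k_x must be a row vector, got shape {k_x.shape}")
        if k_x.shape[1] != l_gain.shape[0]:
            raise ValueError(
                f"k_x ({k_x.shape[1]}) and l_gain ({l_gain.shape[0]}) disagree on n"
            )
        eps = self.epsilon
        eps_pair = (float(eps), float(eps)) if np.isscalar(eps) else (float(eps[0]), float(eps[1]))
        if not (eps_pair[0] > 0 and eps_pair[1] > 0):
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        object.__setattr__(self, "k_x", k_x)
        object.__setattr__(self, "l_gain", l_gain)
        object.__setattr__(self, "k_w1", float(self.k_w1))
        object.__setattr__(self, "k_w2", float(self.k_w2))
        object.__setattr__(self, "k_r", float(self.k_r))

    @property
    def n_states(self) -> int:
        return self.k_x.shape[1]

    @property
    def eps_pair(self) -> tuple[float, float]:
        eps = self.epsilon
        if np.isscalar(eps):
            return float(eps), float(eps)
        return float(eps[0]), float(eps[1])

    @property
    def k_xw(self) -> np.ndarray:
        """Concatenated [K_x, K_w1, K_w2] row (the augmented-plant gain)."""
        return np.hstack([self.k_x, [[self.k_w1]], [[self.k_w2]]])

    def to_json(self) -> str:
        return json.dumps(
            {
                "k_x": self.k_x.ravel().tolist(),
                "k_w1": self.k_w1,
                "k_w2": self.k_w2,
                "k_r": self.k_r,
                "l_gain": self.l_gain.ravel().tolist(),
                "epsilon": list(self.eps_pair),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ControllerGains":
        data = json.loads(text)
        eps = data["epsilon"]
        eps_val = eps[0] if eps[0] == eps[1] else tuple(eps)
        return cls(
            k_x=np.asarray(data["k_x"]),
            k_w1=data["k_w1"],
            k_w2=data["k_w2"],
            k_r=data["k_r"],
            l_gain=np.asarray(data["l_gain"]),
            epsilon=eps_val,
        )


@dataclass(frozen=True)
class AugmentedPlant:
    """Plant + double leaky integrator, the synthesis target for K_xw."""

    a_xwr: np.ndarray
    b_xwr: np.ndarray

    @property
    def n_states(self) -> int:
        return self.a_xwr.shape[0]


def build_augmented_plant(
    model: FractionalStateModel, k_r: float, epsilon: float | tuple[float, float]
) -> AugmentedPlant:
    """Assemble (A_xwr, B_xwr) for the error-driven integrator chain."""
    eps1, eps2 = (epsilon, epsilon) if np.isscalar(epsilon) else epsilon
    if eps1 < 0 or eps2 < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    n, q, p = model.n_states, model.n_outputs, model.n_inputs
    if q != p:
        raise ValueError("integral augmentation requires q == p")
    dim = n + 2 * q
    a = np.zeros((dim, dim))
    a[:n, :n] = model.a
    a[n:n + q, :n] = -(1.0 + k_r) * model.c
    a[n:n + q, n:n + q] = -eps1 * np.eye(q)
    a[n + q:, n:n + q] = np.eye(q)
    a[n + q:, n + q:] = -eps2 * np.eye(q)
    b = np.zeros((dim, p))
    b[:n] = model.b
    b[n:n + q] = -(1.0 + k_r) * model.d
    return AugmentedPlant(a_xwr=a, b_xwr=b)


def design_gains(
    model: FractionalStateModel,
    region_ctrl: SectorDiskRegion,
    region_obs: SectorDiskRegion | None = None,
    k_r: float = 500.0,
    epsilon: float | tuple[float, float] = 0.1,
    **solver_options,
) -> tuple[ControllerGains, dict[str, LmiFeasibility]]:
    """End-to-end gain design: K_xw on the augmented plant, L by duality.

    The observer region defaults to the controller region.  Sector angles
    exceeding the F(alpha)-containment bound are rejected before any
    solve; both syntheses are post-verified in their regions.
    """
    if region_obs is None:
        region_obs = region_ctrl
    theta_max = max_sector_angle(model.alpha)
    for name, reg in (("controller", region_ctrl), ("observer", region_obs)):
        if reg.theta > theta_max + 1e-12:
            raise ValueError(
                f"{name} sector angle {np.rad2deg(reg.theta):.2f} deg exceeds the "
                f"stability-containment bound {np.rad2deg(theta_max):.2f} deg "
                f"for alpha = {model.alpha}"
            )
    plant = build_augmented_plant(model, k_r, epsilon)
    k_xw, feas_ctrl = synthesize_state_feedback(
        plant.a_xwr, plant.b_xwr, region_ctrl, **solver_options
    )
    n = model.n_states
    l_gain, feas_obs = synthesize_observer_gain(
        model.a, model.c, region_obs, **solver_options
    )
    gains = ControllerGains(
        k_x=k_xw[:, :n],
        k_w1=float(k_xw[0, n]),
        k_w2=float(k_xw[0, n + 1]),
        k_r=k_r,
        l_gain=l_gain,
        epsilon=epsilon,
    )
    return gains, {"controller": feas_ctrl, "observer": feas_obs}


def _check_dims(model: FractionalStateModel, gains: ControllerGains) -> None:
    if gains.n_states != model.n_states:
        raise ValueError(
            f"gain dimension {gains.n_states} does not match plant order "
            f"{model.n_states}"
        )
    if model.n_inputs != 1 or model.n_outputs != 1:
        raise ValueError("closed-loop assembly implemented for SISO plants")


def assemble_closed_loop(
    model: FractionalStateModel, gains: ControllerGains
) -> ClosedLoopSystem:
    """Nominal closed loop in the coordinates [x; w1; w2; x_err]."""
    return assemble_perturbed_closed_loop(model, model, gains)


def assemble_perturbed_closed_loop(
    model_nominal: FractionalStateModel,
    model_perturbed: FractionalStateModel,
    gains: ControllerGains,
) -> ClosedLoopSystem:
    """Closed loop with nominal gains acting on a perturbed physical plant.

    With model_perturbed == model_nominal the observer-mismatch row
    vanishes and the block upper-triangular nominal form is recovered
    exactly.
    """
    _check_dims(model_nominal, gains)
    _check_dims(model_perturbed, gains)
    if model_nominal.alpha != model_perturbed.alpha:
        raise ValueError("nominal and perturbed models must share alpha")
    a, b, c, d = model_nominal.a, model_nominal.b, model_nominal.c, model_nominal.d
    ab, bb, cb, db = (
        model_perturbed.a,
        model_perturbed.b,
        model_perturbed.c,
        model_perturbed.d,
    )
    n = model_nominal.n_states
    kx = gains.k_x
    kw1, kw2, kr = gains.k_w1, gains.k_w2, gains.k_r
    l_gain = gains.l_gain
    eps1, eps2 = gains.eps_pair
    gamma = b + l_gain @ (db - d)
    b_mg = bb - gamma  # Bbar - Gamma; zero when D is unperturbed and B matches
    a_lc = a - l_gain @ c
    onekr = 1.0 + kr
    dim = 2 * n + 2
    acl = np.zeros((dim, dim))
    # plant row
    acl[:n, :n] = ab - bb @ kx
    acl[:n, n] = (-bb * kw1).ravel()
    acl[:n, n + 1] = (-bb * kw2).ravel()
    acl[:n, n + 2:] = bb @ kx
    # w1 row
    acl[n, :n] = (onekr * (db @ kx - cb)).ravel()
    acl[n, n] = onekr * db[0, 0] * kw1 - eps1
    acl[n, n + 1] = onekr * db[0, 0] * kw2
    acl[n, n + 2:] = (-onekr * db @ kx).ravel()
    # w2 row
    acl[n + 1, n] = 1.0
    acl[n + 1, n + 1] = -eps2
    # estimation-error row (vanishes off-diagonal in the nominal case)
    acl[n + 2:, :n] = (ab - l_gain @ cb) - a_lc - b_mg @ kx
    acl[n + 2:, n] = (-b_mg * kw1).ravel()
    acl[n + 2:, n + 1] = (-b_mg * kw2).ravel()
    acl[n + 2:, n + 2:] = a_lc + b_mg @ kx
    bcl = np.zeros((dim, 1))
    bcl[n, 0] = onekr
    ccl = np.zeros((1, dim))
    ccl[0, :n] = (cb - db @ kx).ravel()
    ccl[0, n] = -db[0, 0] * kw1
    ccl[0, n + 1] = -db[0, 0] * kw2
    ccl[0, n + 2:] = (db @ kx).ravel()
    dcl = np.zeros((1, 1))
    return ClosedLoopSystem(
        a=acl, b=bcl, c=ccl, d=dcl, alpha=model_nominal.alpha
    )


# Gains of the published nominal design (r = 200, theta = 5 deg, K_r = 500,
# eps = 0.1), stored exactly as printed (5-decimal truncation).  LMI
# solutions are not unique, so these serve as a reference fixture rather
# than a synthesis target.
_KXW_PRINTED = (
    -0.99901, -0.00031, -0.00012, -0.00004, 0.00004, 0.00011, 0.00019,
    0.00027, 0.00034, 0.00040, 0.00048, 0.00060, 0.00076, 0.00099, 0.00138,
    0.00192, 0.00271, 0.00380, 0.00536, 0.00779, 0.01124, 0.01621, 0.02344,
    0.03094, -0.07292, -0.03209,
)
_L_PRINTED = (
    -22.0649, -7.3574, -5.1895, -3.8840, -3.0859, -2.5175, -2.0254, -1.7129,
    -1.4046, -1.0638, -0.7863, -0.5355, -0.2966, -0.1130, 0.0018, 0.0898,
    0.0625, -0.0085, -0.0781, -0.1399, -0.1727, -0.1766, -0.1854, -0.2080,
)


def printed_gains_fixture() -> ControllerGains:
    """The published 24-state design gains (K_r = 500, eps = 0.1)."""
    k_xw = np.asarray(_KXW_PRINTED)
    return ControllerGains(
        k_x=k_xw[:24].reshape(1, -1),
        k_w1=float(k_xw[24]),
        k_w2=float(k_xw[25]),
        k_r=500.0,
        l_gain=np.asarray(_L_PRINTED).reshape(-1, 1),
        epsilon=0.1,
    )
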