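"""D-stability analysis and gain synthesis in the S(r, theta) region.

The region S(r, theta) — origin-centred disk of radius r intersected
with the left cone of half-angle theta — is an LMI region: the matrix A
has all eigenvalues inside S iff there is X = X^T ≻ 0 with

    [[-r X, A X], [X A^T, -r X]] ≺ 0,
    [[(AX+XA^T) sin t, (AX-XA^T) cos t],
     [(-AX+XA^T) cos t, (AX+XA^T) sin t]] ≺ 0.

Replacing A X by A X - B M and recovering K = M X^{-1} turns the same
pair of LMIs into a state-feedback synthesis condition for A - B K; the
observer gain is obtained from the dual pair (A^T, C^T).  Feasibility is
decided by the in-package spectral engine; every returned gain is
post-verified against the direct eigenvalue region test, and every
feasibility verdict carries a certificate X checked by an exact
maximum-eigenvalue computation on the assembled LMIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_continuous_are
from scipy.signal import place_poles

from ._spectral import (
    SpectralResult,
    equalized_certificate,
    lmi_max_eigenvalue,
    spectral_solve,
)
from .regions import SectorDiskRegion, region_membership

__all__ = [
    "LmiFeasibility",
    "LmiInfeasibleError",
    "LmiInconclusiveError",
    "PostVerificationError",
    "check_dstability_lmi",
    "synthesize_state_feedback",
    "synthesize_observer_gain",
    "is_controllable",
]


class LmiInfeasibleError(RuntimeError):
    """The synthesis LMIs admit no solution (e.g. unmovable mode outside S)."""


class LmiInconclusiveError(RuntimeError):
    """The solver could not certify feasibility or infeasibility."""


class PostVerificationError(RuntimeError):
    """A solver-accepted gain failed the eigenvalue region check."""


@dataclass
class LmiFeasibility:
    """Outcome of an LMI feasibility problem, with audit certificates."""

    status: str  # "feasible" | "infeasible" | "inconclusive"
    x_matrix: np.ndarray | None = None
    m_matrix: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("feasible", "infeasible", "inconclusive"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "feasible":
            if self.x_matrix is None:
                raise ValueError("feasible result requires a certificate X")
            lo = float(np.linalg.eigvalsh(self.x_matrix).min())
            if lo <= 0:
                raise ValueError(f"certificate X is not positive definite (min eig {lo})")

    def to_json(self) -> str:
        payload = {"status": self.status, "diagnostics": _jsonable(self.diagnostics)}
        if self.x_matrix is not None:
            payload["x_matrix"] = self.x_matrix.tolist()
        if self.m_matrix is not None:
            payload["m_matrix"] = self.m_matrix.tolist()
        return json.dumps(payload, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def check_dstability_lmi(
    a_matrix: np.ndarray, region: SectorDiskRegion, **solver_options
) -> LmiFeasibility:
    """Solve the two coupled Lemma-1 LMIs in X for ``a_matrix``.

    Feasible verdicts carry an exactly verified certificate X.  A fast
    constructive route (eigenvector-based X) is attempted first; the
    spectral minimization decides the remaining cases.  Solver failure
    yields status "inconclusive" with diagnostics, never a silent pass.
    """
    a = np.atleast_2d(np.asarray(a_matrix, dtype=float))
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"a_matrix must be square, got {a.shape}")
    x = equalized_certificate(a, region)
    if x is not None:
        value = lmi_max_eigenvalue(a, x, region)
        if value < 0:
            return LmiFeasibility(
                status="feasible",
                x_matrix=x,
                diagnostics={"route": "certificate", "lmi_max": value},
            )
    result: SpectralResult = spectral_solve(a, region, **solver_options)
    return LmiFeasibility(
        status=result.status,
        x_matrix=result.x,
        m_matrix=None,
        diagnostics={"lmi_max": result.lmi_max, **result.diagnostics},
    )


def is_controllable(a_matrix: np.ndarray, b_matrix: np.ndarray) -> bool:
    """Controllability via the eigenvector (PBH) test.

    (A, B) is controllable iff rank [A - lambda I, B] = n at every
    eigenvalue lambda, decided through the smallest singular value with
    threshold n * sigma_max * machine epsilon.  This is equivalent to the
    Kalman rank test but remains decidable in double precision for stiff
    spectra (the controllability matrix of the 24-stage ladder spans
    ~40 decades and defeats any direct rank computation).
    """
    a = np.atleast_2d(np.asarray(a_matrix, dtype=float))
    b = np.atleast_2d(np.asarray(b_matrix, dtype=float))
    n = a.shape[0]
    if a.shape[0] != a.shape[1] or b.shape[0] != n:
        raise ValueError("inconsistent dimensions for controllability test")
    for lam in np.linalg.eigvals(a):
        pencil = np.hstack([a - lam * np.eye(n), b]).astype(complex)
        sv = np.linalg.svd(pencil, compute_uv=False)
        if sv[0] == 0.0 or sv[-1] <= n * sv[0] * np.finfo(float).eps:
            return False
    return True


def _lqr_gain(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray | None:
    p_dim = b.shape[1]
    try:
        p = solve_continuous_are(a, b, np.eye(a.shape[0]), rho * np.eye(p_dim))
    except Exception:
        return None
    return np.linalg.solve(rho * np.eye(p_dim), b.T @ p)


def _placement_gain(
    a: np.ndarray, b: np.ndarray, region: SectorDiskRegion
) -> np.ndarray | None:
    n = a.shape[0]
    r = region.radius
    targets = -np.geomspace(0.02 * r, 0.8 * r, n)  # real, strictly inside S
    try:
        res = place_poles(a, b, np.sort(targets))
    except Exception:
        return None
    return res.gain_matrix


def _candidate_gains(a, b, region):
    """Heuristic region-placing gains, certified downstream via Lemma 1."""
    for rho in (1e4, 1e2, 1.0, 1e-2, 1e6):
        k = _lqr_gain(a, b, rho)
        if k is not None:
            yield k, f"lqr(rho={rho:g})"
    k = _placement_gain(a, b, region)
    if k is not None:
        yield k, "pole_placement"
    yield np.zeros((b.shape[1], a.shape[0])), "zero_gain"


def synthesize_state_feedback(
    a_matrix: np.ndarray,
    b_matrix: np.ndarray,
    region: SectorDiskRegion,
    **solver_options,
) -> tuple[np.ndarray, LmiFeasibility]:
    """Theorem-2 synthesis: K = M X^{-1} placing eig(A - B K) inside S(r, theta).

    The spectral LMI solve is attempted first; if its margin is below the
    solver's resolution (spectra spanning many decades do this), heuristic
    region-placing gains are certified through the constructive Lemma-1
    certificate with M = K X.  The returned gain always passes the direct
    eigenvalue post-verification; its failure raises even if a solver
    accepted the solution.
    """
    a = np.atleast_2d(np.asarray(a_matrix, dtype=float))
    b = np.atleast_2d(np.asarray(b_matrix, dtype=float))
    if a.shape[0] != a.shape[1] or b.shape[0] != a.shape[0]:
        raise ValueError(f"inconsistent dimensions: A {a.shape}, B {b.shape}")
    result = spectral_solve(a, region, b=b, **solver_options)
    if result.status == "feasible":
        k = result.m @ np.linalg.inv(result.x)
        feas = LmiFeasibility(
            status="feasible",
            x_matrix=result.x,
            m_matrix=result.m,
            diagnostics={"lmi_max": result.lmi_max, **result.diagnostics},
        )
        _post_verify(a - b @ k, region)
        return k, feas
    for k, route in _candidate_gains(a, b, region):
        closed = a - b @ k
        if not region_membership(np.linalg.eigvals(closed), region).all():
            continue
        x = equalized_certificate(closed, region)
        if x is None:
            continue
        m = k @ x
        value = lmi_max_eigenvalue(a, x, region, b, m)
        if value >= 0:
            continue
        feas = LmiFeasibility(
            status="feasible",
            x_matrix=x,
            m_matrix=m,
            diagnostics={"route": route, "lmi_max": value},
        )
        _post_verify(closed, region)
        return k, feas
    if result.status == "infeasible":
        raise LmiInfeasibleError(
            "synthesis LMIs are infeasible for the requested region "
            f"(residual {result.lmi_max:.3e}); the pair may have a fixed mode "
            "outside S(r, theta)"
        )
    raise LmiInconclusiveError(
        f"LMI solver could not certify a verdict (residual {result.lmi_max:.3e}); "
        "try a larger region or looser solver margins"
    )


def _post_verify(closed: np.ndarray, region: SectorDiskRegion) -> None:
    ev = np.linalg.eigvals(closed)
    if not region_membership(ev, region).all():
        disk, sector = region.membership_margins(ev)
        raise PostVerificationError(
            "synthesized gain failed the eigenvalue region check "
            f"(worst disk margin {disk.max():.3e}, worst sector margin "
            f"{sector.max():.3e}); increase the solver margin"
        )


def synthesize_observer_gain(
    a_matrix: np.ndarray,
    c_matrix: np.ndarray,
    region: SectorDiskRegion,
    **solver_options,
) -> tuple[np.ndarray, LmiFeasibility]:
    """Observer gain L with eig(A - L C) inside S(r, theta), by duality.

    Applies the state-feedback synthesis to (A^T, C^T) and transposes:
    spectrum(A - L C) = spectrum(A^T - C^T L^T).
    """
    a = np.atleast_2d(np.asarray(a_matrix, dtype=float))
    c = np.atleast_2d(np.asarray(c_matrix, dtype=float))
    if a.shape[0] != a.shape[1] or c.shape[1] != a.shape[0]:
        raise ValueError(f"inconsistent dimensions: A {a.shape}, C {c.shape}")
    k_dual, feas = synthesize_state_feedback(a.T, c.T, region, **solver_options)
    return k_dual.T, feas
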