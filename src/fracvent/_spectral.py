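"""Internal LMI feasibility engine for the disk∩sector region.

Two complementary routes, both certified by an exact maximum-eigenvalue
check of the assembled LMIs:

* ``spectral_solve`` — the analysis/synthesis LMIs are linear in (X, M),
  so strict feasibility is equivalent to inf of

      f(X, M) = lambda_max( blkdiag(F_disk, F_sector, delta*I - X) )

  being negative (the problem is homogeneous of degree one in (X, M);
  the delta*I - X block fixes the scale).  f is convex; it is minimized
  through its log-sum-exp smoothing (1/tau) log sum exp(tau*lambda_i)
  with an analytic gradient, under a tau continuation schedule.  A point
  with exact f < 0 is a feasibility certificate; a converged minimum
  that stays clearly positive certifies infeasibility up to the
  smoothing gap log(m)/tau.

* ``equalized_certificate`` — the constructive direction of the
  D-stability lemma: if A is diagonalizable as V diag(lambda) V^{-1}
  with every eigenvalue strictly inside S(r, theta), then
  X = V diag(s) V^H (real for real A, conjugate pairs merging) satisfies
  the region LMIs, because the LMI value is congruent to a direct sum of
  the scalar characteristic functions f_D(lambda_i) * s_i.  Scaling
  s_i = 1/|margin_i| equalizes the per-mode margins, which keeps the
  certificate numerically verifiable even when the spectrum spans many
  decades (the lung ladder covers ~1e-4 .. 1e2 rad^alpha/s).  The route
  fails gracefully (returns None) for defective or badly conditioned
  eigenvector matrices and the caller falls back to ``spectral_solve``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eig
from scipy.optimize import minimize

from .regions import SectorDiskRegion

__all__ = [
    "SpectralResult",
    "assemble_region_lmis",
    "lmi_max_eigenvalue",
    "equalized_certificate",
    "spectral_solve",
]


@dataclass
class SpectralResult:
    status: str  # "feasible" | "infeasible" | "inconclusive"
    x: np.ndarray | None
    m: np.ndarray | None
    lmi_max: float  # exact lambda_max of the assembled LMIs at the returned point
    diagnostics: dict = field(default_factory=dict)


def assemble_region_lmis(
    a: np.ndarray,
    x: np.ndarray,
    region: SectorDiskRegion,
    b: np.ndarray | None = None,
    m: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disk and sector LMI matrices for A (analysis) or (A, B, M) (synthesis).

    With H = A X - B M (H = A X when B is None), the blocks are
    [[-r X, H], [H^T, -r X]] and
    [[ (H+H^T) sin t, (H-H^T) cos t ], [ -(H-H^T) cos t, (H+H^T) sin t ]].
    """
    h = a @ x
    if b is not None and m is not None:
        h = h - b @ m
    r, th = region.radius, region.theta
    s, c = np.sin(th), np.cos(th)
    hs, ha = h + h.T, h - h.T
    disk = np.block([[-r * x, h], [h.T, -r * x]])
    sector = np.block([[s * hs, c * ha], [-c * ha, s * hs]])
    return disk, sector


def lmi_max_eigenvalue(
    a: np.ndarray,
    x: np.ndarray,
    region: SectorDiskRegion,
    b: np.ndarray | None = None,
    m: np.ndarray | None = None,
) -> float:
    """Exact lambda_max over both region LMIs (negative iff both hold strictly)."""
    disk, sector = assemble_region_lmis(a, x, region, b, m)
    return float(
        max(np.linalg.eigvalsh(disk).max(), np.linalg.eigvalsh(sector).max())
    )


def equalized_certificate(
    a_closed: np.ndarray, region: SectorDiskRegion, cond_limit: float = 1e10
) -> np.ndarray | None:
    """Eigenvector-based X ≻ 0 verifying the region LMIs for ``a_closed``.

    Returns None when some eigenvalue is not strictly inside the region or
    the eigenvector matrix is too ill-conditioned (defective A).  The
    caller is responsible for the final exact verification.
    """
    lam, v = eig(a_closed)
    disk_m, sector_m = region.membership_margins(lam)
    worst = np.maximum(disk_m, sector_m)
    if worst.max() >= 0:
        return None
    if np.linalg.cond(v) > cond_limit:
        return None
    s = 1.0 / (-worst)
    x = (v * s) @ v.conj().T
    x = np.real(0.5 * (x + x.conj().T))
    lo = np.linalg.eigvalsh(x).min()
    if lo <= 0:
        return None
    return x / lo  # smallest eigenvalue normalized to 1


def _smoothed_value_grad(
    v: np.ndarray,
    a: np.ndarray,
    b: np.ndarray | None,
    region: SectorDiskRegion,
    delta: float,
    tau: float,
) -> tuple[float, np.ndarray]:
    """Log-sum-exp smoothed max eigenvalue over the LMI blocks, with gradient."""
    n = a.shape[0]
    p = b.shape[1] if b is not None else 0
    x = v[: n * n].reshape(n, n)
    x = 0.5 * (x + x.T)
    m = v[n * n:].reshape(p, n) if p else None
    disk, sector = assemble_region_lmis(a, x, region, b, m)
    ed, ud = np.linalg.eigh(disk)
    es, us = np.linalg.eigh(sector)
    ex, ux = np.linalg.eigh(delta * np.eye(n) - x)
    vals = np.concatenate([ed, es, ex])
    top = vals.max()
    w = np.exp(tau * (vals - top))
    z = w.sum()
    f = top + np.log(z) / tau
    wd, ws, wx = w[: 2 * n] / z, w[2 * n: 4 * n] / z, w[4 * n:] / z
    pd = (ud * wd) @ ud.T
    ps = (us * ws) @ us.T
    px = (ux * wx) @ ux.T
    r, th = region.radius, region.theta
    s_t, c_t = np.sin(th), np.cos(th)
    # disk [[-rX, H],[H^T, -rX]]: d f = -r<P11+P22, dX> + 2<P12, dH>
    gx = -r * (pd[:n, :n] + pd[n:, n:])
    gh = 2.0 * pd[:n, n:]
    # sector blocks in terms of H±H^T
    q11, q12, q22 = ps[:n, :n], ps[:n, n:], ps[n:, n:]
    gh = gh + 2.0 * s_t * (q11 + q22) + 2.0 * c_t * (q12 - q12.T)
    # positivity block delta*I - X
    gx = gx - px
    gx_total = gx + a.T @ gh
    gx_total = 0.5 * (gx_total + gx_total.T)
    if p:
        gm = -(b.T @ gh)
        grad = np.concatenate([gx_total.ravel(), gm.ravel()])
    else:
        grad = gx_total.ravel()
    return f, grad


def spectral_solve(
    a: np.ndarray,
    region: SectorDiskRegion,
    b: np.ndarray | None = None,
    delta: float = 1e-3,
    taus: tuple[float, ...] = (16.0, 128.0, 1024.0, 8192.0, 65536.0),
    maxiter: int = 600,
    feas_tol: float = 1e-9,
    infeas_tol: float = 1e-7,
) -> SpectralResult:
    """Minimize the smoothed LMI max-eigenvalue; decide feasibility.

    The problem is rescaled internally so the disk has unit radius and the
    input column(s) unit norm; certificates are mapped back to the
    original LMIs before the exact verification.
    """
    r = region.radius
    scaled_region = SectorDiskRegion(radius=1.0, theta=region.theta)
    a_s = a / r
    n = a.shape[0]
    if b is not None:
        beta = np.linalg.norm(b)
        if beta == 0:
            beta = 1.0
        b_s = b / (r * beta)
        p = b.shape[1]
    else:
        beta = 1.0
        b_s = None
        p = 0
    v = np.concatenate([np.eye(n).ravel(), np.zeros(p * n)])
    history = []
    fe = np.inf
    for tau in taus:
        res = minimize(
            _smoothed_value_grad,
            v,
            args=(a_s, b_s, scaled_region, delta, tau),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-13},
        )
        v = res.x
        x_s = v[: n * n].reshape(n, n)
        x_s = 0.5 * (x_s + x_s.T)
        m_s = v[n * n:].reshape(p, n) if p else None
        fe = lmi_max_eigenvalue(a_s, x_s, scaled_region, b_s, m_s)
        fe = max(fe, float(delta - np.linalg.eigvalsh(x_s).min()))
        history.append({"tau": tau, "smoothed": float(res.fun), "exact": fe,
                        "iterations": int(res.nit)})
        if fe < -feas_tol:
            break
    x_s = v[: n * n].reshape(n, n)
    x_s = 0.5 * (x_s + x_s.T)
    m_s = v[n * n:].reshape(p, n) if p else None
    if fe < -feas_tol:
        # map back: X unchanged, M = M_s / beta solves the original LMIs
        x_out = x_s
        m_out = m_s / beta if p else None
        return SpectralResult(
            status="feasible",
            x=x_out,
            m=m_out,
            lmi_max=lmi_max_eigenvalue(a, x_out, region, b, m_out),
            diagnostics={"route": "spectral", "history": history},
        )
    status = "infeasible" if fe > infeas_tol else "inconclusive"
    return SpectralResult(
        status=status,
        x=None,
        m=None,
        lmi_max=fe,
        diagnostics={"route": "spectral", "history": history,
                     "note": "exact value is for the rescaled problem"},
    )
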