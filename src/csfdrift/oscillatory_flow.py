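"""Leading-order oscillatory lubrication flow in the compliant canal.

The intracranial pressure fluctuation drives a harmonic lubrication flow
through the annular canal, accommodated by the elastic displacement of the
dura.  All leading-order fields are time-harmonic,

    u0 = Re(i e^{it} U),   v0 = Re(i e^{it} V),   w0 = Re(i e^{it} W),
    p0' = Re(e^{it} P'),   phat0 = Re(e^{it} Phat),   h0' = Re(e^{it} H'),

with complex amplitudes depending on (x, eta, s).  The axial momentum
balance reduces, per transverse column, to the Womersley channel problem

    U + (i / (alpha^2 hbar^2)) d2U/deta2 = dP'/dx,   U(0) = U(1) = 0,

whose closed form is a cosh profile; the axial pressure amplitude P'(x)
satisfies a second-order two-point boundary-value problem expressing mass
conservation of the section-integrated flux against the wall motion
H' = gamma (1 + k^2 P'), with P'(0) = 0 at the open entrance and zero net
axial flux at the closed end x = 1.  The azimuthal pressure amplitude
Phat(x, s) closes the azimuthal flux balance periodically in s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from ._fd import (
    cumtrapz0,
    cumtrapz0_periodic,
    ddx,
    dds_periodic,
    trapz,
    trapz_periodic,
)
from .geometry import CanalGeometry, Grid3D

__all__ = [
    "OscillatoryFlowSolution",
    "SolverError",
    "axial_profile",
    "axial_profile_bvp",
    "womersley_profile_factor",
    "flux_factor",
    "solve_pressure_bvp",
    "assemble_solution",
]

_SQRT_I = np.exp(1j * np.pi / 4.0)  # sqrt(i), principal branch


class SolverError(RuntimeError):
    """The discrete lubrication operator is singular or ill-posed."""


def _Lambda(alpha: float, h_bar: np.ndarray | float) -> np.ndarray | float:
    """Complex transverse decay rate Lambda = alpha * hbar * sqrt(i)."""
    return alpha * np.asarray(h_bar) * _SQRT_I


def womersley_profile_factor(eta: np.ndarray, alpha: float, h_bar) -> np.ndarray:
    """G(eta) with U = (dP'/dx) G: Womersley-type channel profile.

    G = 1 - cosh(Lambda (eta - 1/2)) / cosh(Lambda / 2), Lambda = alpha hbar sqrt(i).
    Broadcasts over an (x, s)-shaped ``h_bar`` against a 1-D ``eta``.
    """
    lam = _Lambda(alpha, h_bar)
    lam = np.asarray(lam)[..., np.newaxis] if np.ndim(lam) else lam
    e = np.asarray(eta)
    return 1.0 - np.cosh(lam * (e - 0.5)) / np.cosh(lam * 0.5)


def womersley_cumulative_factor(eta: np.ndarray, alpha: float, h_bar) -> np.ndarray:
    """g(eta) = int_0^eta G, closed form (used for V and depth fluxes)."""
    lam = _Lambda(alpha, h_bar)
    lam = np.asarray(lam)[..., np.newaxis] if np.ndim(lam) else lam
    e = np.asarray(eta)
    return e - (np.sinh(lam * (e - 0.5)) + np.sinh(lam * 0.5)) / (lam * np.cosh(lam * 0.5))


def flux_factor(alpha: float, h_bar) -> np.ndarray:
    """Q(hbar) = int_0^1 G deta = 1 - tanh(Lambda/2) / (Lambda/2)."""
    half = 0.5 * _Lambda(alpha, h_bar)
    return 1.0 - np.tanh(half) / half


def axial_profile(
    dPdx: complex, h_bar: float, alpha: float, eta: np.ndarray
) -> np.ndarray:
    """Complex axial velocity amplitude U(eta) for one transverse column."""
    if not (h_bar > 0 and alpha > 0):
        raise ValueError("h_bar and alpha must be positive")
    return dPdx * womersley_profile_factor(np.asarray(eta), alpha, h_bar)


def axial_profile_bvp(
    dPdx: complex, h_bar: float, alpha: float, eta: np.ndarray
) -> np.ndarray:
    """Numerical fallback for :func:`axial_profile`.

    Solves U + (i/(alpha^2 hbar^2)) U'' = dP'/dx with U(0)=U(1)=0 by
    second-order finite differences on the supplied eta grid.
    """
    eta = np.asarray(eta, dtype=float)
    n = eta.size
    d = eta[1] - eta[0]
    coef = 1j / (alpha**2 * h_bar**2)
    ab = np.zeros((3, n), dtype=complex)
    ab[1, :] = 1.0 - 2.0 * coef / d**2
    ab[0, 1:] = coef / d**2
    ab[2, :-1] = coef / d**2
    rhs = np.full(n, dPdx, dtype=complex)
    # Dirichlet ends
    ab[1, 0] = ab[1, -1] = 1.0
    ab[0, 1] = ab[2, -2] = 0.0
    rhs[0] = rhs[-1] = 0.0
    return solve_banded((1, 1), ab, rhs)


@dataclass(frozen=True)
class OscillatoryFlowSolution:
    """Complex harmonic amplitudes of the leading-order pulsatile flow."""

    geometry: CanalGeometry
    grid: Grid3D
    alpha: float
    k: float
    U: np.ndarray  # (Nx, Neta, Ns)
    V: np.ndarray  # (Nx, Neta, Ns)
    W: np.ndarray  # (Nx, Neta, Ns)
    P_prime: np.ndarray  # (Nx,)
    P_hat: np.ndarray  # (Nx, Ns), gauge P_hat(x, 0) = 0
    P_hat_s: np.ndarray  # (Nx, Ns): dP_hat/ds
    H_prime: np.ndarray  # (Nx, Ns)

    def axial_flux_amplitude(self) -> np.ndarray:
        """Complex amplitude of the net axial volume flux at each x."""
        geom = self.geometry
        depth = trapz(self.U, self.grid.deta, axis=1)  # (Nx, Ns)
        return geom.ell * trapz_periodic(geom.h_bar * depth, geom.ds, axis=1)


def solve_pressure_bvp(
    geometry: CanalGeometry, alpha: float, k: float, grid: Grid3D | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pressure and wall amplitudes: (P', dPhat/ds, Phat, H' on x).

    P'(x) solves  d/dx[ a(x) dP'/dx ] + ell gamma (1 + k^2 P') = 0  with
    a(x) = ell int_0^1 hbar Q(hbar) ds, P'(0) = 0, dP'/dx(1) = 0 (zero net
    axial flux at the closed end).  Phat(x, s) closes the azimuthal flux
    balance with s-periodicity.
    """
    grid = grid or Grid3D(Nx=geometry.Nx, Ns=geometry.Ns)
    x, dx, ds = geometry.x, geometry.dx, geometry.ds
    h, ell, gamma = geometry.h_bar, geometry.ell, geometry.gamma
    n = x.size

    hQ = h * flux_factor(alpha, h)  # (Nx, Ns)
    a = ell * trapz_periodic(hQ, ds, axis=1)  # (Nx,) complex
    b = ell * gamma  # (Nx,)

    if np.all(b == 0.0):
        P = np.zeros(n, dtype=complex)
    else:
        # conservative tridiagonal discretization; row 0 Dirichlet,
        # last row a half-cell with zero-flux face at x = 1
        ah = 0.5 * (a[:-1] + a[1:])  # a at faces i+1/2
        lower = np.zeros(n, dtype=complex)
        diag = np.zeros(n, dtype=complex)
        upper = np.zeros(n, dtype=complex)
        rhs = np.zeros(n, dtype=complex)
        diag[0] = 1.0
        for i in range(1, n - 1):
            lower[i] = ah[i - 1] / dx**2
            upper[i] = ah[i] / dx**2
            diag[i] = -(ah[i - 1] + ah[i]) / dx**2 + b[i] * k**2
            rhs[i] = -b[i]
        lower[n - 1] = ah[n - 2] / (0.5 * dx**2)
        diag[n - 1] = -ah[n - 2] / (0.5 * dx**2) + b[n - 1] * k**2
        rhs[n - 1] = -b[n - 1]
        ab = np.zeros((3, n), dtype=complex)
        ab[0, 1:] = upper[:-1]
        ab[1, :] = diag
        ab[2, :-1] = lower[1:]
        try:
            P = solve_banded((1, 1), ab, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise SolverError(f"singular axial pressure operator: {exc}") from exc
        if not np.all(np.isfinite(P)):
            raise SolverError(
                "axial pressure solve produced non-finite values "
                "(degenerate compliance/wavenumber combination)"
            )

    # azimuthal closure: d/ds (hbar Wbar) = R with zero s-mean
    Px = ddx(P, dx)
    Px[-1] = 0.0  # flux condition holds exactly at the closed end
    H = gamma * (1.0 + k**2 * P)  # (Nx,)
    Ubar = Px[:, None] * hQ  # hbar * (depth flux) /... = h*Q*Px  -> = hbar Ubar
    R = -ddx(ell[:, None] * Ubar, dx, axis=0) - (ell * H)[:, None] * np.ones_like(h)
    R = R - trapz_periodic(R, ds, axis=1)[:, None]  # enforce solvability exactly
    IR = cumtrapz0_periodic(R, ds, axis=1)
    denom = hQ  # hbar Q
    A = -trapz_periodic(IR / denom, ds, axis=1) / trapz_periodic(1.0 / denom, ds, axis=1)
    Phat_s = ell[:, None] * (IR + A[:, None]) / denom
    Phat = cumtrapz0_periodic(Phat_s, ds, axis=1)
    return P, Phat_s, Phat, H


def assemble_solution(
    geometry: CanalGeometry, alpha: float, k: float, grid: Grid3D | None = None
) -> OscillatoryFlowSolution:
    """Build the full set of complex amplitudes (U, V, W, P', Phat, H')."""
    grid = grid or Grid3D(Nx=geometry.Nx, Ns=geometry.Ns)
    if (grid.Nx, grid.Ns) != (geometry.Nx, geometry.Ns):
        raise ValueError("grid (Nx, Ns) must match the geometry sampling")
    eta, dx, ds = grid.eta, geometry.dx, geometry.ds
    h, ell = geometry.h_bar, geometry.ell

    P, Phat_s, Phat, Hx = solve_pressure_bvp(geometry, alpha, k, grid)
    Px = ddx(P, dx)
    Px[-1] = 0.0
    H = np.broadcast_to(Hx[:, None], h.shape).copy()  # (Nx, Ns)

    G = womersley_profile_factor(eta, alpha, h)  # (Nx, Ns, Neta)
    g = womersley_cumulative_factor(eta, alpha, h)
    G = np.moveaxis(G, -1, 1)  # (Nx, Neta, Ns)
    g = np.moveaxis(g, -1, 1)

    U = Px[:, None, None] * G
    W = (Phat_s / ell[:, None])[:, None, :] * G
    IU = Px[:, None, None] * g  # int_0^eta U
    IW = (Phat_s / ell[:, None])[:, None, :] * g

    hx = ddx(h, dx, axis=0)
    hs = dds_periodic(h, ds, axis=1)
    e3 = eta[None, :, None]
    ell3 = ell[:, None, None]

    V = -h[:, None, :] * (
        ddx(ell3 * IU, dx, axis=0) / ell3
        + (hx[:, None, :] / h[:, None, :]) * (IU - e3 * U)
        + dds_periodic(IW, ds, axis=2) / ell3
        + (hs[:, None, :] / (h[:, None, :] * ell3)) * (IW - e3 * W)
    )
    # pin the exact kinematic values at the walls (the quadrature above
    # carries O(dx^2) residuals there)
    V[:, 0, :] = 0.0

    return OscillatoryFlowSolution(
        geometry=geometry,
        grid=grid,
        alpha=alpha,
        k=k,
        U=U,
        V=V,
        W=W,
        P_prime=P,
        P_hat=Phat,
        P_hat_s=Phat_s,
        H_prime=H,
    )
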