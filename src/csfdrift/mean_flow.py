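"""Cycle-averaged Lagrangian drift: steady streaming, Stokes drift and
buoyancy-induced drift.

The solute is transported on the slow time scale by the mean Lagrangian
velocity

    uL = uSS + uB + uSD   (and likewise for v, w),

where

* ``uSS`` (steady streaming) is the cycle-averaged Eulerian velocity driven
  by the time-averaged convective acceleration and canal-deformation
  forcings built from products of the oscillatory amplitudes;
* ``uSD`` (Stokes drift) is the kinematic drift caused by spatial
  non-uniformity of the pulsatile flow;
* ``uB`` (buoyancy drift) is driven by the weight of the solute-laden fluid
  and depends on transverse/azimuthal moments of the current concentration
  field, making the transport equation integro-differential.

Time averages of products of harmonic signals reduce to conjugate
products of amplitudes:  with a = Re(i e^{it} A), b = Re(i e^{it} B),
<a b> = Re(A conj(B))/2;  with a = Re(e^{it} A) instead,
<a b> = Im(A conj(B))/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fd import (
    cumtrapz0,
    cumtrapz0_periodic,
    ddx,
    dds_periodic,
    trapz,
    trapz_periodic,
)
from .geometry import CanalGeometry, Grid3D
from .oscillatory_flow import OscillatoryFlowSolution

__all__ = [
    "MeanForcings",
    "MeanFlowField",
    "BuoyancyKernels",
    "compute_calC",
    "compute_fB",
    "buoyancy_drift",
    "mean_forcings",
    "steady_streaming",
    "stokes_drift",
    "compose_lagrangian",
    "lagrangian_mean_flow",
    "width_averaged_streamfunction",
]


def _re_avg(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """<Re(i e^{it} A) Re(i e^{it} B)> = Re(A conj(B)) / 2."""
    return 0.5 * np.real(A * np.conj(B))


def _im_avg(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """<Re(e^{it} A) Re(i e^{it} B)> = Im(A conj(B)) / 2."""
    return 0.5 * np.imag(A * np.conj(B))


@dataclass(frozen=True)
class MeanForcings:
    """Cycle-averaged forcings of the order-eps mean Eulerian problem.

    ``F_mass`` forces the mean continuity balance (wall-motion/flow
    correlations); ``F_x`` and ``F_s`` force the axial and azimuthal mean
    momentum balances (convective acceleration + deformation-modulated
    viscous stresses).  All are real fields on (x, eta, s).
    """

    F_mass: np.ndarray
    F_x: np.ndarray
    F_s: np.ndarray


@dataclass(frozen=True)
class BuoyancyKernels:
    """Concentration moments entering the buoyancy drift.

    ``calC(x, s) = int_0^1 c0 eta (1 - eta) deta`` weights the transverse
    distribution of solute weight; ``f_B(x, eta, s)`` is its cumulative
    counterpart entering the transverse drift component.
    """

    calC: np.ndarray
    f_B: np.ndarray


@dataclass
class MeanFlowField:
    """The three steady drift components on the (x, eta, s) grid."""

    u_ss: np.ndarray
    v_ss: np.ndarray
    w_ss: np.ndarray
    u_sd: np.ndarray
    v_sd: np.ndarray
    w_sd: np.ndarray
    u_b: np.ndarray
    v_b: np.ndarray
    w_b: np.ndarray
    p1_mean: np.ndarray  # (Nx,), diagnostic

    def lagrangian(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        uL = self.u_ss + self.u_sd + self.u_b
        vL = self.v_ss + self.v_sd + self.v_b
        wL = self.w_ss + self.w_sd + self.w_b
        return uL, vL, wL


# ----------------------------------------------------------------------
# buoyancy drift
# ----------------------------------------------------------------------

def _eta_moment_integrals(
    c0: np.ndarray, eta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative moments (Ic, Ict, Ict2) of a concentration profile.

    Ic = int_0^eta c0 dt, Ict = int_0^eta c0 t dt, Ict2 = int_0^eta c0 t^2 dt,
    evaluated exactly for a piecewise-linear c0 (product-weighted segment
    rule).  This keeps the closed-form buoyancy-drift cancellations — a
    spatially uniform solute must produce no drift — exact at the discrete
    level.  ``c0`` has eta on axis 1.
    """
    d = eta[1] - eta[0]
    a = eta[:-1][None, :, None]
    b = eta[1:][None, :, None]
    ca = c0[:, :-1, :]
    cb = c0[:, 1:, :]
    Sc = 0.5 * d * (ca + cb)
    Sct = d * (ca * (2.0 * a + b) + cb * (a + 2.0 * b)) / 6.0
    Sct2 = d * (
        ca * (3.0 * a * a + 2.0 * a * b + b * b)
        + cb * (a * a + 2.0 * a * b + 3.0 * b * b)
    ) / 12.0

    def cum(seg: np.ndarray) -> np.ndarray:
        out = np.zeros((c0.shape[0], c0.shape[1], c0.shape[2]))
        out[:, 1:, :] = np.cumsum(seg, axis=1)
        return out

    return cum(Sc), cum(Sct), cum(Sct2)


def compute_calC(c0: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """calC = int_0^1 c0 eta (1 - eta) deta, eta on axis 1.

    Uses the product-weighted segment rule (exact for piecewise-linear
    c0, hence exact for the parabolic weight itself).  Accepts
    (Nx, Neta, Ns) fields or a bare (Neta,) profile.
    """
    c0 = np.asarray(c0, dtype=float)
    one_d = c0.ndim == 1
    if one_d:
        c0 = c0[None, :, None]
    Ic, Ict, Ict2 = _eta_moment_integrals(c0, eta)
    out = Ict[:, -1, :] - Ict2[:, -1, :]
    return out[0, 0] if one_d else out


def compute_fB(c0: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Cumulative buoyancy kernel

    f_B(eta) = 1/2 int_0^eta c0 t^2 dt + (eta^2/2 - eta) int_0^eta c0 t dt
               - eta^2/2 int_eta^1 c0 (1 - t) dt,

    evaluated with the same piecewise-linear-exact cumulative moments at
    every eta node.  Equivalent to the double integral of c0 with
    homogeneous Dirichlet data at both walls.
    """
    c0 = np.asarray(c0, dtype=float)
    one_d = c0.ndim == 1
    if one_d:
        c0 = c0[None, :, None]
    e = eta[None, :, None]
    Ic, Ict, Ict2 = _eta_moment_integrals(c0, eta)
    I1mt = Ic - Ict
    tail = I1mt[:, -1:, :] - I1mt  # int_eta^1 c0 (1 - t) dt
    out = 0.5 * Ict2 + (0.5 * e**2 - e) * Ict - 0.5 * e**2 * tail
    return out[0, :, 0] if one_d else out


def buoyancy_drift(
    c0: np.ndarray,
    geometry: CanalGeometry,
    grid: Grid3D,
    alpha: float,
    Ri: float,
    azimuthal_gauge: str = "as_printed",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Buoyancy-induced drift (u_b, v_b, w_b) for a concentration field c0.

    The drift is exactly linear in Ri * c0 and vanishes identically both
    for Ri = 0 and for spatially uniform c0 (a uniform density offset is
    hydrostatic).  ``azimuthal_gauge`` selects how the s-uniform mode of
    the azimuthal flux is fixed: ``"as_printed"`` (zero constant, the form
    the closed-form triplet is published in) or ``"periodic"`` (enforces a
    single-valued mean azimuthal pressure); see docs/methods.md.
    """
    eta, deta = grid.eta, grid.deta
    h, ell, dx, ds = geometry.h_bar, geometry.ell, geometry.dx, geometry.ds
    if Ri == 0.0:
        z = np.zeros((geometry.Nx, grid.Neta, geometry.Ns))
        return z, z.copy(), z.copy()

    c0 = np.asarray(c0, dtype=float)
    Ic, Ict, Ict2 = _eta_moment_integrals(c0, eta)
    calC = Ict[:, -1, :] - Ict2[:, -1, :]  # (Nx, Ns)
    h3 = h**3
    int_h3C = trapz_periodic(h3 * calC, ds, axis=1)  # (Nx,)
    int_h3 = trapz_periodic(h3, ds, axis=1)
    r = int_h3C / int_h3  # (Nx,)

    e = eta[None, :, None]
    shape_par = 3.0 * e * (1.0 - e)  # parabolic profile 3 eta (1 - eta)

    D = (Ic - Ict)[:, -1:, :]  # int_0^1 c0 (1 - t) dt
    J = e * Ic - Ict - e * D  # Green-solve of c0, zero at both walls

    h2 = (h**2)[:, None, :]
    u_b = alpha**2 * Ri * h2 * (shape_par * r[:, None, None] + J)

    # azimuthal component: x-derivative of the cumulative azimuthal flux
    Psi = ell[:, None] * (
        cumtrapz0_periodic(h3 * calC, ds, axis=1)
        - r[:, None] * cumtrapz0_periodic(h3, ds, axis=1)
    )
    dPsi_dx = ddx(Psi, dx, axis=0)  # (Nx, Ns)
    hW = 0.5 * alpha**2 * Ri * dPsi_dx  # hbar * (depth-integrated w_b)
    if azimuthal_gauge == "periodic":
        corr = -trapz_periodic(hW / h3, ds, axis=1) / trapz_periodic(1.0 / h3, ds, axis=1)
        hW = hW + corr[:, None]
    elif azimuthal_gauge != "as_printed":
        raise ValueError(f"unknown azimuthal_gauge {azimuthal_gauge!r}")
    w_b = 2.0 * shape_par * (hW / h)[:, None, :]

    # transverse component from the closed-form cumulative kernel
    I1mt = Ic - Ict
    fB = 0.5 * Ict2 + (0.5 * e**2 - e) * Ict - 0.5 * e**2 * (I1mt[:, -1:, :] - I1mt)
    hx = ddx(h, dx, axis=0)[:, None, :]
    hs = dds_periodic(h, ds, axis=1)[:, None, :]
    ell3 = ell[:, None, None]
    term_C = (e**2 * (e - 1.5) / ell3) * ddx(
        (ell[:, None] * h3 * calC), dx, axis=0
    )[:, None, :]
    term_fB = -ddx(ell3 * h3[:, None, :] * fB, dx, axis=0) / ell3
    v_b = (
        alpha**2 * Ri * (term_C + term_fB)
        + e * hx * u_b
        + (e / ell3) * hs * w_b
    )
    return u_b, v_b, w_b


# ----------------------------------------------------------------------
# mean Eulerian forcings and steady streaming
# ----------------------------------------------------------------------

def mean_forcings(osc: OscillatoryFlowSolution) -> MeanForcings:
    """Assemble the cycle-averaged forcings from the harmonic amplitudes."""
    geom, grid, alpha = osc.geometry, osc.grid, osc.alpha
    h, ell, dx, ds = geom.h_bar, geom.ell, geom.dx, geom.ds
    eta, deta = grid.eta, grid.deta
    U, V, W, H = osc.U, osc.V, osc.W, osc.H_prime

    e = eta[None, :, None]
    h3 = h[:, None, :]
    ell3 = ell[:, None, None]
    hx = ddx(h, dx, axis=0)[:, None, :]
    hs = dds_periodic(h, ds, axis=1)[:, None, :]
    H3 = H[:, None, :]
    Hx3 = ddx(H, dx, axis=0)[:, None, :]
    Hs3 = dds_periodic(H, ds, axis=1)[:, None, :]

    U_x = ddx(U, dx, axis=0)
    U_e = ddx(U, deta, axis=1)
    U_ee = ddx(U_e, deta, axis=1)
    U_s = dds_periodic(U, ds, axis=2)
    W_e = ddx(W, deta, axis=1)
    W_ee = ddx(W_e, deta, axis=1)
    W_s = dds_periodic(W, ds, axis=2)
    lW_x = ddx(ell3 * W, dx, axis=0)

    F_x = (
        -(e / h3) * _re_avg(H3, U_e)
        + _re_avg(U, U_x)
        - (e * hx / h3) * _re_avg(U, U_e)
        + _re_avg(V, U_e) / h3
        + _re_avg(W, U_s) / ell3
        - (e * hs / (h3 * ell3)) * _re_avg(W, U_e)
        + (2.0 / (alpha**2 * h3**3)) * _im_avg(H3, U_ee)
    )
    F_s = (
        -(e / h3) * _re_avg(H3, W_e)
        + _re_avg(U, lW_x) / ell3
        - (e * hx / h3) * _re_avg(U, W_e)
        + _re_avg(V, W_e) / h3
        + _re_avg(W, W_s) / ell3
        - (e * hs / (h3 * ell3)) * _re_avg(W, W_e)
        + (2.0 / (alpha**2 * h3**3)) * _im_avg(H3, W_ee)
    )
    lU_x = ddx(ell3 * U, dx, axis=0)
    F_mass = (
        -_im_avg(H3, lU_x) / ell3
        + e * _im_avg(Hx3, U_e)
        - _im_avg(H3, W_s) / ell3
        + (e / ell3) * _im_avg(Hs3, W_e)
    )
    return MeanForcings(F_mass=F_mass, F_x=F_x, F_s=F_s)


def _green_dirichlet(
    g: np.ndarray, eta: np.ndarray, with_flux: bool = False
):
    """Solve u'' = g on eta in [0,1] with u(0) = u(1) = 0 by quadrature.

    u(eta) = int_0^eta (eta - t) g dt - eta int_0^1 (1 - t) g dt, evaluated
    with the same piecewise-linear-exact moment rule as the buoyancy
    kernels, so that the quasi-steady solver and the closed-form drift
    expressions coincide at the discrete level.  With ``with_flux`` the
    depth integral int_0^1 u deta = -int_0^1 g t (1 - t)/2 dt is returned
    as well (exact for the same representation).
    """
    Ic, Ict, Ict2 = _eta_moment_integrals(g, eta)
    e = eta[None, :, None]
    D = (Ic - Ict)[:, -1:, :]
    u = e * Ic - Ict - e * D
    if not with_flux:
        return u
    flux = -0.5 * (Ict[:, -1, :] - Ict2[:, -1, :])
    return u, flux


def steady_streaming(
    forcings: MeanForcings,
    geometry: CanalGeometry,
    grid: Grid3D,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Solve the quasi-steady mean lubrication system for the
    Ri-independent Eulerian streaming (u_ss, v_ss, w_ss, p1_mean).

    The mean axial pressure gradient closes the section-integrated flux,
    whose x-profile is fixed by the mass forcing and the zero-flux
    condition at the closed end; the mean azimuthal pressure gradient
    closes the azimuthal flux balance with a single-valued (s-periodic)
    pressure.
    """
    eta, deta = grid.eta, grid.deta
    h, ell, dx, ds = geometry.h_bar, geometry.ell, geometry.dx, geometry.ds
    h3 = h[:, None, :]
    ell3 = ell[:, None, None]
    e = eta[None, :, None]

    # axial: particular profile + pressure-gradient parabola
    u_p, Ubar_p = _green_dirichlet(alpha**2 * h3**2 * forcings.F_x, eta, with_flux=True)

    Fbar = trapz(forcings.F_mass, deta, axis=1)  # (Nx, Ns)
    lF = ell * trapz_periodic(Fbar, ds, axis=1)  # (Nx,)
    T = cumtrapz0(lF, dx)
    Phi = T - T[-1]  # net axial flux of the mean Eulerian flow

    int_h3 = trapz_periodic(h**3, ds, axis=1)
    px = 12.0 * (trapz_periodic(h * Ubar_p, ds, axis=1) - Phi / ell) / (
        alpha**2 * int_h3
    )  # (Nx,)
    u_ss = u_p - 0.5 * alpha**2 * h3**2 * px[:, None, None] * e * (1.0 - e)
    p1_mean = cumtrapz0(px, dx)

    # azimuthal: flux closure with s-periodic mean pressure
    w_p, Wbar_p = _green_dirichlet(alpha**2 * h3**2 * forcings.F_s, eta, with_flux=True)
    Ubar = Ubar_p - alpha**2 * h**2 * px[:, None] / 12.0  # depth flux of u_ss
    Rm = ell[:, None] * Fbar - ddx(ell[:, None] * h * Ubar, dx, axis=0)
    Rm = Rm - trapz_periodic(Rm, ds, axis=1)[:, None]  # exact solvability
    Gt = cumtrapz0_periodic(Rm, ds, axis=1)  # target hbar Wbar minus constant
    qsl_wo = 12.0 * (Wbar_p - Gt / h) / (alpha**2 * h**2)  # q_s/ell before gauge
    Cw = trapz_periodic(qsl_wo, ds, axis=1) / trapz_periodic(
        12.0 / (alpha**2 * h**3), ds, axis=1
    )
    qsl = qsl_wo - Cw[:, None] * 12.0 / (alpha**2 * h**3)
    w_ss = w_p - 0.5 * alpha**2 * h3**2 * qsl[:, None, :] * e * (1.0 - e)

    # transverse from the mean continuity balance
    hx = ddx(h, dx, axis=0)[:, None, :]
    hs = dds_periodic(h, ds, axis=1)[:, None, :]
    div = (
        forcings.F_mass
        - ddx(ell3 * h3 * u_ss, dx, axis=0) / ell3
        - dds_periodic(h3 * w_ss, ds, axis=2) / ell3
    )
    v_ss = e * hx * u_ss + (e / ell3) * hs * w_ss + cumtrapz0(div, deta, axis=1)
    v_ss[:, 0, :] = 0.0
    return u_ss, v_ss, w_ss, p1_mean


def kinematic_drift(
    osc: OscillatoryFlowSolution,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinate-space particle drift (x, eta, s components).

    The cycle average of (displacement . gradient) acting on the
    oscillatory coordinate velocities (U, Omega, W/ell) with gradients at
    fixed (x, eta, s).  This is what trajectory integration of the
    reconstructed leading-order field measures (the test suite's particle
    oracle); the transport equation's effective drift,
    :func:`stokes_drift`, additionally carries the metric terms that
    appear when the slow advection operator is written in the normalized
    transverse coordinate.
    """
    geom, grid = osc.geometry, osc.grid
    h, ell, dx, ds = geom.h_bar, geom.ell, geom.dx, geom.ds
    eta, deta = grid.eta, grid.deta
    e = eta[None, :, None]
    h3 = h[:, None, :]
    ell3 = ell[:, None, None]
    U, V, W = osc.U, osc.V, osc.W
    Omega = (V - e * osc.H_prime[:, None, :]) / h3

    def drift_of(A: np.ndarray) -> np.ndarray:
        return (
            _im_avg(U, ddx(A, dx, axis=0))
            + _im_avg(Omega, ddx(A, deta, axis=1))
            + _im_avg(W / ell3, dds_periodic(A, ds, axis=2))
        )

    return drift_of(U), drift_of(Omega), drift_of(W)


def stokes_drift(
    osc: OscillatoryFlowSolution,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Effective Stokes drift (u_sd, v_sd, w_sd) of the transport equation.

    Obtained by averaging the oscillatory advection acting on the
    order-eps concentration response: the drift of each velocity slot is
    the cycle average of (displacement . gradient) with the horizontal
    gradients taken at fixed physical transverse position (fixed y, not
    fixed eta), plus wall-correlation terms from the oscillation of the
    coordinate mapping.  Together with the steady streaming this field
    carries zero net axial flux section by section, so the width-averaged
    streamlines of the composed Lagrangian drift close.
    """
    geom, grid = osc.geometry, osc.grid
    h, ell, dx, ds = geom.h_bar, geom.ell, geom.dx, geom.ds
    eta, deta = grid.eta, grid.deta
    e = eta[None, :, None]
    h3 = h[:, None, :]
    ell3 = ell[:, None, None]

    U, V, W = osc.U, osc.V, osc.W
    H = osc.H_prime[:, None, :]
    hx = ddx(h, dx, axis=0)[:, None, :]
    hs = dds_periodic(h, ds, axis=1)[:, None, :]
    Omega = (V - e * H) / h3  # oscillatory eta-velocity amplitude
    # total oscillatory advection coefficient of d(c0)/deta
    G = Omega - (e * hx / h3) * U - (e * hs / (h3 * ell3)) * W

    def drift_of(A: np.ndarray) -> np.ndarray:
        A_eta = ddx(A, deta, axis=1)
        return (
            _im_avg(U, ddx(A, dx, axis=0))
            + _im_avg(Omega, A_eta)
            + _im_avg(W / ell3, dds_periodic(A, ds, axis=2))
            - (e * hx / h3) * _im_avg(U, A_eta)
            - (e * hs / (h3 * ell3)) * _im_avg(W, A_eta)
        )

    u_sd = drift_of(U)
    w_sd = ell3 * drift_of(W / ell3)
    a_eta = (
        drift_of(G)
        + (e * hx / h3**2) * _im_avg(H, U)
        - (e / h3) * _im_avg(ddx(osc.H_prime, dx, axis=0)[:, None, :], U)
        - _im_avg(H, V) / h3**2
        + (e * hs / (h3**2 * ell3)) * _im_avg(H, W)
        - (e / (h3 * ell3)) * _im_avg(
            dds_periodic(osc.H_prime, ds, axis=1)[:, None, :], W
        )
    )
    v_sd = h3 * a_eta + e * (u_sd * hx + (w_sd / ell3) * hs)
    return u_sd, v_sd, w_sd


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------

def lagrangian_mean_flow(
    osc: OscillatoryFlowSolution,
    c0: np.ndarray | None = None,
    Ri: float = 0.0,
    azimuthal_gauge: str = "as_printed",
) -> MeanFlowField:
    """Build the full mean-flow field for an oscillatory solution.

    The buoyancy component is evaluated for the supplied concentration
    field (zeros when ``c0`` is None or Ri == 0).
    """
    geom, grid = osc.geometry, osc.grid
    f = mean_forcings(osc)
    u_ss, v_ss, w_ss, p1 = steady_streaming(f, geom, grid, osc.alpha)
    u_sd, v_sd, w_sd = stokes_drift(osc)
    if c0 is None or Ri == 0.0:
        z = np.zeros_like(u_ss)
        u_b, v_b, w_b = z, z.copy(), z.copy()
    else:
        u_b, v_b, w_b = buoyancy_drift(
            c0, geom, grid, osc.alpha, Ri, azimuthal_gauge=azimuthal_gauge
        )
    return MeanFlowField(
        u_ss=u_ss, v_ss=v_ss, w_ss=w_ss,
        u_sd=u_sd, v_sd=v_sd, w_sd=w_sd,
        u_b=u_b, v_b=v_b, w_b=w_b,
        p1_mean=p1,
    )


def compose_lagrangian(
    mean: MeanFlowField, geometry: CanalGeometry, grid: Grid3D
) -> dict[str, np.ndarray]:
    """Lagrangian velocity triplet plus width-averaged fields.

    Returns a dict with keys ``uL, vL, wL`` (on (x, eta, s)),
    ``uL_bar, wL_bar`` (width averages on (x, s)) and ``psi`` (the
    width-averaged streamfunction of the metric-weighted flux, constant
    along mean transport streamlines).
    """
    uL, vL, wL = mean.lagrangian()
    shapes = {a.shape for a in (uL, vL, wL)}
    if len(shapes) != 1:
        raise ValueError("mean-flow components are not on a common grid")
    deta = grid.deta
    uL_bar = trapz(uL, deta, axis=1)
    wL_bar = trapz(wL, deta, axis=1)
    psi = width_averaged_streamfunction(uL_bar, wL_bar, geometry)
    return {"uL": uL, "vL": vL, "wL": wL, "uL_bar": uL_bar, "wL_bar": wL_bar, "psi": psi}


def width_averaged_streamfunction(
    uL_bar: np.ndarray, wL_bar: np.ndarray, geometry: CanalGeometry
) -> np.ndarray:
    """Streamfunction psi(x, s) of the width-averaged transport flux.

    Defined by d(psi)/ds = ell hbar uL_bar and d(psi)/dx = -hbar wL_bar,
    anchored at psi(0, 0) = 0.
    """
    h, ell, dx, ds = geometry.h_bar, geometry.ell, geometry.dx, geometry.ds
    Fx = ell[:, None] * h * uL_bar
    Fs = h * wL_bar
    psi0 = -cumtrapz0(Fs[:, 0], dx)  # along s = 0
    return psi0[:, None] + cumtrapz0_periodic(Fx, ds, axis=1)
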