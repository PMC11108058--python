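"""Independent finite-eps oracle for the cycle-averaged Eulerian flow.

Integrates the primitive unsteady thin-film system (continuity, x/s
momentum, elastic wall law) in the time domain at small finite eps —
semi-implicit viscous step, exact axial/azimuthal pressure projection —
and returns the cycle-averaged velocity divided by eps.  This shares no
code path with the harmonic solver or the time-averaged mean-flow
formulas, so it provides an independent check of the steady-streaming
field (sign, pattern and magnitude).
"""

import numpy as np
from scipy.linalg import solve_banded

from csfdrift._fd import (
    cumtrapz0,
    cumtrapz0_periodic,
    ddx,
    dds_periodic,
    trapz,
    trapz_periodic,
)


def mean_eulerian_flow_oracle(
    geom,
    grid,
    alpha: float,
    k: float,
    eps: float = 0.02,
    nt_per: int = 700,
    nper_transient: int = 4,
    nper_average: int = 2,
):
    """Return <u>/eps on (x, eta, s): the order-eps mean Eulerian velocity."""
    Nx, Ne, Ns = grid.Nx, grid.Neta, grid.Ns
    x, eta = grid.x, grid.eta
    dx, deta, ds = grid.dx, grid.deta, grid.ds
    hb, ell, gam = geom.h_bar, geom.ell, geom.gamma
    dt = 2 * np.pi / nt_per
    e3 = eta[None, :, None]
    ell3 = ell[:, None, None]

    def thomas_eta(D, rhs):
        # (I - dt D d2/deta2) u = rhs per (x, s) column, u(0)=u(1)=0
        r = dt * D / deta**2
        rhs = rhs.copy()
        rhs[:, 0, :] = 0.0
        rhs[:, -1, :] = 0.0
        cp = np.zeros_like(rhs)
        dp = np.zeros_like(rhs)
        for j in range(1, Ne):
            if j == Ne - 1:
                dp[:, j, :] = rhs[:, j, :]
                cp[:, j, :] = 0.0
                continue
            m = (1.0 + 2.0 * r) - (-r) * cp[:, j - 1, :]
            cp[:, j, :] = -r / m
            dp[:, j, :] = (rhs[:, j, :] - (-r) * dp[:, j - 1, :]) / m
        u = np.zeros_like(rhs)
        u[:, -1, :] = dp[:, -1, :]
        for j in range(Ne - 2, 0, -1):
            u[:, j, :] = dp[:, j, :] - cp[:, j, :] * u[:, j + 1, :]
        u[:, 0, :] = 0.0
        return u

    def depth(f):
        return trapz(f, deta, axis=1)

    def vdiag(u, w, h):
        hx = ddx(h, dx, axis=0)[:, None, :]
        hs = dds_periodic(h, ds, axis=1)[:, None, :]
        h3 = h[:, None, :]
        integrand = (
            ddx(ell3 * u, dx, axis=0) / ell3
            - (e3 * hx / h3) * ddx(u, deta, axis=1)
            + dds_periodic(w, ds, axis=2) / ell3
            - (e3 * hs / (h3 * ell3)) * ddx(w, deta, axis=1)
        )
        return -h3 * cumtrapz0(integrand, deta, axis=1)

    u = np.zeros((Nx, Ne, Ns))
    w = np.zeros((Nx, Ne, Ns))
    p = np.zeros(Nx)
    p_prev = np.zeros(Nx)
    avg_u = np.zeros_like(u)
    navg = 0
    t = 0.0
    for step in range((nper_transient + nper_average) * nt_per):
        tn1 = t + dt
        hp = gam[:, None] * (np.cos(t) + k**2 * p[:, None]) * np.ones((Nx, Ns))
        h = hb + eps * hp
        pt = (p - p_prev) / dt if step > 0 else np.zeros(Nx)
        hpt = gam[:, None] * (-np.sin(t) + k**2 * pt[:, None]) * np.ones((Nx, Ns))
        ht = eps * hpt
        D = 1.0 / (alpha**2 * h**2)
        hx = ddx(h, dx, axis=0)[:, None, :]
        hs = dds_periodic(h, ds, axis=1)[:, None, :]
        h3 = h[:, None, :]

        v = vdiag(u, w, h)
        u_e = ddx(u, deta, axis=1)
        w_e = ddx(w, deta, axis=1)
        Nu = (e3 * ht[:, None, :] / h3) * u_e - eps * (
            u * (ddx(u, dx, axis=0) - (e3 * hx / h3) * u_e)
            + (v / h3) * u_e
            + (w / ell3) * (dds_periodic(u, ds, axis=2) - (e3 * hs / h3) * u_e)
        )
        Nw = (e3 * ht[:, None, :] / h3) * w_e - eps * (
            (u / ell3) * (ddx(ell3 * w, dx, axis=0) - ell3 * (e3 * hx / h3) * w_e)
            + (v / h3) * w_e
            + (w / ell3) * (dds_periodic(w, ds, axis=2) - (e3 * hs / h3) * w_e)
        )

        a_u = thomas_eta(D, u + dt * Nu)
        c_w = thomas_eta(D, w + dt * Nw)
        b_prof = thomas_eta(D, np.ones_like(u))
        Bbar = depth(b_prof)

        # axial pressure projection (elastic wall law, closed end)
        abar = depth(a_u)
        F = ell * trapz_periodic(h * abar, ds, axis=1)
        A = dt * ell * trapz_periodic(h * Bbar, ds, axis=1)
        beta = ell * gam * k**2 / dt
        dcos = (np.cos(tn1) - np.cos(t)) / dt
        Ah = 0.5 * (A[:-1] + A[1:])
        Fh = 0.5 * (F[:-1] + F[1:])
        lower = np.zeros(Nx)
        diag = np.zeros(Nx)
        upper = np.zeros(Nx)
        rr = np.zeros(Nx)
        diag[0] = 1.0
        for i in range(1, Nx - 1):
            lower[i] = -Ah[i - 1] / dx**2
            upper[i] = -Ah[i] / dx**2
            diag[i] = (Ah[i - 1] + Ah[i]) / dx**2 + beta[i]
            rr[i] = beta[i] * p[i] - ell[i] * gam[i] * dcos - (Fh[i] - Fh[i - 1]) / dx
        lower[Nx - 1] = -Ah[Nx - 2] / (0.5 * dx**2)
        diag[Nx - 1] = Ah[Nx - 2] / (0.5 * dx**2) + beta[Nx - 1]
        rr[Nx - 1] = (
            beta[Nx - 1] * p[Nx - 1]
            - ell[Nx - 1] * gam[Nx - 1] * dcos
            - (0.0 - Fh[Nx - 2]) / (0.5 * dx)
        )
        ab = np.zeros((3, Nx))
        ab[0, 1:] = upper[:-1]
        ab[1] = diag
        ab[2, :-1] = lower[1:]
        pn1 = solve_banded((1, 1), ab, rr)

        px = ddx(pn1, dx)
        px[-1] = F[-1] / A[-1]
        u_new = a_u - dt * px[:, None, None] * b_prof

        # azimuthal projection with s-periodic pressure
        hp1 = gam[:, None] * (np.cos(tn1) + k**2 * pn1[:, None]) * np.ones((Nx, Ns))
        h1 = hb + eps * hp1
        hpt1 = (hp1 - hp) / dt
        R = -ell[:, None] * hpt1 - ddx(ell[:, None] * h1 * depth(u_new), dx, axis=0)
        R = R - trapz_periodic(R, ds, axis=1)[:, None]
        Wt = cumtrapz0_periodic(R, ds, axis=1)
        cbar = depth(c_w)
        num = trapz_periodic((h1 * cbar - Wt) / (dt * h1 * Bbar), ds, axis=1)
        den = trapz_periodic(1.0 / (dt * h1 * Bbar), ds, axis=1)
        Cc = num / den
        phs_over_ell = (h1 * cbar - Wt - Cc[:, None]) / (dt * h1 * Bbar)
        w_new = c_w - dt * phs_over_ell[:, None, :] * b_prof

        p_prev, p, u, w, t = p, pn1, u_new, w_new, tn1
        if step >= nper_transient * nt_per:
            avg_u += u
            navg += 1

    return (avg_u / navg) / eps
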