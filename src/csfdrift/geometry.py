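"""Dimensionless canal geometry and the computational grid.

The spinal subarachnoid space is modelled as a slender annular canal with
curvilinear coordinates

* ``x``   -- axial position, 0 at the (cranial) entrance, 1 at the closed
  (sacral) end; for a sitting subject gravity points along +x,
* ``eta`` -- normalized transverse coordinate, 0 at the pia/cord surface,
  1 at the dura,
* ``s``   -- azimuthal position in [0, 1), periodic, with s = 0 on the
  posterior midline.

A geometry consists of the dimensionless canal width ``h_bar(x, s)``
(scaled with the characteristic width h_c), the cord perimeter ``ell(x)``
(scaled with its characteristic value) and the compliance profile
``gamma(x)`` (local dura compliance over its mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

import numpy as np

__all__ = [
    "Grid3D",
    "CanalGeometry",
    "GeometryFormatError",
    "make_constant_eccentricity",
    "make_variable_eccentricity",
    "make_uniform_annulus",
    "subject_compliance_profile",
    "save_tabulated_geometry",
    "load_tabulated_geometry",
    "H_MIN",
]

logger = logging.getLogger(__name__)

#: Floor applied to tabulated canal widths; protects the 1/h^2 diffusion
#: factor from degenerate (pinched) sections of measured geometries.
H_MIN = 1.0e-3


class GeometryFormatError(ValueError):
    """A tabulated geometry file violates the expected layout."""


@dataclass(frozen=True)
class Grid3D:
    """Uniform structured grid on (x, eta, s).

    x and eta include both endpoints; s is periodic and omits the
    duplicated endpoint s=1.
    """

    Nx: int = 121
    Neta: int = 21
    Ns: int = 40

    def __post_init__(self) -> None:
        if min(self.Nx, self.Neta, self.Ns) < 3:
            raise ValueError("Nx, Neta, Ns must all be >= 3")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.Nx)

    @property
    def eta(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.Neta)

    @property
    def s(self) -> np.ndarray:
        return np.arange(self.Ns) / self.Ns

    @property
    def dx(self) -> float:
        return 1.0 / (self.Nx - 1)

    @property
    def deta(self) -> float:
        return 1.0 / (self.Neta - 1)

    @property
    def ds(self) -> float:
        return 1.0 / self.Ns


@dataclass(frozen=True)
class CanalGeometry:
    """Canal shape sampled on the (x, s) grid.

    ``h_bar`` has shape (Nx, Ns); ``ell`` and ``gamma`` have shape (Nx,).
    """

    x: np.ndarray
    s: np.ndarray
    h_bar: np.ndarray
    ell: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        s = np.asarray(self.s, dtype=float)
        h = np.asarray(self.h_bar, dtype=float)
        ell = np.asarray(self.ell, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        for name, a in (("x", x), ("s", s), ("h_bar", h), ("ell", ell), ("gamma", gamma)):
            if not np.all(np.isfinite(a)):
                raise GeometryFormatError(f"{name} contains non-finite values")
        if x.ndim != 1 or x.size < 3 or not np.all(np.diff(x) > 0):
            raise GeometryFormatError("x grid must be strictly increasing with >= 3 points")
        if abs(x[0]) > 1e-12 or abs(x[-1] - 1.0) > 1e-12:
            raise GeometryFormatError("x grid must span [0, 1]")
        if s.ndim != 1 or s.size < 3 or not np.all(np.diff(s) > 0) or s[0] != 0.0 or s[-1] >= 1.0:
            raise GeometryFormatError("s grid must be increasing in [0, 1) starting at 0")
        if h.shape != (x.size, s.size):
            raise GeometryFormatError(
                f"h_bar shape {h.shape} does not match (Nx, Ns) = ({x.size}, {s.size})"
            )
        if ell.shape != (x.size,) or gamma.shape != (x.size,):
            raise GeometryFormatError("ell and gamma must be 1-D arrays on the x grid")
        if not np.all(h > 0.0):
            raise GeometryFormatError("h_bar must be strictly positive")
        if not np.all(ell > 0.0):
            raise GeometryFormatError("ell must be strictly positive")
        if np.any(gamma < 0.0):
            raise GeometryFormatError("gamma must be non-negative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "h_bar", h)
        object.__setattr__(self, "ell", ell)
        object.__setattr__(self, "gamma", gamma)

    @property
    def Nx(self) -> int:
        return self.x.size

    @property
    def Ns(self) -> int:
        return self.s.size

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def ds(self) -> float:
        return float(self.s[1] - self.s[0])


def _model_canal(grid: Grid3D, h_of_xs) -> CanalGeometry:
    x, s = grid.x, grid.s
    X, S = np.meshgrid(x, s, indexing="ij")
    return CanalGeometry(
        x=x,
        s=s,
        h_bar=h_of_xs(X, S),
        ell=np.ones_like(x),
        gamma=np.ones_like(x),
    )


def make_constant_eccentricity(grid: Grid3D | None = None) -> CanalGeometry:
    """Annulus of constant eccentricity: h(s) = 1 - 0.5 cos(2 pi s).

    The cord sits closest to the dura on the posterior midline (s=0, where
    h = 0.5) and farthest on the anterior side (s=0.5, where h = 1.5);
    ell = gamma = 1.
    """
    grid = grid or Grid3D()
    return _model_canal(grid, lambda X, S: 1.0 - 0.5 * np.cos(2.0 * np.pi * S))


def make_variable_eccentricity(grid: Grid3D | None = None) -> CanalGeometry:
    """Annulus whose eccentricity flips along the canal:
    h(x, s) = 1 - 0.5 cos(2 pi s) cos(2 pi x); ell = gamma = 1.

    Mimics the alternation of the cord between the posterior and anterior
    sides of the dura along the human spine.
    """
    grid = grid or Grid3D()
    return _model_canal(
        grid, lambda X, S: 1.0 - 0.5 * np.cos(2.0 * np.pi * S) * np.cos(2.0 * np.pi * X)
    )


def make_uniform_annulus(grid: Grid3D | None = None) -> CanalGeometry:
    """Concentric annulus h = ell = gamma = 1 (useful for analytic checks)."""
    grid = grid or Grid3D()
    return _model_canal(grid, lambda X, S: np.ones_like(X))


def subject_compliance_profile(
    x: np.ndarray, gamma_c: float | None = None
) -> np.ndarray:
    """Axial compliance profile fitted to subject-specific MRI flow data.

    Dimensional form (m MPa^-1): gamma'(x) = 14.3 (0.8 + 0.3 tanh[4(x - 0.2)]),
    increasing caudally (the lumbar dura is the most compliant).  When
    ``gamma_c`` (the mean compliance, same unit) is given, the profile is
    returned nondimensionalized as gamma = gamma'/gamma_c.
    """
    x = np.asarray(x, dtype=float)
    gp = 14.3 * (0.8 + 0.3 * np.tanh(4.0 * (x - 0.2)))
    if gamma_c is not None:
        return gp / gamma_c
    return gp


# ----------------------------------------------------------------------
# Tabulated (subject-specific) geometry I/O: columnar text format.
#
# Layout:   # csfdrift-geometry <Nx> <Ns>
#           # x ell gamma
#           <Nx rows of three columns>
#           # h_bar rows: x-index major, Ns columns each
#           <Nx rows of Ns columns>
# ----------------------------------------------------------------------

def save_tabulated_geometry(geom: CanalGeometry, path: Union[str, Path, IO[str]]) -> None:
    """Write a geometry as columnar text (round-trips with the loader)."""

    def _write(fh: IO[str]) -> None:
        fh.write(f"# csfdrift-geometry {geom.Nx} {geom.Ns}\n")
        fh.write("# x ell gamma\n")
        for xi, li, gi in zip(geom.x, geom.ell, geom.gamma):
            fh.write(f"{xi:.17g} {li:.17g} {gi:.17g}\n")
        fh.write("# h_bar (one x row per line)\n")
        for row in geom.h_bar:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")

    if hasattr(path, "write"):
        _write(path)  # type: ignore[arg-type]
    else:
        with open(path, "w") as fh:
            _write(fh)


def load_tabulated_geometry(
    path: Union[str, Path, IO[str]], h_min: float = H_MIN
) -> CanalGeometry:
    """Read a tabulated geometry; widths below ``h_min`` are floored.

    Raises :class:`GeometryFormatError` with the offending row/column for
    malformed files (non-rectangular data, non-monotone x, NaN values).
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()  # type: ignore[union-attr]
    else:
        lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# csfdrift-geometry"):
        raise GeometryFormatError("missing '# csfdrift-geometry Nx Ns' header")
    try:
        _, _, nx_s, ns_s = lines[0].split()
        Nx, Ns = int(nx_s), int(ns_s)
    except ValueError as exc:
        raise GeometryFormatError(f"malformed header line: {lines[0]!r}") from exc

    data_lines = [
        (i, ln) for i, ln in enumerate(lines[1:], start=2) if ln.strip() and not ln.startswith("#")
    ]
    if len(data_lines) != Nx + Nx:
        raise GeometryFormatError(
            f"expected {2 * Nx} data rows ({Nx} grid rows + {Nx} width rows), "
            f"found {len(data_lines)}"
        )

    def _parse(lineno: int, ln: str, ncol: int) -> np.ndarray:
        parts = ln.split()
        if len(parts) != ncol:
            raise GeometryFormatError(f"line {lineno}: expected {ncol} columns, got {len(parts)}")
        try:
            vals = np.array([float(p) for p in parts])
        except ValueError as exc:
            raise GeometryFormatError(f"line {lineno}: non-numeric entry") from exc
        if not np.all(np.isfinite(vals)):
            col = int(np.flatnonzero(~np.isfinite(vals))[0]) + 1
            raise GeometryFormatError(f"line {lineno}, column {col}: non-finite value")
        return vals

    grid_rows = np.array([_parse(no, ln, 3) for no, ln in data_lines[:Nx]])
    h_rows = np.array([_parse(no, ln, Ns) for no, ln in data_lines[Nx:]])
    x, ell, gamma = grid_rows.T
    if not np.all(np.diff(x) > 0):
        bad = int(np.flatnonzero(np.diff(x) <= 0)[0]) + 2
        raise GeometryFormatError(f"x grid not strictly increasing at row {bad}")

    n_floored = int(np.sum(h_rows < h_min))
    if n_floored:
        logger.warning("floored %d canal-width values below h_min=%g", n_floored, h_min)
        h_rows = np.maximum(h_rows, h_min)

    s = np.arange(Ns) / Ns
    return CanalGeometry(x=x, s=s, h_bar=h_rows, ell=ell, gamma=gamma)
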