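"""Canonical case registry: the model-canal validation cases and the
subject/infusion templates.

Each fixture is a complete, self-contained configuration (geometry
constructor, dimensionless parameters, delivery specification and slow-time
schedule); the two ``*_template`` entries require a user-supplied tabulated
geometry file and are returned with ``geometry_kind="tabulated"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .geometry import (
    CanalGeometry,
    Grid3D,
    load_tabulated_geometry,
    make_constant_eccentricity,
    make_variable_eccentricity,
)
from .transport import CaseConfig

__all__ = ["CaseFixture", "fixture", "available_fixtures", "build_config"]


@dataclass(frozen=True)
class CaseFixture:
    """Named, fully specified dispersion case."""

    name: str
    geometry_kind: str  # constant_eccentricity | variable_eccentricity | tabulated
    alpha: float
    k: float
    sigma: float
    Ri: float
    mode: str = "bolus"
    delivery_kind: str = "banded"
    delivery_params: dict = field(default_factory=dict)
    tau_end: float = 3.0
    description: str = ""


_BANDED = {"x0": 0.65, "delta": 0.2}
_SUBJECT_BOLUS = {
    "x0": 0.8, "eta0": 0.5, "s0": 0.0,
    "delta_x": 1.0 / 16.0, "delta_eta": 500.0, "delta_s": 2.0 / 7.0,
}
_SUBJECT_SOURCE = {
    "center": (0.8, 0.5, 0.0),
    "widths": (1.0 / 18.0, 1.0 / 5.0, 1.0 / 13.0),
}


def _model_case(name: str, geometry_kind: str, Ri: float, label: str) -> CaseFixture:
    return CaseFixture(
        name=name,
        geometry_kind=geometry_kind,
        alpha=3.0,
        k=0.5,
        sigma=0.4,
        Ri=Ri,
        delivery_kind="banded",
        delivery_params=dict(_BANDED),
        tau_end=3.0,
        description=f"{label} bolus in the {geometry_kind.replace('_', '-')} canal",
    )


_REGISTRY: dict[str, CaseFixture] = {}
for _geom, _prefix in (
    ("constant_eccentricity", "fig2"),
    ("variable_eccentricity", "fig3"),
):
    _REGISTRY[f"{_prefix}_heavy"] = _model_case(f"{_prefix}_heavy", _geom, -1.0, "heavy (Ri=-1)")
    _REGISTRY[f"{_prefix}_neutral"] = _model_case(f"{_prefix}_neutral", _geom, 0.0, "neutral (Ri=0)")
    _REGISTRY[f"{_prefix}_light"] = _model_case(f"{_prefix}_light", _geom, 1.0, "light (Ri=1)")

_REGISTRY["bolus_subject_template"] = CaseFixture(
    name="bolus_subject_template",
    geometry_kind="tabulated",
    alpha=10.8,
    k=0.73,
    sigma=1.0,
    Ri=1.0,
    delivery_kind="gaussian3d",
    delivery_params=dict(_SUBJECT_BOLUS),
    tau_end=3.0,
    description=(
        "lumbar bolus (L3/L4 posterior injection) in a subject-specific canal; "
        "supply the tabulated geometry file and the desired Ri"
    ),
)
_REGISTRY["infusion_template"] = CaseFixture(
    name="infusion_template",
    geometry_kind="tabulated",
    alpha=10.8,
    k=0.73,
    sigma=1.0,
    Ri=0.1,  # rescaled Richardson number Ri* in infusion mode
    mode="infusion",
    delivery_params=dict(_SUBJECT_SOURCE),
    tau_end=2.0,
    description=(
        "continuous lumbar infusion in a subject-specific canal; Ri is the "
        "rescaled Ri* = c_c Ri"
    ),
)


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def fixture(name: str, Ri: Optional[float] = None) -> CaseFixture:
    """Look up a fixture by name (optionally overriding Ri for templates)."""
    try:
        fx = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        ) from None
    if Ri is not None:
        fx = replace(fx, Ri=Ri)
    return fx


def build_config(
    fx: CaseFixture,
    grid: Optional[Grid3D] = None,
    geometry: Optional[CanalGeometry] = None,
    geometry_file: Optional[str] = None,
    tau_end: Optional[float] = None,
    **overrides,
) -> CaseConfig:
    """Materialize a fixture into a runnable :class:`CaseConfig`."""
    grid = grid or Grid3D()
    if geometry is None:
        if fx.geometry_kind == "constant_eccentricity":
            geometry = make_constant_eccentricity(grid)
        elif fx.geometry_kind == "variable_eccentricity":
            geometry = make_variable_eccentricity(grid)
        elif fx.geometry_kind == "tabulated":
            if geometry_file is None:
                raise ValueError(
                    f"fixture {fx.name!r} needs a tabulated geometry "
                    "(pass geometry= or geometry_file=)"
                )
            geometry = load_tabulated_geometry(geometry_file)
        else:  # pragma: no cover - registry is static
            raise ValueError(f"unknown geometry kind {fx.geometry_kind!r}")
    return CaseConfig(
        geometry=geometry,
        grid=grid,
        alpha=fx.alpha,
        k=fx.k,
        sigma=fx.sigma,
        Ri=fx.Ri,
        mode=fx.mode,
        delivery_kind=fx.delivery_kind,
        delivery_params=dict(fx.delivery_params),
        tau_end=fx.tau_end if tau_end is None else tau_end,
        **overrides,
    )
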