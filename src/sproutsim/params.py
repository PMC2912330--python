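"""Parameter records for the sprout proteolysis model.

One validated record (:class:`ParameterSet`) is the single source of truth for
every kinetic, transport and geometric constant used by the simulator.  The
defaults are the model's base conditions: an endothelial sprout idealised as a
2 um-radius cylinder whose 40 um tip cell secretes active protease at
3e6 molecules/h, immersed in an ECM with 750 nM (fluid-frame) HSPG and
sheathed by a 43 nm basement membrane with 13 uM HSPG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any, Literal, Mapping

import yaml

from .constants import N_AVOGADRO, SECONDS_PER_HOUR

__all__ = [
    "KineticParams",
    "Geometry",
    "MatrixProps",
    "BoundarySpec",
    "ParameterSet",
    "make_parameters",
    "concentration_convert",
    "molecules_to_bm_fluid_concentration",
    "load_config",
    "dump_defaults",
]


class ConfigurationError(KeyError):
    """Unknown parameter name in an override or configuration file."""


class ValidationError(ValueError):
    """Parameter value violates a physical constraint."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants (bimolecular constants in M^-1 s^-1, unimolecular in s^-1).

    ``qP`` is the whole-cell protease secretion rate in molecules/cell/h;
    ``qV`` (molecules um^-2 s^-1) and ``kclear`` (um/s) are the bounded-tissue
    VEGF source and clearance coefficients, normally recomputed by the case-2
    calibration stage.  ``r2_total`` is receptors per cell.
    """

    kon_R2: float = 1.0e7
    koff_R2: float = 1.0e-3
    kint: float = 2.8e-4
    kon_H: float = 4.2e5
    koff_H: float = 0.01
    kP: float = 631.0
    kdeg: float = 0.0
    qP: float = 3.0e6
    kclear: float = 0.0866
    qV: float = 7.68e-5
    r2_total: float = 1.0e4

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValidationError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValidationError(f"{f.name} must be non-negative, got {v!r}")

    @property
    def Kd_H(self) -> float:
        """VEGF165-HSPG dissociation constant, koff/kon (M); ~23.8 nM."""
        if self.kon_H == 0:
            raise ValidationError("Kd_H undefined for kon_H = 0")
        return self.koff_H / self.kon_H

    @property
    def Kd_R2(self) -> float:
        """VEGF-VEGFR2 dissociation constant (M); 100 pM at defaults."""
        return self.koff_R2 / self.kon_R2


@dataclass(frozen=True)
class Geometry:
    """Cylindrical domain geometry (um). Sprout occupies z in [-L, 0]."""

    L: float = 1200.0
    R_edge: float = 1200.0
    L_tip: float = 40.0
    R_sprout: float = 2.0
    d_BM: float = 0.043

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{f.name} must be positive and finite")
        if self.L_tip > self.L:
            raise ValidationError("tip cell cannot be longer than the half-domain")
        if self.R_sprout >= self.R_edge:
            raise ValidationError("sprout radius must be smaller than domain radius")

    @property
    def A_tip(self) -> float:
        """Tip-cell surface area including the end cap (um^2); 515 at defaults."""
        return 2.0 * math.pi * self.R_sprout * self.L_tip + math.pi * self.R_sprout**2


@dataclass(frozen=True)
class MatrixProps:
    """Porous-media transport properties of ECM and basement membrane.

    HSPG totals are interstitial-fluid (intra-pore) molar concentrations.
    """

    K_ECM: float = 0.85
    K_BM: float = 0.20
    D_ECM: float = 68.8
    D_BM: float = 18.0
    H_total_ECM: float = 750.0e-9
    H_total_BM: float = 13.0e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.K_BM <= self.K_ECM <= 1.0):
            raise ValidationError("require 0 < K_BM <= K_ECM <= 1")
        if self.D_ECM <= 0 or self.D_BM <= 0:
            raise ValidationError("diffusivities must be positive")
        if self.H_total_ECM < 0 or self.H_total_BM < 0:
            raise ValidationError("HSPG totals must be non-negative")


@dataclass(frozen=True)
class BoundarySpec:
    """External boundary conditions.

    ``isolated`` (case 1): Dirichlet fluid concentrations V0/P0 on all outer
    faces.  ``tissue`` (case 2): no-flux at r=R_edge, VEGF secretion flux at
    z=+L balanced by first-order clearance at z=-L, calibrated to produce mean
    fluid [VEGF165]=V0 at z=0 with fractional gradient g0 per tip length.
    """

    case: Literal["isolated", "tissue"] = "isolated"
    V0: float = 1.0e-12
    P0: float = 0.0
    g0: float | None = None
    uniform_protease: float | None = None

    def __post_init__(self) -> None:
        if self.case not in ("isolated", "tissue"):
            raise ValidationError(f"unknown boundary case {self.case!r}")
        if self.V0 < 0 or self.P0 < 0:
            raise ValidationError("boundary concentrations must be non-negative")
        if self.uniform_protease is not None and self.uniform_protease < 0:
            raise ValidationError("uniform protease level must be non-negative")
        if self.case == "isolated" and self.g0 is not None:
            raise ValidationError("g0 is only meaningful for the tissue case")
        if self.case == "tissue" and self.g0 is None:
            object.__setattr__(self, "g0", 0.05)


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated model configuration with derived constants."""

    kinetics: KineticParams = field(default_factory=KineticParams)
    geometry: Geometry = field(default_factory=Geometry)
    matrix: MatrixProps = field(default_factory=MatrixProps)
    boundary: BoundarySpec = field(default_factory=BoundarySpec)

    @property
    def r2_density(self) -> float:
        """Total VEGFR2 surface density, mol/um^2 (r2_total over tip-cell area)."""
        return self.kinetics.r2_total / (self.geometry.A_tip * N_AVOGADRO)

    @property
    def sR2(self) -> float:
        """VEGFR2 insertion rate, mol um^-2 s^-1 = kint * [R2]_total."""
        return self.kinetics.kint * self.r2_density

    @property
    def qP_flux(self) -> float:
        """Protease secretion flux over the tip cell, mol um^-2 s^-1."""
        return self.kinetics.qP / SECONDS_PER_HOUR / self.geometry.A_tip / N_AVOGADRO

    def replace(self, **overrides: Any) -> "ParameterSet":
        return make_parameters(overrides, base=self)


_SECTIONS = {
    "kinetics": KineticParams,
    "geometry": Geometry,
    "matrix": MatrixProps,
    "boundary": BoundarySpec,
}

_FIELD_TO_SECTION: dict[str, str] = {}
for _sec, _cls in _SECTIONS.items():
    for _f in fields(_cls):
        _FIELD_TO_SECTION[_f.name] = _sec

_CASE_GEOMETRY = {
    "isolated": {"L": 1200.0, "R_edge": 1200.0},
    "tissue": {"L": 80.0, "R_edge": 50.0},
}


def make_parameters(
    overrides: Mapping[str, Any] | None = None,
    *,
    case: str | None = None,
    base: ParameterSet | None = None,
) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from the base conditions.

    ``overrides`` maps field names (flat, or nested by section name) to
    values.  ``case`` selects the boundary-condition case and with it the
    default domain size (isolated: 1200x1200 um; tissue: 80x50 um).
    Derived quantities (A_tip, sR2, Kd_H, qP flux) are always recomputed
    from the primitive fields.

    Raises
    ------
    ConfigurationError
        for an override key that names no known field.
    ValidationError
        for non-finite or physically inadmissible values.
    """
    per_section: dict[str, dict[str, Any]] = {s: {} for s in _SECTIONS}

    if base is not None:
        for sec, cls in _SECTIONS.items():
            rec = getattr(base, sec)
            per_section[sec].update(
                {f.name: getattr(rec, f.name) for f in fields(cls)}
            )

    if case is not None:
        if case not in _CASE_GEOMETRY:
            raise ConfigurationError(f"unknown boundary case {case!r}")
        per_section["boundary"]["case"] = case
        if base is None:
            per_section["geometry"].update(_CASE_GEOMETRY[case])

    for key, value in dict(overrides or {}).items():
        if key in _SECTIONS:
            if not isinstance(value, Mapping):
                raise ConfigurationError(f"section {key!r} must map field names to values")
            for k, v in value.items():
                if k not in _FIELD_TO_SECTION or _FIELD_TO_SECTION[k] != key:
                    raise ConfigurationError(f"unknown field {k!r} in section {key!r}")
                per_section[key][k] = v
        elif key in _FIELD_TO_SECTION:
            per_section[_FIELD_TO_SECTION[key]][key] = value
        else:
            raise ConfigurationError(f"unknown parameter {key!r}")

    if per_section["boundary"].get("case") == "tissue" and base is None and case is None:
        # a bare {"case": "tissue"} override also switches the default domain
        for k, v in _CASE_GEOMETRY["tissue"].items():
            per_section["geometry"].setdefault(k, v)

    built = {sec: _SECTIONS[sec](**per_section[sec]) for sec in _SECTIONS}
    return ParameterSet(**built)


def concentration_convert(value, from_frame: str, K_av: float):
    """Convert between bulk (tissue-averaged) and fluid (intra-pore) frames.

    ``bulk = fluid * K_av``.  ``from_frame`` names the frame of ``value``;
    the returned value is in the other frame.
    """
    if not (0.0 < K_av <= 1.0):
        raise ValidationError(f"K_av must lie in (0, 1], got {K_av!r}")
    if from_frame == "fluid":
        return value * K_av
    if from_frame == "bulk":
        return value / K_av
    raise ConfigurationError(f"unknown frame {from_frame!r}")


def molecules_to_bm_fluid_concentration(
    n: float, area_um2: float, d_bm_um: float, K_bm: float
) -> float:
    """Fluid-frame molar concentration of ``n`` molecules confined to the pore
    space of a basement-membrane patch of ``area_um2`` and thickness ``d_bm_um``.

    For 1e5 proteases on a 515 um^2 tip cell with a 43 nm membrane at
    K_BM = 0.2 this evaluates to 37.5 uM.
    """
    if n < 0:
        raise ValidationError("molecule count must be non-negative")
    if area_um2 <= 0 or d_bm_um <= 0 or K_bm <= 0:
        raise ValidationError("BM geometry (area, thickness, porosity) must be positive")
    pore_volume_l = area_um2 * d_bm_um * K_bm * 1.0e-15
    return n / (N_AVOGADRO * pore_volume_l)


def load_config(path) -> ParameterSet:
    """Read a YAML configuration with sections kinetics/geometry/matrix/boundary."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    return make_parameters(raw)


def dump_defaults(case: str = "isolated") -> str:
    """YAML text of the default parameter set for ``case``."""
    ps = make_parameters(case=case)
    out: dict[str, dict[str, Any]] = {}
    for sec, cls in _SECTIONS.items():
        rec = getattr(ps, sec)
        out[sec] = {f.name: getattr(rec, f.name) for f in fields(cls)}
    return yaml.safe_dump(out, sort_keys=False)
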