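"""Scenario construction: boundary cases, staged initialisation, presets.

Two boundary-condition cases bracket the biology:

* **case 1 (isolated)** -- one sprout alone in a large (1200 um) domain with
  fixed far-field concentrations on every outer face; measures what a single
  cell can do.
* **case 2 (tissue)** -- the sprout as one of many, 100 um apart: no-flux at
  the radial edge, VEGF secreted across the leading face and cleared by a
  first-order sink at the trailing face, calibrated to a 1 pM mean and a
  5%/40 um gradient at z = 0; measures collective proteolysis.

The case-2 initialisation follows a staged protocol: converge a Dirichlet
gradient solve without HSPG while the receptor pool equilibrates, convert
the boundary to calibrated flux/clearance conditions and re-converge, then
impose the HSPG pools from binding equilibrium (valid because the soluble
steady state is HSPG-independent without proteases).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .constants import N_AVOGADRO
from .params import BoundarySpec, ParameterSet, ValidationError, make_parameters
from .solver import (
    NonConvergenceError,
    SolverControls,
    SproutModel,
    State,
    suggest_omega,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "CalibrationError",
    "case1_boundaries",
    "case2_calibrate",
    "initialize_case2",
    "run_scenario",
    "sweep",
    "flux_audit",
    "PRESETS",
    "get_preset",
]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one simulation experiment."""

    name: str
    case: str = "isolated"  # isolated | tissue
    protease_mode: str = "none"  # none | secreted | uniform_field | tethered
    protease_level: float = 0.0  # molecules/h, molar, or count, per mode
    kdeg: float = 0.0
    V0: float = 1.0e-12
    g0: float | None = None
    hspg_override: float | None = None  # ECM H_total, fluid molar
    receptor_placement: str = "sprout"
    secretion_placement: str = "tip"
    bare_tip: bool = False
    spacing: str = "coarse"
    overrides: Mapping[str, Any] = field(default_factory=dict)

    def build_params(self) -> ParameterSet:
        ov: dict[str, Any] = {"V0": self.V0, "kdeg": self.kdeg}
        if self.case == "tissue":
            ov["g0"] = 0.05 if self.g0 is None else self.g0
        if self.hspg_override is not None:
            ov["H_total_ECM"] = self.hspg_override
        if self.protease_mode == "secreted":
            ov["qP"] = self.protease_level
        elif self.protease_mode == "uniform_field":
            ov["uniform_protease"] = self.protease_level
        ov.update(self.overrides)
        return make_parameters(ov, case=self.case)

    def build_model(self, params: ParameterSet | None = None) -> SproutModel:
        params = params or self.build_params()
        return SproutModel(
            params,
            spacing=self.spacing,
            receptor_placement=self.receptor_placement,
            protease_mode=self.protease_mode,
            tethered_count=self.protease_level if self.protease_mode == "tethered" else 0.0,
            secretion_placement=self.secretion_placement,
            bare_tip=self.bare_tip,
        )


@dataclass
class ScenarioResult:
    """Converged fields plus reference state, calibration and diagnostics."""

    name: str
    model: SproutModel
    state: State
    reference: State
    diagnostics: dict
    calibration: dict = field(default_factory=dict)

    @property
    def params(self) -> ParameterSet:
        return self.model.params


def default_controls(model: SproutModel) -> SolverControls:
    """Solver controls with a mesh-tuned SOR factor (matters on the large
    isolated-sprout grid)."""
    return SolverControls(sor_omega=suggest_omega(model.grid))


# ----------------------------------------------------------------------
def case1_boundaries(V0: float, P0: float) -> dict[str, dict[str, tuple]]:
    """Dirichlet fluid concentrations on all outer faces: [V165]=V0,
    [V114]=0, [P]=P0; symmetry at the axis is implicit in the mesh."""
    if V0 < 0 or P0 < 0:
        raise ValidationError("boundary concentrations must be non-negative")
    edges = ("z_lo", "z_hi", "r_hi")
    return {
        "V165": {e: ("dirichlet", V0) for e in edges},
        "V114": {e: ("dirichlet", 0.0) for e in edges},
        "P": {e: ("dirichlet", P0) for e in edges},
    }


def flux_audit(model: SproutModel, state: State) -> dict[str, float]:
    """Boundary and uptake bookkeeping for VEGF165 at a converged state.

    Returns fluxes in AU/s (= 1e-15 mol/s): positive ``top_in`` enters at
    z=+L, positive ``bottom_out`` leaves at z=-L, ``internalized`` is the
    receptor-mediated uptake over the sprout surface.
    """
    from .solver import _boundary_conductances_cached

    g = model.grid
    m = model.params.matrix
    k = model.params.kinetics
    gb = _boundary_conductances_cached(g, m.D_ECM)
    C = state.field.V165

    def edge_flux_in(edge):
        bc = model.bc["V165"].get(edge, ("noflux",))
        if bc[0] == "dirichlet":
            vals = gb[edge] * (bc[1] * m.K_ECM - (C[-1, :] if edge == "z_hi" else C[0, :]))
            act = model.act[-1, :] if edge == "z_hi" else model.act[0, :]
            return float(np.sum(vals * act))
        if bc[0] == "flux_in":
            area = g.ring_areas if edge in ("z_lo", "z_hi") else None
            act = model.act[-1, :] if edge == "z_hi" else model.act[0, :]
            return float(np.sum(bc[1] * area * act))
        if bc[0] == "robin":
            act = model.act[0, :]
            return -float(np.sum(bc[1] * g.ring_areas * C[0, :] * act))
        return 0.0

    internal = float(np.sum(k.kint * state.surface.V165R2 * model.bm_area))
    return {
        "top_in": edge_flux_in("z_hi"),
        "bottom_in": edge_flux_in("z_lo"),
        "internalized": internal,
    }


def case2_calibrate(model: SproutModel, dirichlet_state: State) -> dict[str, float]:
    """Derive the tissue-case flux boundary conditions from a converged
    Dirichlet-stage solution.

    The VEGF secretion flux ``q`` is the area-averaged diffusive influx
    through z=+L; the clearance coefficient ``k_clear`` is the efflux
    through z=-L divided by the mean bulk concentration there, so that the
    flux-boundary problem reproduces the Dirichlet-stage steady state.

    Returns ``q_molar_um`` (M um/s, bulk frame), ``qV`` (molecules um^-2
    s^-1, the printed unit), ``kclear`` (um/s) and ``kclear_over_2L`` (s^-1).
    """
    from .solver import _boundary_conductances_cached

    g = model.grid
    m = model.params.matrix
    gb = _boundary_conductances_cached(g, m.D_ECM)
    C = dirichlet_state.field.V165

    bc_top = model.bc["V165"].get("z_hi")
    bc_bot = model.bc["V165"].get("z_lo")
    if not bc_top or bc_top[0] != "dirichlet" or not bc_bot or bc_bot[0] != "dirichlet":
        raise CalibrationError("calibration needs a converged Dirichlet-stage solution")

    act_top, act_bot = model.act[-1, :], model.act[0, :]
    ring = g.ring_areas
    flux_top = float(np.sum(gb["z_hi"] * (bc_top[1] * m.K_ECM - C[-1, :]) * act_top))
    flux_bot_out = float(np.sum(gb["z_lo"] * (C[0, :] - bc_bot[1] * m.K_ECM) * act_bot))
    area_top = float(np.sum(ring * act_top))
    area_bot = float(np.sum(ring * act_bot))
    mean_c_bot = float(np.sum(ring * C[0, :] * act_bot) / area_bot)

    if flux_top <= 0.0 or flux_bot_out <= 1e-30:
        raise CalibrationError(
            "degenerate gradient: no net flux through the domain "
            "(the trailing face must act as a clearance sink)"
        )
    if mean_c_bot <= 0.0:
        raise CalibrationError("vanishing concentration at the clearance face")

    q = flux_top / area_top  # AU um^-2 s^-1 = M um/s
    kclear = flux_bot_out / area_bot / mean_c_bot  # um/s
    L2 = g.z_faces[-1] - g.z_faces[0]
    return {
        "q_molar_um": q,
        "qV": q * N_AVOGADRO * 1.0e-15,  # molecules um^-2 s^-1
        "kclear": kclear,
        "kclear_over_2L": kclear / L2,
    }


def initialize_case2(
    spec: ScenarioSpec,
    controls: SolverControls | None = None,
    model: SproutModel | None = None,
) -> tuple[SproutModel, State, dict]:
    """Run the staged tissue-case initialisation; returns the model, the
    protease-free reference state (with HSPG imposed) and the calibration."""
    if spec.case != "tissue":
        raise ValidationError("staged initialisation applies to the tissue case")
    model = model or spec.build_model()
    controls = controls or default_controls(model)
    p = model.params
    g0 = p.boundary.g0
    ratio = g0 * p.geometry.L / p.geometry.L_tip
    v_top, v_bot = p.boundary.V0 * (1.0 + ratio), p.boundary.V0 * (1.0 - ratio)

    # stage 1: Dirichlet gradient, no HSPG, receptors equilibrating
    model.active_species = ("V165",)
    model.bc = {
        "V165": {"z_lo": ("dirichlet", v_bot), "z_hi": ("dirichlet", v_top)},
        "V114": {},
        "P": {},
    }
    st = model.initial_state(V165_fluid=p.boundary.V0)
    try:
        st, diag1 = model.solve_steady_state(st, controls)
    except NonConvergenceError as err:
        raise NonConvergenceError(f"case-2 stage 1 (Dirichlet): {err}", err.history)

    # stage 2: convert to flux boundaries
    calib = case2_calibrate(model, st)
    model.bc = {
        "V165": {
            "z_hi": ("flux_in", calib["q_molar_um"]),
            "z_lo": ("robin", calib["kclear"]),
        },
        "V114": {"z_lo": ("robin", calib["kclear"])},
        "P": {},
    }

    # stage 3: re-converge under the flux boundaries
    try:
        st, diag3 = model.solve_steady_state(st, controls)
    except NonConvergenceError as err:
        raise NonConvergenceError(f"case-2 stage 3 (flux boundaries): {err}", err.history)

    # stage 4: impose HSPG binding equilibrium
    model.impose_hspg_equilibrium(st)
    diags = {"stage1": diag1, "stage3": diag3, "calibration": calib}
    return model, st, diags


def _case1_reference(
    model: SproutModel, controls: SolverControls
) -> tuple[State, dict]:
    """Protease-free isolated-sprout steady state with HSPG imposed."""
    p = model.params
    model.active_species = ("V165",)
    model.bc = case1_boundaries(p.boundary.V0, p.boundary.P0)
    st = model.initial_state(V165_fluid=p.boundary.V0)
    try:
        st, diag = model.solve_steady_state(st, controls)
    except NonConvergenceError as err:
        raise NonConvergenceError(f"case-1 reference stage: {err}", err.history)
    model.impose_hspg_equilibrium(st)
    return st, diag


def run_scenario(
    spec: ScenarioSpec,
    controls: SolverControls | None = None,
    reference: tuple[SproutModel, State] | None = None,
) -> ScenarioResult:
    """Build the protease-free reference state, switch on the protease per
    ``spec.protease_mode``, converge to steady state and collect results.

    ``reference`` may carry a previously computed (model, reference-state)
    pair for the same parameters to skip the reference stage.
    """
    calib: dict = {}
    diags: dict = {}
    if reference is not None:
        model, ref = reference[0], reference[1].copy()
    elif spec.case == "tissue":
        model, ref, diags = initialize_case2(spec, controls)
        calib = diags.get("calibration", {})
    else:
        model = spec.build_model()
        controls = controls or default_controls(model)
        ref, diag = _case1_reference(model, controls)
        diags["reference"] = diag
    controls = controls or default_controls(model)

    st = ref.copy()
    if spec.protease_mode == "none":
        result_state, diag2 = st, {"time_to_steady_s": 0.0, "n_steps": 0, "total_sor_iters": 0}
    else:
        if spec.protease_mode == "uniform_field":
            model.clamp_uniform_protease(st)
        elif spec.protease_mode == "tethered":
            st.surface.P_teth = model.p_tethered.copy()
        if spec.case == "isolated":
            # far-field clamps for the protease stage
            model.bc = case1_boundaries(model.params.boundary.V0, model.params.boundary.P0)
        try:
            if spec.protease_mode == "secreted":
                # the protease transport has no VEGF feedback: march it to its
                # own steady state first, then the VEGF species against it
                model.active_species = ("P",)
                st, diag_p = model.solve_steady_state(st, controls)
                diags["protease_field"] = diag_p
            model.active_species = ("V165", "V114", "V165H")
            result_state, diag2 = model.solve_steady_state(st, controls)
        except NonConvergenceError as err:
            raise NonConvergenceError(f"protease stage ({spec.name}): {err}", err.history)
    diags["protease_stage"] = diag2
    return ScenarioResult(
        name=spec.name,
        model=model,
        state=result_state,
        reference=ref,
        diagnostics=diags,
        calibration=calib,
    )


def sweep(
    base: ScenarioSpec,
    axes: Mapping[str, list],
    controls: SolverControls | None = None,
    metrics_location: str = "surface",
) -> pd.DataFrame:
    """Run ``base`` over the cartesian product of ``axes`` (field name ->
    values; fields of :class:`ScenarioSpec` or parameter overrides).

    One row per grid point, in deterministic (itertools product) order;
    failed points are recorded with the error message and the sweep
    continues.
    """
    from itertools import product

    from .analysis import conversion_metrics

    if not axes:
        raise ValidationError("sweep needs at least one axis")
    names = list(axes)
    rows = []
    spec_fields = set(ScenarioSpec.__dataclass_fields__)
    for values in product(*(axes[n] for n in names)):
        point = dict(zip(names, values))
        spec_kw = {k: v for k, v in point.items() if k in spec_fields}
        ov_kw = {k: v for k, v in point.items() if k not in spec_fields}
        spec_i = replace(
            base,
            name=base.name + "/" + ",".join(f"{k}={v:g}" for k, v in point.items()),
            overrides={**base.overrides, **ov_kw},
            **spec_kw,
        )
        row: dict[str, Any] = dict(point)
        row["scenario"] = spec_i.name
        try:
            res = run_scenario(spec_i, controls)
            row.update(conversion_metrics(res, metrics_location).as_dict())
            row["error"] = ""
        except Exception as err:  # failed point: record, continue
            row["error"] = f"{type(err).__name__}: {err}"
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Preset battery: the named in-silico experiments.
PRESETS: dict[str, ScenarioSpec] = {
    "fig2-reference": ScenarioSpec(
        name="fig2-reference",
        case="isolated",
        protease_mode="secreted",
        protease_level=3.0e6,
        kdeg=0.0,
    ),
    "fig2-kdeg-1e-4": ScenarioSpec(
        name="fig2-kdeg-1e-4",
        case="isolated",
        protease_mode="secreted",
        protease_level=3.0e6,
        kdeg=1.0e-4,
    ),
    "fig2-kdeg-1e-2": ScenarioSpec(
        name="fig2-kdeg-1e-2",
        case="isolated",
        protease_mode="secreted",
        protease_level=3.0e6,
        kdeg=1.0e-2,
    ),
    "fig4-tethered-1e5": ScenarioSpec(
        name="fig4-tethered-1e5",
        case="isolated",
        protease_mode="tethered",
        protease_level=1.0e5,
    ),
    "fig4-tethered-1e10": ScenarioSpec(
        name="fig4-tethered-1e10",
        case="isolated",
        protease_mode="tethered",
        protease_level=1.0e10,
    ),
    "fig5-10nM": ScenarioSpec(
        name="fig5-10nM",
        case="tissue",
        protease_mode="uniform_field",
        protease_level=10.0e-9,
    ),
    "capture-tip-only": ScenarioSpec(
        name="capture-tip-only",
        case="isolated",
        protease_mode="none",
        receptor_placement="tip",
    ),
    "case1-reference": ScenarioSpec(
        name="case1-reference",
        case="isolated",
        protease_mode="none",
    ),
}


def get_preset(name: str) -> ScenarioSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
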