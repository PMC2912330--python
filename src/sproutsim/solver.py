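"""Implicit finite-volume solver for the sprout reaction-diffusion system.

State layout
------------
Three diffusible species (VEGF165, VEGF114, protease) and the immobile
VEGF165-HSPG complex live on the 2-D cylindrical grid as *bulk* molar
concentrations; free HSPG is eliminated through site conservation
(``H = H_total - V165H``, exact because cleavage returns the site).  The
43 nm basement membrane around the sprout is a dedicated per-axial-node
state vector carrying *fluid* molar concentrations plus VEGFR2 surface
densities (mol per 1e15 um^2, the natural unit for ~10^4 receptors/cell).

Amount bookkeeping uses "AU" = molar x um^3 (1 AU = 1e-15 mol); surface
densities in mol/1e15 um^2 times areas in um^2 are in the same unit, so no
Avogadro factors appear inside the solver.

Time stepping is first-order fully implicit.  Each step's coupled nonlinear
system is solved by red-black successive over-relaxation: every sweep
updates each unknown from its own implicit equation with all partners at
their current iterates (bilinear reaction terms are linear in the unknown
being updated, so each scalar update is exact).  The converged step is
declared when the largest fractional per-node change in a sweep falls
below ``convergence_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import N_AVOGADRO
from .grid import Grid, build_grid
from .params import ParameterSet

__all__ = [
    "SolverControls",
    "FieldState",
    "SurfaceState",
    "State",
    "SproutModel",
    "NonConvergenceError",
]

DIFFUSIBLE = ("V165", "V114", "P")
#: mol/1e15 um^2 == molar * um; converts mol/um^2 to the internal surface unit
SURF = 1.0e15


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, history=None):
        super().__init__(msg)
        self.history = list(history or [])


@dataclass
class SolverControls:
    """Numerical controls for the implicit stepper and steady-state march."""

    dt_init: float = 0.1
    dt_growth: float = 1.2
    dt_max: float = 600.0
    sor_omega: float = 1.5
    max_iters: int = 5000
    convergence_tol: float = 1.0e-7
    steady_tol: float = 1.0e-6  # max fractional change per simulated hour
    max_time: float = 2.0e6  # simulated seconds before giving up
    extrapolate_guess: bool = True
    #: direct sparse steady solve as the march's initial state (the march
    #: remains the arbiter of steady state)
    presolve: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.sor_omega < 2.0):
            raise ValueError("SOR relaxation factor must lie in (0, 2)")
        if self.convergence_tol <= 0 or self.steady_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FieldState:
    """Bulk molar concentrations on the (nz, nr) grid."""

    V165: np.ndarray
    V114: np.ndarray
    P: np.ndarray
    V165H: np.ndarray
    frame: str = "bulk"

    def copy(self) -> "FieldState":
        return FieldState(
            self.V165.copy(), self.V114.copy(), self.P.copy(), self.V165H.copy()
        )


@dataclass
class SurfaceState:
    """Basement-membrane layer state, indexed by BM node (wall nodes along the
    sprout, then the tip end-cap node last).  Concentrations are fluid molar;
    receptor densities are mol/1e15 um^2; ``P_teth`` is the fixed effective
    pore concentration of surface-tethered protease."""

    V165: np.ndarray
    V114: np.ndarray
    P: np.ndarray
    V165H: np.ndarray
    R2: np.ndarray
    V165R2: np.ndarray
    V114R2: np.ndarray
    P_teth: np.ndarray
    frame: str = "fluid"

    def copy(self) -> "SurfaceState":
        return SurfaceState(*(getattr(self, k).copy() for k in _SURF_KEYS), frame=self.frame)


_SURF_KEYS = ("V165", "V114", "P", "V165H", "R2", "V165R2", "V114R2", "P_teth")
_FIELD_KEYS = ("V165", "V114", "P", "V165H")


@dataclass
class State:
    field: FieldState
    surface: SurfaceState
    t: float = 0.0

    def copy(self) -> "State":
        return State(self.field.copy(), self.surface.copy(), self.t)


def _rel_change(new: np.ndarray, old: np.ndarray) -> float:
    """Largest fractional per-node change; nodes far below the species scale
    are measured against a floor of 1e-9 x the species maximum."""
    scale = max(np.max(np.abs(new)), np.max(np.abs(old)))
    if scale == 0.0:
        return 0.0
    floor = 1.0e-9 * scale
    return float(np.max(np.abs(new - old) / (np.abs(new) + floor)))


class SproutModel:
    """Discretised sprout model: grid + parameters + scenario switches.

    Parameters
    ----------
    params
        Full parameter set (kinetics, geometry, matrix, boundary).
    grid
        Mesh; built from ``params.geometry`` if omitted.
    receptor_placement
        ``"sprout"`` (VEGFR2 on every sprout cell), ``"tip"`` (tip cell
        only), ``"tip_front"`` (leading-edge microdomain) or ``"none"``.
    protease_mode
        ``"none"``, ``"secreted"`` (flux from the tip), ``"uniform_field"``
        (protease clamped everywhere) or ``"tethered"`` (fixed count affixed
        to the tip's BM layer).
    tethered_count
        Number of tethered protease molecules (tethered mode).
    secretion_placement / tethered_placement
        ``"tip"`` spreads uniformly over the tip-cell surface,
        ``"front_edge"`` concentrates everything in the leading-edge nodes.
    bare_tip
        Remove the basement membrane over the tip cell (its surface nodes
        then see ECM porosity/HSPG and no membrane resistance).
    """

    def __init__(
        self,
        params: ParameterSet,
        grid: Grid | None = None,
        *,
        spacing: str = "coarse",
        receptor_placement: str = "sprout",
        protease_mode: str = "none",
        tethered_count: float = 0.0,
        secretion_placement: str = "tip",
        tethered_placement: str = "tip",
        bare_tip: bool = False,
    ) -> None:
        self.params = params
        self.grid = grid if grid is not None else build_grid(params.geometry, spacing)
        if receptor_placement not in ("sprout", "tip", "tip_front", "none"):
            raise ValueError(f"unknown receptor placement {receptor_placement!r}")
        if protease_mode not in ("none", "secreted", "uniform_field", "tethered"):
            raise ValueError(f"unknown protease mode {protease_mode!r}")
        if tethered_count < 0:
            raise ValueError("tethered protease count must be non-negative")
        self.receptor_placement = receptor_placement
        self.protease_mode = protease_mode
        self.tethered_count = float(tethered_count)
        self.secretion_placement = secretion_placement
        self.tethered_placement = tethered_placement
        self.bare_tip = bare_tip
        #: species actually solved; others are held fixed
        self.active_species: tuple[str, ...] = ("V165", "V114", "P", "V165H")
        #: boundary conditions, bc[species][edge] = (kind, value)
        self.bc: dict[str, dict[str, tuple]] = {s: {} for s in DIFFUSIBLE}

        self._setup_geometry()
        self._setup_bm_nodes()

    # ------------------------------------------------------------------
    def _setup_geometry(self) -> None:
        g, m = self.grid, self.params.matrix
        self.vol = g.cell_volumes
        self.act = g.active
        self.g_z, self.g_r = _face_conductances_cached(g, m.D_ECM)
        gsum = np.zeros((g.nz, g.nr))
        gsum += self.g_z[:-1, :] + self.g_z[1:, :]
        gsum += self.g_r[:, :-1] + self.g_r[:, 1:]
        self.gsum = gsum
        cmask = (np.add.outer(np.arange(g.nz), np.arange(g.nr)) % 2) == 0
        self.color_masks = (cmask & self.act, (~cmask) & self.act)

    def _setup_bm_nodes(self) -> None:
        g, geo, m = self.grid, self.params.geometry, self.params.matrix
        wall = g.sprout_wall_nodes
        self.n_wall = len(wall)
        self.wall_iz = wall
        self.n_bm = self.n_wall + 1  # + end cap
        self.cap_index = self.n_bm - 1

        dz = g.dz[wall]
        A = 2.0 * np.pi * geo.R_sprout * dz
        A_cap = np.pi * geo.R_sprout**2
        self.bm_area = np.concatenate([A, [A_cap]])

        tip_mask = np.zeros(self.n_bm, dtype=bool)
        tip_mask[: self.n_wall][np.isin(wall, g.tip_wall_nodes)] = True
        tip_mask[self.cap_index] = True
        self.tip_mask = tip_mask
        front_mask = np.zeros(self.n_bm, dtype=bool)
        front_mask[self.cap_index] = True
        if self.n_wall:
            front_mask[self.n_wall - 1] = True  # wall node adjacent to z = 0
        self.front_mask = front_mask

        bare = tip_mask.copy() if self.bare_tip else np.zeros(self.n_bm, bool)
        self.K_layer = np.where(bare, m.K_ECM, m.K_BM)
        self.H_tot_layer = np.where(bare, m.H_total_ECM, m.H_total_BM)
        d = geo.d_BM
        self.layer_thickness = d
        self.pore_depth = d * self.K_layer  # um; fluid conc x area x this = AU
        self.Vp = self.bm_area * self.pore_depth

        # exchange resistance BM node <-> first ECM ring cell (AU/s per unit
        # fluid-concentration difference -> conductance 1/R_tot)
        rc1 = g.r_centers[1]
        R_s = geo.R_sprout
        R_bm_wall = np.where(bare, 0.0, (d / 2.0) / (m.D_BM * m.K_BM)) / np.maximum(self.bm_area, 1e-300)
        R_ecm_wall = np.log(rc1 / R_s) / (2.0 * np.pi * dz * m.D_ECM * m.K_ECM)
        R_wall = R_bm_wall[: self.n_wall] + R_ecm_wall

        iz_cap = g.cap_cell
        zc_cap = g.z_centers[iz_cap]
        R_bm_cap = (0.0 if (self.bare_tip) else (d / 2.0) / (m.D_BM * m.K_BM)) / A_cap
        R_ecm_cap = zc_cap / (m.D_ECM * m.K_ECM * A_cap)
        self.exch_conductance = 1.0 / np.concatenate([R_wall, [R_bm_cap + R_ecm_cap]])
        self.cap_iz = iz_cap

        # axial diffusion along the BM sheath (wall chain only)
        if self.n_wall > 1:
            zc = g.z_centers[wall]
            a_cross = 2.0 * np.pi * R_s * d * m.K_BM
            self.bm_axial_g = m.D_BM * a_cross / np.diff(zc)
        else:
            self.bm_axial_g = np.zeros(0)

        # receptor placement
        rmask = np.zeros(self.n_bm, dtype=bool)
        if self.receptor_placement == "sprout":
            rmask[:] = True
        elif self.receptor_placement == "tip":
            rmask = tip_mask.copy()
        elif self.receptor_placement == "tip_front":
            rmask = front_mask.copy()
        self.receptor_mask = rmask

        # protease secretion flux per node (AU um^-2 s^-1 = M um / s)
        qflux = np.zeros(self.n_bm)
        if self.protease_mode == "secreted":
            rate_mol_s = self.params.kinetics.qP / 3600.0 / N_AVOGADRO  # mol/s
            target = front_mask if self.secretion_placement == "front_edge" else tip_mask
            area = self.bm_area[target].sum()
            qflux[target] = rate_mol_s / area * SURF
        self.secretion_flux = qflux

        # tethered protease effective pore concentration per node (fluid M)
        pteth = np.zeros(self.n_bm)
        if self.protease_mode == "tethered" and self.tethered_count > 0:
            target = front_mask if self.tethered_placement == "front_edge" else tip_mask
            pore_vol_l = (self.bm_area[target] * self.pore_depth[target]).sum() * 1e-15
            pteth[target] = self.tethered_count / (N_AVOGADRO * pore_vol_l)
        self.p_tethered = pteth

    # ------------------------------------------------------------------
    def initial_state(
        self,
        V165_fluid: float | np.ndarray | None = None,
        with_hspg: bool = False,
    ) -> State:
        """Uniform (or per-cell) initial state at fluid concentration
        ``V165_fluid`` (defaults to the boundary V0), receptors at their
        turnover steady state, everything else zero."""
        p = self.params
        g = self.grid
        v0 = p.boundary.V0 if V165_fluid is None else V165_fluid
        shape = (g.nz, g.nr)
        V165 = np.where(self.act, np.broadcast_to(v0, shape) * p.matrix.K_ECM, 0.0)
        zeros = np.zeros(shape)
        fs = FieldState(V165.astype(float), zeros.copy(), zeros.copy(), zeros.copy())

        nb = self.n_bm
        r2 = np.where(self.receptor_mask, p.r2_density * SURF, 0.0)
        ss = SurfaceState(
            V165=np.full(nb, float(np.mean(np.broadcast_to(v0, shape)))),
            V114=np.zeros(nb),
            P=np.zeros(nb),
            V165H=np.zeros(nb),
            R2=r2,
            V165R2=np.zeros(nb),
            V114R2=np.zeros(nb),
            P_teth=self.p_tethered.copy(),
        )
        st = State(fs, ss)
        if with_hspg:
            self.impose_hspg_equilibrium(st)
        # note: the uniform-protease clamp is applied by the scenario runner
        # at the protease stage, never in the protease-free reference stages
        return st

    def impose_hspg_equilibrium(self, state: State) -> None:
        """Impose [V165H] = [V]*[H]_total/(Kd + [V]) everywhere (the staged-
        initialisation shortcut: soluble steady state is HSPG-independent in
        the absence of proteases)."""
        from .kinetics import hspg_equilibrium

        p = self.params
        Kd = p.kinetics.Kd_H
        K = p.matrix.K_ECM
        v_f = state.field.V165 / K
        vh_f = hspg_equilibrium(v_f, p.matrix.H_total_ECM, Kd)
        state.field.V165H = np.where(self.act, vh_f * K, 0.0)
        state.surface.V165H = hspg_equilibrium(state.surface.V165, self.H_tot_layer, Kd)

    def clamp_uniform_protease(self, state: State) -> None:
        level = self.params.boundary.uniform_protease
        if level is None:
            level = self.params.boundary.P0
        state.field.P = np.where(self.act, level * self.params.matrix.K_ECM, 0.0)
        state.surface.P = np.full(self.n_bm, level)

    # ------------------------------------------------------------------
    def _bc_arrays(self, species: str):
        """(g_dir, g_dir_times_value, flux_src, robin_g) arrays for one species."""
        g = self.grid
        m = self.params.matrix
        nz, nr = g.nz, g.nr
        g_dir = np.zeros((nz, nr))
        g_dir_c = np.zeros((nz, nr))
        flux_src = np.zeros((nz, nr))
        robin = np.zeros((nz, nr))
        gb = _boundary_conductances_cached(g, m.D_ECM)
        ring = g.ring_areas

        for edge, spec in self.bc.get(species, {}).items():
            kind = spec[0]
            if kind == "noflux":
                continue
            if edge == "z_lo":
                sl = (0, slice(None))
                face_area = ring
            elif edge == "z_hi":
                sl = (-1, slice(None))
                face_area = ring
            elif edge == "r_hi":
                sl = (slice(None), -1)
                face_area = 2.0 * np.pi * g.r_faces[-1] * g.dz
            else:
                raise ValueError(f"unknown edge {edge!r}")
            if kind == "dirichlet":
                value_bulk = spec[1] * m.K_ECM  # fluid -> bulk
                g_dir[sl] += gb[edge]
                g_dir_c[sl] += gb[edge] * value_bulk
            elif kind == "flux_in":
                flux_src[sl] += spec[1] * face_area  # M um/s * um^2 -> AU/s
            elif kind == "robin":
                robin[sl] += spec[1] * face_area  # kclear * area, acts on bulk C
            else:
                raise ValueError(f"unknown BC kind {kind!r}")
        g_dir[~self.act] = 0.0
        g_dir_c[~self.act] = 0.0
        flux_src[~self.act] = 0.0
        robin[~self.act] = 0.0
        return g_dir, g_dir_c, flux_src, robin

    def _unpinned_species(self) -> frozenset:
        """Active diffusible species with no Dirichlet boundary anywhere
        (their global mass mode is only weakly constrained)."""
        out = []
        for name in DIFFUSIBLE:
            if name not in self.active_species:
                continue
            if name == "P" and self.protease_mode == "uniform_field":
                continue
            kinds = {spec[0] for spec in self.bc.get(name, {}).values()}
            if "dirichlet" not in kinds:
                out.append(name)
        return frozenset(out)

    # ------------------------------------------------------------------
    def _sweep(self, st: State, old: State, dt: float, omega: float, bc_cache) -> float:
        """One red-black SOR sweep over every active unknown; returns the
        largest fractional per-node change."""
        p = self.params
        k = p.kinetics
        K = p.matrix.K_ECM
        inv_dt = 1.0 / dt
        f = st.field
        worst = 0.0

        H_tot_bulk = p.matrix.H_total_ECM * K

        solveP = "P" in self.active_species and self.protease_mode != "uniform_field"
        wall_iz = self.wall_iz
        exch = self.exch_conductance
        exch_wall = exch[: self.n_wall]
        exch_cap = exch[self.cap_index]

        for name in DIFFUSIBLE:
            if name not in self.active_species:
                continue
            if name == "P" and not solveP:
                continue
            C = getattr(f, name)
            C_old = getattr(old.field, name)
            g_dir, g_dir_c, flux_src, robin = bc_cache[name]

            # reaction coefficients, linear in this species; HSPG binding is
            # only active together with its bound-pool species
            hspg_on = "V165H" in self.active_species
            if name == "V165":
                H_b = H_tot_bulk - f.V165H
                src = k.koff_H * f.V165H if hspg_on else 0.0
                sink = (k.kP * f.P) / K
                if hspg_on:
                    sink = sink + (k.kon_H / K) * H_b
            elif name == "V114":
                src = (k.kP / K) * f.P * (f.V165 + f.V165H)
                sink = 0.0
            else:  # P
                src = 0.0
                sink = k.kdeg

            # BM exchange contributions into the first ECM ring / cap cell
            wall_num = np.zeros_like(C)
            wall_den = np.zeros_like(C)
            c_bm = getattr(st.surface, name)
            if self.n_wall:
                wall_num[wall_iz, 1] += exch_wall * c_bm[: self.n_wall]
                wall_den[wall_iz, 1] += exch_wall / K
            wall_num[self.cap_iz, 0] += exch_cap * c_bm[self.cap_index]
            wall_den[self.cap_iz, 0] += exch_cap / K

            vol = self.vol
            num_static = (
                vol * C_old * inv_dt + g_dir_c + flux_src + vol * src + wall_num
            )
            den = (
                vol * inv_dt
                + self.gsum
                + g_dir
                + robin
                + vol * sink
                + wall_den
            )

            before = C.copy()
            for mask in self.color_masks:
                Cp = np.pad(C, 1)
                nb = (
                    self.g_z[:-1, :] * Cp[:-2, 1:-1]
                    + self.g_r[:, :-1] * Cp[1:-1, :-2]
                    + self.g_z[1:, :] * Cp[2:, 1:-1]
                    + self.g_r[:, 1:] * Cp[1:-1, 2:]
                )
                C_gs = (num_static + nb) / den
                C[mask] += omega * (C_gs[mask] - C[mask])

            # constant-mode deflation: with flux/Robin-only boundaries the
            # global mass mode is barely pinned and plain SOR stalls on it; a
            # uniform shift solving the summed residual removes it exactly
            # for transport.  Dirichlet-pinned species do not need it.
            if name in self._unpinned_species():
                Cp = np.pad(C, 1)
                nb = (
                    self.g_z[:-1, :] * Cp[:-2, 1:-1]
                    + self.g_r[:, :-1] * Cp[1:-1, :-2]
                    + self.g_z[1:, :] * Cp[2:, 1:-1]
                    + self.g_r[:, 1:] * Cp[1:-1, 2:]
                )
                res = (num_static + nb - den * C)[self.act]
                pin = (den - self.gsum)[self.act]
                pin_sum = float(np.sum(pin))
                if pin_sum > 0:
                    delta = float(np.sum(res)) / pin_sum
                    C[self.act] += delta
            worst = max(worst, _rel_change(C, before))

        # immobile bound pool (exact pointwise implicit solve)
        if "V165H" in self.active_species:
            a = (k.kon_H / K) * f.V165
            b2 = k.koff_H + (k.kP / K) * f.P
            before = f.V165H.copy()
            VH = (old.field.V165H * inv_dt + a * H_tot_bulk) / (inv_dt + a + b2)
            f.V165H = np.where(self.act, VH, 0.0)
            worst = max(worst, _rel_change(f.V165H, before))

        worst = max(worst, self._update_surface(st, old, dt, bc_cache))
        return worst

    def _update_surface(self, st: State, old: State, dt: float, bc_cache) -> float:
        """Gauss-Seidel update of the BM-layer/surface system (Eqns-style
        ODE rows of the same implicit system)."""
        p = self.params
        k = p.kinetics
        K = p.matrix.K_ECM
        inv_dt = 1.0 / dt
        s, so = st.surface, old.surface
        f = st.field
        exch = self.exch_conductance
        A = self.bm_area
        Vp = self.Vp
        worst = 0.0

        # adjacent ECM cell bulk concentrations, per BM node
        def ring_conc(name):
            arr = getattr(f, name)
            vals = np.empty(self.n_bm)
            vals[: self.n_wall] = arr[self.wall_iz, 1]
            vals[self.cap_index] = arr[self.cap_iz, 0]
            return vals

        def axial_terms(c):
            num = np.zeros(self.n_bm)
            den = np.zeros(self.n_bm)
            if self.bm_axial_g.size:
                gax = self.bm_axial_g
                num[: self.n_wall - 1] += gax * c[1 : self.n_wall]
                num[1 : self.n_wall] += gax * c[: self.n_wall - 1]
                den[: self.n_wall - 1] += gax
                den[1 : self.n_wall] += gax
            return num, den

        P_tot = s.P + s.P_teth
        H_layer = self.H_tot_layer - s.V165H

        solveP = "P" in self.active_species and self.protease_mode != "uniform_field"
        if solveP:
            before = s.P.copy()
            nax, dax = axial_terms(s.P)
            num = (
                Vp * so.P * inv_dt
                + exch * ring_conc("P") / K
                + A * self.secretion_flux
                + nax
            )
            den = Vp * inv_dt + exch + dax + Vp * k.kdeg
            s.P = num / den
            worst = max(worst, _rel_change(s.P, before))
            P_tot = s.P + s.P_teth

        hspg_on = "V165H" in self.active_species
        if "V165" in self.active_species:
            before = s.V165.copy()
            nax, dax = axial_terms(s.V165)
            num = (
                Vp * so.V165 * inv_dt
                + exch * ring_conc("V165") / K
                + A * k.koff_R2 * s.V165R2
                + (Vp * k.koff_H * s.V165H if hspg_on else 0.0)
                + nax
            )
            den = (
                Vp * inv_dt
                + exch
                + dax
                + A * k.kon_R2 * s.R2
                + Vp * ((k.kon_H * H_layer if hspg_on else 0.0) + k.kP * P_tot)
            )
            s.V165 = num / den
            worst = max(worst, _rel_change(s.V165, before))

        if "V165H" in self.active_species:
            before = s.V165H.copy()
            a = k.kon_H * s.V165
            b2 = k.koff_H + k.kP * P_tot
            s.V165H = (so.V165H * inv_dt + a * self.H_tot_layer) / (inv_dt + a + b2)
            worst = max(worst, _rel_change(s.V165H, before))

        if "V114" in self.active_species:
            before = s.V114.copy()
            nax, dax = axial_terms(s.V114)
            num = (
                Vp * so.V114 * inv_dt
                + exch * ring_conc("V114") / K
                + A * k.koff_R2 * s.V114R2
                + Vp * k.kP * P_tot * (s.V165 + s.V165H)
                + nax
            )
            den = Vp * inv_dt + exch + dax + A * k.kon_R2 * s.R2
            s.V114 = num / den
            worst = max(worst, _rel_change(s.V114, before))

        # receptor turnover and binding
        rm = self.receptor_mask
        if rm.any():
            sR2 = p.sR2 * SURF * rm  # insertion only where receptors live
            before = s.R2.copy()
            num = so.R2 * inv_dt + sR2 + k.koff_R2 * (s.V165R2 + s.V114R2)
            den = inv_dt + k.kint + k.kon_R2 * (s.V165 + s.V114)
            s.R2 = np.where(rm, num / den, 0.0)
            worst = max(worst, _rel_change(s.R2, before))

            for bound, lig in (("V165R2", "V165"), ("V114R2", "V114")):
                cur = getattr(s, bound)
                before = cur.copy()
                num = getattr(so, bound) * inv_dt + k.kon_R2 * getattr(s, lig) * s.R2
                den = inv_dt + k.koff_R2 + k.kint
                new = np.where(rm, num / den, 0.0)
                setattr(s, bound, new)
                worst = max(worst, _rel_change(new, before))
        return worst

    # ------------------------------------------------------------------
    def _presolve_partners(self, st: State) -> None:
        """Closed-form steady-state updates of the slaved unknowns (bound
        HSPG pools and the receptor system) given the current fields."""
        p = self.params
        k = p.kinetics
        K = p.matrix.K_ECM
        f, s = st.field, st.surface

        if "V165H" in self.active_species:
            a = (k.kon_H / K) * f.V165
            b2 = k.koff_H + (k.kP / K) * f.P
            H_tot_bulk = p.matrix.H_total_ECM * K
            f.V165H = np.where(self.act, a * H_tot_bulk / (a + b2), 0.0)
            P_tot = s.P + s.P_teth
            a_s = k.kon_H * s.V165
            s.V165H = a_s * self.H_tot_layer / (a_s + k.koff_H + k.kP * P_tot)

        rm = self.receptor_mask
        if rm.any():
            kd_app = (k.koff_R2 + k.kint) / k.kon_R2
            r2_tot = p.r2_density * SURF
            s.R2 = np.where(rm, r2_tot / (1.0 + (s.V165 + s.V114) / kd_app), 0.0)
            s.V165R2 = k.kon_R2 * s.V165 * s.R2 / (k.koff_R2 + k.kint)
            s.V114R2 = k.kon_R2 * s.V114 * s.R2 / (k.koff_R2 + k.kint)

    def _presolve_species(self, st: State, name: str, bc_arrays) -> bool:
        """Direct sparse solve of one species' steady equation (partners
        lagged), jointly over the field and its BM-layer nodes.  Returns
        False when the species has no steady pinning (singular system)."""
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        p = self.params
        k = p.kinetics
        K = p.matrix.K_ECM
        f, s = st.field, st.surface
        g = self.grid
        nz, nr = g.nz, g.nr
        nf = nz * nr
        g_dir, g_dir_c, flux_src, robin = bc_arrays

        hspg_on = "V165H" in self.active_species
        if name == "V165":
            # bound-pool closure: at pM VEGF (far below Kd) the equilibrium
            # V165H is linear in V165, so cleavage of the bound pool folds
            # into an effective sink kP*P*(1+gamma), gamma = bound/free ratio
            src = 0.0
            sink = (k.kP * f.P) / K
            if hspg_on:
                H_tot_bulk = p.matrix.H_total_ECM * K
                gamma = (k.kon_H / K) * H_tot_bulk / (k.koff_H + (k.kP / K) * f.P)
                sink = sink * (1.0 + gamma)
        elif name == "V114":
            src = (k.kP / K) * f.P * (f.V165 + f.V165H)
            sink = 0.0
        else:
            src = 0.0
            sink = k.kdeg

        vol = self.vol
        diag = self.gsum + g_dir + robin + vol * sink
        rhs = g_dir_c + flux_src + vol * src
        # BM exchange couplings
        wall_cells = np.concatenate(
            [self.wall_iz * nr + 1, [self.cap_iz * nr + 0]]
        )
        diag = diag.ravel().copy()
        diag[wall_cells] += self.exch_conductance / K

        pinned = float(np.sum((g_dir + robin + vol * sink)[self.act]))
        # BM-side sinks can also pin (e.g. receptor capture, cleavage)
        P_tot = s.P + s.P_teth
        if name == "V165":
            bm_sink = self.bm_area * k.kon_R2 * s.R2 * (
                k.kint / (k.koff_R2 + k.kint)
            ) + self.Vp * k.kP * P_tot
        elif name == "V114":
            bm_sink = self.bm_area * k.kon_R2 * s.R2 * (k.kint / (k.koff_R2 + k.kint))
        else:
            bm_sink = self.Vp * k.kdeg + self.bm_area * self.secretion_flux * 0.0
        if pinned + float(np.sum(bm_sink)) <= 0.0:
            return False

        rows, cols, vals = [], [], []
        idx = np.arange(nf).reshape(nz, nr)

        def couple(i0, j0, i1, j1, gg):
            m = gg > 0
            a, b = idx[i0, j0][m], idx[i1, j1][m]
            rows.extend([a, b])
            cols.extend([b, a])
            vals.extend([-gg[m], -gg[m]])

        sl = np.s_
        couple(sl[:-1], sl[:], sl[1:], sl[:], self.g_z[1:-1, :])
        couple(sl[:], sl[:-1], sl[:], sl[1:], self.g_r[:, 1:-1])

        # inactive cells: identity rows
        inact = ~self.act.ravel()
        diag[inact] = 1.0
        rhs = rhs.ravel().copy()
        rhs[inact] = 0.0

        # BM rows
        exch = self.exch_conductance
        A_bm, Vp = self.bm_area, self.Vp
        if name == "V165":
            bm_sink_eff = k.kP * P_tot
            if hspg_on:
                gamma_bm = k.kon_H * self.H_tot_layer / (k.koff_H + k.kP * P_tot)
                bm_sink_eff = bm_sink_eff * (1.0 + gamma_bm)
            bm_diag = exch + A_bm * k.kon_R2 * s.R2 + Vp * bm_sink_eff
            bm_rhs = A_bm * k.koff_R2 * s.V165R2
        elif name == "V114":
            bm_diag = exch + A_bm * k.kon_R2 * s.R2
            bm_rhs = A_bm * k.koff_R2 * s.V114R2 + Vp * k.kP * P_tot * (
                s.V165 + s.V165H
            )
        else:
            bm_diag = exch + Vp * k.kdeg
            bm_rhs = A_bm * self.secretion_flux

        bm_rows = nf + np.arange(self.n_bm)
        full_diag = np.concatenate([diag, bm_diag])
        full_rhs = np.concatenate([rhs, bm_rhs])
        # field <-> BM off-diagonals: field gains exch*c_bm, BM gains exch*C/K
        rows.extend([wall_cells, bm_rows])
        cols.extend([bm_rows, wall_cells])
        vals.extend([-exch, -exch / K])
        if self.bm_axial_g.size:
            gax = self.bm_axial_g
            a = bm_rows[: self.n_wall - 1]
            b = bm_rows[1 : self.n_wall]
            rows.extend([a, b])
            cols.extend([b, a])
            vals.extend([-gax, -gax])
            full_diag[a] += gax
            full_diag[b] += gax

        n_all = nf + self.n_bm
        rows.append(np.arange(n_all))
        cols.append(np.arange(n_all))
        vals.append(full_diag)
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_all, n_all),
        )
        x = spla.spsolve(A.tocsc(), full_rhs)
        if not np.all(np.isfinite(x)):
            return False
        setattr(f, name, np.maximum(x[:nf].reshape(nz, nr), 0.0))
        setattr(s, name, np.maximum(x[nf:], 0.0))
        return True

    def _steady_presolve(self, st: State, tol: float = 1e-7, max_rounds: int = 80) -> None:
        """Accelerated Picard iteration of direct per-species steady solves,
        used as the initial state for the implicit march (which remains the
        arbiter of steady state).

        The protease field is independent and solved once; VEGF165 and its
        lagged partners (bound HSPG, receptors) are iterated to ``tol`` with
        Aitken extrapolation on the geometrically converging sequence;
        VEGF114, which feeds back on nothing, is solved last.
        """
        order = [
            name
            for name in ("P", "V165", "V114")
            if name in self.active_species
            and not (name == "P" and self.protease_mode == "uniform_field")
        ]
        bc_arrays = {name: self._bc_arrays(name) for name in order}
        if "P" in order:
            self._presolve_species(st, "P", bc_arrays["P"])

        if "V165" in order:
            # the bound pool is eliminated analytically inside the V165
            # solve; the only remaining lag is the (weak) receptor feedback
            for _ in range(max_rounds):
                before_f = st.field.V165.copy()
                self._presolve_partners(st)
                self._presolve_species(st, "V165", bc_arrays["V165"])
                if _rel_change(st.field.V165, before_f) < tol:
                    break
            self._presolve_partners(st)

        if "V114" in order:
            self._presolve_species(st, "V114", bc_arrays["V114"])
        self._presolve_partners(st)

    # ------------------------------------------------------------------
    def advance_implicit(
        self,
        state: State,
        dt: float,
        controls: SolverControls,
        guess: State | None = None,
    ) -> tuple[State, int]:
        """One fully-implicit step of size ``dt``.

        Returns the new state and the number of SOR sweeps used.  Raises
        :class:`NonConvergenceError` (with the residual history attached)
        if the sweep cap is exceeded.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        old = state
        st = (guess if guess is not None else state).copy()
        st.t = state.t + dt
        bc_cache = {name: self._bc_arrays(name) for name in DIFFUSIBLE}
        # the projected-error stall guard is only needed when a species has no
        # Dirichlet pinning (flux/Robin-only boundaries), where SOR's slowest
        # mode can leave updates far below the remaining error
        guarded = bool(self._unpinned_species())
        history = []
        for it in range(1, controls.max_iters + 1):
            worst = self._sweep(st, old, dt, controls.sor_omega, bc_cache)
            history.append(worst)
            if worst <= controls.convergence_tol:
                if not guarded:
                    return st, it
                if it >= 3:
                    # geometric-series estimate of the remaining change from
                    # the observed contraction factor
                    rho = max(
                        history[-1] / history[-2] if history[-2] > 0 else 0.0,
                        history[-2] / history[-3] if history[-3] > 0 else 0.0,
                    )
                    rho = min(rho, 0.995)
                    projected = worst * rho / (1.0 - rho)
                    if projected <= controls.convergence_tol:
                        return st, it
        raise NonConvergenceError(
            f"SOR did not reach {controls.convergence_tol:g} in "
            f"{controls.max_iters} sweeps (last change {history[-1]:.3e})",
            history,
        )

    def solve_steady_state(
        self, initial: State, controls: SolverControls | None = None
    ) -> tuple[State, dict]:
        """Pseudo-time march with a geometrically growing step until the
        largest fractional change per simulated hour drops below
        ``controls.steady_tol`` for every node of every species."""
        controls = controls or SolverControls()
        st = initial.copy()
        prev: State | None = None
        prev_dt = None
        dt = controls.dt_init
        if controls.presolve and self.active_species:
            self._steady_presolve(st)
            # from a (near-)steady guess, start at the step cap: the march
            # then only has to confirm (or finish) convergence
            dt = controls.dt_max
        total_iters = 0
        n_steps = 0
        rates = []
        calm = 0
        backoffs = 0
        window = 5  # steps per steadiness evaluation
        anchor, anchor_t = st.copy(), st.t
        while True:
            guess = None
            last_rate = rates[-1] if rates else np.inf
            if (
                controls.extrapolate_guess
                and prev is not None
                and last_rate > 10.0 * controls.steady_tol
            ):
                # near steady state the extrapolated guess would perpetuate
                # solver-noise drift that cheap sweeps accept; fall back to
                # the plain fixed-point guess there
                guess = _extrapolate(prev, st, dt / prev_dt)
            try:
                new, iters = self.advance_implicit(st, dt, controls, guess=guess)
            except NonConvergenceError:
                # a too-ambitious step: halve dt and retry (the SOR sweep cap
                # is a per-step budget, not a death sentence for the march)
                backoffs += 1
                if backoffs > 12:
                    raise
                dt *= 0.5
                continue
            backoffs = 0
            total_iters += iters
            n_steps += 1
            rates.append(self._state_change(new, st) / dt * 3600.0)
            prev, prev_dt = st, dt
            st = new
            # steadiness is judged on the sustained drift over a window of
            # steps (single-step changes sit at the per-step solver noise);
            # two consecutive calm windows are required
            if n_steps % window == 0:
                w_rate = self._state_change(st, anchor) / (st.t - anchor_t) * 3600.0
                anchor, anchor_t = st.copy(), st.t
                calm = calm + 1 if w_rate < controls.steady_tol else 0
                if calm >= 2:
                    break
            if st.t > controls.max_time:
                raise NonConvergenceError(
                    f"no steady state within {controls.max_time:g} simulated "
                    f"seconds (change rate {rates[-1]:.3e}/h, "
                    f"tol {controls.steady_tol:g}/h)",
                    rates,
                )
            dt = min(dt * controls.dt_growth, controls.dt_max)
        diagnostics = {
            "time_to_steady_s": st.t,
            "n_steps": n_steps,
            "total_sor_iters": total_iters,
            "final_rate_per_hour": rates[-1],
            "min_concentration": self.min_concentration(st),
        }
        return st, diagnostics

    def _state_change(self, new: State, old: State) -> float:
        worst = 0.0
        for kname in _FIELD_KEYS:
            if kname in self.active_species or kname == "V165H":
                worst = max(
                    worst,
                    _rel_change(getattr(new.field, kname), getattr(old.field, kname)),
                )
        for kname in _SURF_KEYS:
            if kname == "P_teth":
                continue
            worst = max(
                worst, _rel_change(getattr(new.surface, kname), getattr(old.surface, kname))
            )
        return worst

    # ------------------------------------------------------------------
    def total_mass(self, state: State, species: str) -> float:
        """Total amount (AU = 1e-15 mol) of a diffusible species, including
        its BM-layer pool (and receptor-bound pool for the VEGF isoforms)."""
        f_arr = getattr(state.field, species)
        total = float(np.sum(f_arr * self.vol))
        total += float(np.sum(getattr(state.surface, species) * self.Vp))
        if species == "V165":
            total += float(np.sum(state.field.V165H * self.vol))
            total += float(np.sum(state.surface.V165H * self.Vp))
            total += float(np.sum(state.surface.V165R2 * self.bm_area))
        if species == "V114":
            total += float(np.sum(state.surface.V114R2 * self.bm_area))
        return total

    def min_concentration(self, state: State) -> float:
        vals = [getattr(state.field, kname)[self.act].min() for kname in _FIELD_KEYS]
        vals += [
            getattr(state.surface, kname).min()
            for kname in _SURF_KEYS
            if kname != "P_teth"
        ]
        return float(min(vals))

    # -- convenience accessors ------------------------------------------
    def pericellular(self, state: State, species: str, region: str = "tip") -> float:
        """Area-weighted mean fluid concentration in the BM layer over the
        tip cell (``region="tip"``) or the whole sprout wall."""
        mask = self.tip_mask if region == "tip" else np.ones(self.n_bm, bool)
        w = self.bm_area[mask]
        return float(np.sum(getattr(state.surface, species)[mask] * w) / w.sum())


def _extrapolate(prev: State, cur: State, ratio: float) -> State:
    """Linear extrapolation y* = y + (y - y_prev) * dt_new/dt_old, clipped at
    zero (it is only an initial guess for the implicit solve)."""
    out = cur.copy()
    for kname in _FIELD_KEYS:
        a, b = getattr(prev.field, kname), getattr(cur.field, kname)
        setattr(out.field, kname, np.maximum(b + ratio * (b - a), 0.0))
    for kname in _SURF_KEYS:
        if kname == "P_teth":
            continue
        a, b = getattr(prev.surface, kname), getattr(cur.surface, kname)
        setattr(out.surface, kname, np.maximum(b + ratio * (b - a), 0.0))
    return out


def suggest_omega(grid: Grid) -> float:
    """Near-optimal SOR relaxation factor for this mesh (classic estimate
    for the 5-point stencil); worthwhile on the large isolated-sprout grid."""
    n = max(grid.nz, grid.nr)
    return float(min(2.0 / (1.0 + np.sin(np.pi / n)), 1.98))


# light caches: grids are few and reused across stages (grid object is pinned
# in the value so ids cannot be recycled)
_COND_CACHE: dict = {}
_BCOND_CACHE: dict = {}


def _face_conductances_cached(grid: Grid, D: float):
    from .grid import _face_conductances

    key = (id(grid), D)
    if key not in _COND_CACHE:
        _COND_CACHE[key] = (grid, _face_conductances(grid, D))
    return _COND_CACHE[key][1]


def _boundary_conductances_cached(grid: Grid, D: float):
    from .grid import _boundary_conductances

    key = (id(grid), D)
    if key not in _BCOND_CACHE:
        _BCOND_CACHE[key] = (grid, _boundary_conductances(grid, D))
    return _BCOND_CACHE[key][1]
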