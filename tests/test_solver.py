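"""Implicit stepper: conservation, accuracy, fixed points, surface system."""

import numpy as np
import pytest

from sproutsim import make_parameters
from sproutsim.params import Geometry
from sproutsim.scenarios import case1_boundaries
from sproutsim.solver import SURF, SolverControls, SproutModel
from sproutsim.surface import receptor_occupancy, surface_rhs


def small_model(receptors="none", protease_mode="none", **model_kw):
    """A miniature sprout domain (80 x 26 um) that keeps unit tests fast."""
    params = make_parameters(
        {"L": 40.0, "R_edge": 26.0, "L_tip": 16.0}, case="isolated"
    )
    return SproutModel(
        params, receptor_placement=receptors, protease_mode=protease_mode, **model_kw
    )


class TestConservation:
    def test_pure_diffusion_step_conserves_mass(self):
        """With no-flux boundaries and no reactions, total VEGF is constant
        to 1e-10 relative per step (conservative scheme)."""
        model = small_model()
        model.active_species = ("V165",)
        model.bc = {"V165": {}, "V114": {}, "P": {}}  # all no-flux
        st = model.initial_state(V165_fluid=1e-12)
        # non-uniform blob so diffusion actually happens
        zc = model.grid.z_centers
        st.field.V165 *= (1.0 + 0.8 * np.exp(-((zc[:, None] / 20.0) ** 2)))
        ctl = SolverControls(convergence_tol=1e-13, max_iters=200000)
        m0 = model.total_mass(st, "V165")
        for dt in (1.0, 10.0, 100.0):
            st, _ = model.advance_implicit(st, dt, ctl)
            m1 = model.total_mass(st, "V165")
            assert m1 == pytest.approx(m0, rel=1e-10)

    def test_non_negativity_through_transient(self):
        model = small_model(receptors="sprout", protease_mode="secreted")
        model.bc = case1_boundaries(1e-12, 0.0)
        st = model.initial_state()
        st, diag = model.solve_steady_state(st, SolverControls(steady_tol=1e-4))
        assert diag["min_concentration"] >= 0.0


class TestAccuracy:
    def test_equilibrium_is_a_fixed_point(self):
        """One step from a uniform state clamped at the same boundary value
        changes nothing."""
        model = small_model()
        model.active_species = ("V165",)
        model.bc = case1_boundaries(1e-12, 0.0)
        st = model.initial_state(V165_fluid=1e-12)
        st.surface.V165[:] = 1e-12
        new, _ = model.advance_implicit(st, 100.0, SolverControls())
        assert np.allclose(new.field.V165, st.field.V165, rtol=1e-6)

    def test_decay_only_first_order_accuracy(self):
        """D-isolated decay matches exp(-kdeg t) to first order; halving dt
        halves the error."""
        kdeg = 1e-3
        model = small_model(protease_mode="secreted")
        model.params = model.params.replace(kdeg=kdeg)
        model.active_species = ("P",)
        model.bc = {"V165": {}, "V114": {}, "P": {}}
        model.secretion_flux[:] = 0.0
        horizon = 400.0
        errs = []
        for nsteps in (1, 2):
            st = model.initial_state()
            st.field.P = np.where(model.act, 1e-9, 0.0)
            st.surface.P[:] = 1e-9
            ctl = SolverControls(convergence_tol=1e-12, max_iters=100000)
            for _ in range(nsteps):
                st, _ = model.advance_implicit(st, horizon / nsteps, ctl)
            exact = 1e-9 * np.exp(-kdeg * horizon)
            errs.append(abs(st.field.P[model.act].mean() - exact) / exact)
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.15)

    def test_steady_state_is_dt_path_independent(self):
        """Two different step schedules reach the same steady state within
        0.1% (the steady state does not remember the pseudo-time path)."""
        results = []
        for dt0, cap in ((0.1, 600.0), (0.05, 300.0)):
            model = small_model(receptors="tip")
            model.bc = case1_boundaries(1e-12, 0.0)
            st = model.initial_state()
            model.active_species = ("V165",)
            ctl = SolverControls(dt_init=dt0, dt_max=cap, steady_tol=1e-7, presolve=False)
            out, _ = model.solve_steady_state(st, ctl)
            results.append(out.field.V165.copy())
        ref = np.abs(results[0]).max()
        assert np.max(np.abs(results[0] - results[1])) < 1e-3 * ref


class TestSurfaceSystem:
    def test_receptor_pool_relaxes_to_turnover_steady_state(self):
        """From an empty surface, VEGFR2 relaxes to sR2/kint = [R2]_total
        (insertion/internalization balance, no VEGF)."""
        model = small_model(receptors="sprout")
        model.active_species = ()
        model.bc = {"V165": {}, "V114": {}, "P": {}}
        st = model.initial_state(V165_fluid=0.0)
        st.surface.R2[:] = 0.0
        out, _ = model.solve_steady_state(
            st, SolverControls(steady_tol=1e-7, presolve=False)
        )
        expected = model.params.r2_density * SURF
        assert out.surface.R2[model.receptor_mask] == pytest.approx(expected, rel=1e-4)

    def test_occupancy_against_apparent_kd(self):
        """At a converged state the bound fraction follows
        V/(V + Kd_app) with Kd_app = (koff + kint)/kon = 128 pM."""
        model = small_model(receptors="sprout")
        model.active_species = ("V165",)
        model.bc = case1_boundaries(1e-12, 0.0)
        out, _ = model.solve_steady_state(model.initial_state(), SolverControls())
        k = model.params.kinetics
        kd_app = (k.koff_R2 + k.kint) / k.kon_R2
        assert kd_app == pytest.approx(128e-12, rel=1e-6)
        occ = receptor_occupancy(model, out)
        v_local = model.pericellular(out, "V165")
        assert occ["V165R2"] / (occ["R2"] + occ["V165R2"]) == pytest.approx(
            v_local / (v_local + kd_app), rel=0.01
        )

    def test_surface_rhs_vanishes_at_steady_state(self):
        """The explicit surface RHS evaluates to ~0 on the solver's converged
        state (independent consistency check of the surface rows)."""
        model = small_model(receptors="sprout", protease_mode="tethered", tethered_count=1e5)
        model.bc = case1_boundaries(1e-12, 0.0)
        st = model.initial_state(with_hspg=True)
        out, _ = model.solve_steady_state(st, SolverControls(steady_tol=1e-8))
        rhs = surface_rhs(model, out)
        # scale each derivative by its pool over one hour
        for name in ("V165", "V114", "P", "V165H"):
            scale = max(np.abs(getattr(out.surface, name)).max(), 1e-18)
            assert np.abs(rhs[name]).max() * 3600.0 < 1e-3 * scale
        for name in ("R2", "V165R2", "V114R2"):
            scale = np.abs(out.surface.R2).max()
            assert np.abs(rhs[name]).max() * 3600.0 < 1e-3 * scale

    def test_hspg_site_conservation_in_bm_layer(self):
        """H + V165H = H_total in the BM layer at all times (site-conserving
        formulation)."""
        model = small_model(receptors="tip", protease_mode="tethered", tethered_count=1e5)
        model.bc = case1_boundaries(1e-12, 0.0)
        st = model.initial_state(with_hspg=True)
        out, _ = model.solve_steady_state(st, SolverControls(steady_tol=1e-5))
        assert np.all(out.surface.V165H <= model.H_tot_layer + 1e-20)


class TestTetheredProtease:
    def test_effective_pore_concentration(self):
        """1e5 proteases spread over the tip's BM pores give the 37.5 uM
        effective concentration when the tip area matches the reference."""
        params = make_parameters()
        model = SproutModel(params, protease_mode="tethered", tethered_count=1e5)
        conc = model.p_tethered[model.tip_mask]
        assert conc == pytest.approx(37.5e-6, rel=0.02)
        assert model.p_tethered[~model.tip_mask].max() == 0.0

    def test_front_edge_placement_concentrates(self):
        params = make_parameters()
        uniform = SproutModel(params, protease_mode="tethered", tethered_count=1e5)
        front = SproutModel(
            params,
            protease_mode="tethered",
            tethered_count=1e5,
            tethered_placement="front_edge",
        )
        # leading-edge area (cap + one wall node) is ~4.5x smaller than the tip
        assert front.p_tethered.max() > 4 * uniform.p_tethered.max()
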