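"""Reaction laws, closed-form estimators, and cleavage-rate fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sproutsim import make_parameters
from sproutsim.kinetics import (
    CleavageTimeCourse,
    DegenerateFitWarning,
    conversion_at_clearance,
    equilibration_time,
    fit_effective_kp,
    hspg_equilibrium,
    kp_from_half_life,
    reaction_terms,
    read_time_course_csv,
    required_protease,
    retardation_factor,
    simulate_two_step_cleavage,
    synthetic_cleavage_course,
)
from sproutsim.params import ValidationError

LN2 = math.log(2.0)


class TestReactionTerms:
    def test_binding_equilibrium_is_stationary(self, params):
        """Without protease, the reversible HSPG reaction at equilibrium
        produces zero net rates (detailed balance)."""
        Kd = params.kinetics.Kd_H
        V, H_total = 1e-12, 750e-9
        VH = hspg_equilibrium(V, H_total, Kd)
        r = reaction_terms(V, 0.0, 0.0, H_total - VH, VH, params)
        scale = params.kinetics.kon_H * V * H_total
        for dv in (r.dV165, r.dV114, r.dP, r.dH, r.dV165H):
            assert abs(dv) < 1e-9 * scale

    def test_per_molecule_cleavage_rate(self, params):
        """kP*[P] at the BM pore concentration of 1e5 tethered proteases is
        the printed 0.0236 s^-1 per VEGF molecule."""
        P = 37.5e-6
        r = reaction_terms(1e-12, 0.0, P, 0.0, 0.0, params)
        assert -r.dV165 / 1e-12 == pytest.approx(0.0236, rel=0.02)

    @settings(max_examples=50, deadline=None)
    @given(
        v=st.floats(0, 1e-9),
        v114=st.floats(0, 1e-9),
        p=st.floats(0, 1e-4),
        h=st.floats(0, 1e-4),
        vh=st.floats(0, 1e-4),
        kdeg=st.floats(0, 1e-2),
        kav=st.floats(0.2, 1.0),
    )
    def test_vegf_mass_moves_only_between_pools(self, v, v114, p, h, vh, kdeg, kav):
        """Protease is catalytic: dV165 + dV114 + dV165H = 0 for any state,
        any kdeg, in any frame."""
        ps = make_parameters({"kdeg": kdeg})
        r = reaction_terms(v, v114, p, h, vh, ps, K_av=kav)
        total = r.dV165 + r.dV114 + r.dV165H
        scale = abs(r.dV165) + abs(r.dV114) + abs(r.dV165H) + 1e-30
        assert abs(total) <= 1e-12 * scale
        # HSPG sites are conserved too: dH + dV165H = 0
        assert abs(r.dH + r.dV165H) <= 1e-12 * scale

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValidationError):
            reaction_terms(-1e-12, 0, 0, 0, 0, params)


class TestClosedForms:
    def test_hspg_equilibrium_printed_values(self, params):
        Kd = params.kinetics.Kd_H
        # BM pool at ~1 pM free VEGF: the 540 pM bound level
        assert hspg_equilibrium(1e-12, 13e-6, Kd) == pytest.approx(540e-12, rel=0.03)
        assert hspg_equilibrium(0.0, 13e-6, Kd) == 0.0
        # ECM pool: direct evaluation of the closed form
        assert hspg_equilibrium(1e-12, 750e-9, Kd) == pytest.approx(31.5e-12, rel=0.01)

    @settings(max_examples=50, deadline=None)
    @given(v=st.floats(1e-15, 1e-6), h=st.floats(1e-12, 1e-3))
    def test_hspg_equilibrium_monotone_and_saturating(self, v, h):
        Kd = 23.81e-9
        b = hspg_equilibrium(v, h, Kd)
        assert 0 <= b <= h  # saturates at H_total
        assert hspg_equilibrium(2 * v, h, Kd) >= b
        assert hspg_equilibrium(v, 2 * h, Kd) >= b

    def test_retardation_factor(self, params):
        Kd = params.kinetics.Kd_H
        assert retardation_factor(750e-9, Kd) == pytest.approx(32.5, rel=0.01)
        assert retardation_factor(0.0, Kd) == 1.0
        assert retardation_factor(13e-6, Kd) == pytest.approx(547.0, rel=0.01)

    def test_equilibration_time(self):
        assert equilibration_time(4.2e5, 750e-9, 0.01) == pytest.approx(3.1, rel=0.02)
        assert equilibration_time(4.2e5, 0.0, 0.01) == pytest.approx(100.0)
        # binding-dominated limit
        assert equilibration_time(4.2e5, 1e-3, 0.01) == pytest.approx(
            1.0 / (4.2e5 * 1e-3), rel=1e-3
        )

    def test_conversion_and_required_protease(self):
        kclear = LN2 / 3600.0
        assert required_protease(631.0, kclear, 0.5) == pytest.approx(305e-9, rel=0.02)
        assert required_protease(631.0, kclear, 0.0) == 0.0
        # round trip of the two closed forms
        assert conversion_at_clearance(631.0, 305e-9, kclear) == pytest.approx(0.50, rel=0.01)
        with pytest.raises(ValidationError):
            required_protease(631.0, kclear, 1.0)

    def test_kp_from_half_life_printed_band(self):
        # 1-4 h half-life at ~40 nM plasmin maps onto the 1.2e3-5e3 band
        hi = kp_from_half_life(3600.0, 40e-9)
        lo = kp_from_half_life(4 * 3600.0, 40e-9)
        assert hi == pytest.approx(4.8e3, rel=0.02)
        assert lo == pytest.approx(1.2e3, rel=0.02)
        assert 1.2e3 <= lo <= hi <= 5e3
        # scaling identity: (t, P) and (2t, P/2) give identical kP
        assert kp_from_half_life(2 * 3600.0, 20e-9) == pytest.approx(hi, rel=1e-12)


class TestTwoStepCleavage:
    def test_initial_state(self):
        f = simulate_two_step_cleavage(315.5, 315.5, 40e-9, [0.0])
        assert f[0] == pytest.approx([1.0, 0.0, 0.0])

    @settings(max_examples=30, deadline=None)
    @given(
        k1=st.floats(1.0, 1e4),
        k2=st.floats(1.0, 1e4),
        t=st.floats(0.0, 1e5),
    )
    def test_fractions_sum_to_one(self, k1, k2, t):
        f = simulate_two_step_cleavage(k1, k2, 40e-9, [t])
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(f >= -1e-12)

    def test_fast_second_cut_approaches_one_step(self):
        """k2 -> inf collapses the sequential system onto a single
        exponential with rate 2*k1*P."""
        k1, P = 315.5, 40e-9
        t = np.linspace(0, 6 * 3600, 25)
        f = simulate_two_step_cleavage(k1, 1e4 * k1, P, t)
        one_step = np.exp(-2 * k1 * P * t)
        assert f[:, 0] == pytest.approx(one_step, abs=1e-6)
        # intermediate never accumulates
        assert f[:, 1].max() < 1e-3
        assert f[:, 2] == pytest.approx(1 - one_step, abs=1e-3)


class TestFitEffectiveKp:
    def test_exact_recovery_on_noise_free_single_exponential(self):
        P = 40e-9
        kp = 1e-4 / P  # kP*P = 1e-4 s^-1
        t = np.linspace(0, 8 * 3600, 10)
        course = CleavageTimeCourse(t, np.exp(-kp * P * t), P)
        est, hw = fit_effective_kp(course, n_bootstrap=0)
        assert est == pytest.approx(kp, rel=1e-6)

    def test_recovery_from_two_step_synthetic_data(self):
        """The generator's study conditions: effective kP = 631, 40 nM
        protease, 10 points over 8 h, 2% densitometry noise."""
        course = synthetic_cleavage_course(
            631.0, 40e-9, np.linspace(0, 8 * 3600, 10), noise_sd=0.02, rng=7
        )
        est, hw = fit_effective_kp(course)
        assert est == pytest.approx(631.0, rel=0.05)
        assert hw > 0  # bootstrap produced an uncertainty

    @pytest.mark.parametrize("kp_true", [1e2, 631.0, 1e3, 1e4])
    def test_recovery_across_rate_range(self, kp_true):
        """< 5% relative error on noise-free synthetic data over the
        physiologically debated kP range."""
        P = 40e-9
        t_end = min(5.0 / (kp_true * P), 48 * 3600.0)
        course = synthetic_cleavage_course(kp_true, P, np.linspace(0, t_end, 12))
        est, _ = fit_effective_kp(course, n_bootstrap=0)
        assert est == pytest.approx(kp_true, rel=0.05)

    def test_bootstrap_is_reproducible(self):
        course = synthetic_cleavage_course(
            631.0, 40e-9, np.linspace(0, 8 * 3600, 10), noise_sd=0.02, rng=7
        )
        a = fit_effective_kp(course, seed=1729)
        b = fit_effective_kp(course, seed=1729)
        assert a == b

    def test_constant_course_warns_degenerate(self):
        t = np.linspace(0, 8 * 3600, 8)
        course = CleavageTimeCourse(t, np.ones_like(t), 40e-9)
        with pytest.warns(DegenerateFitWarning):
            est, _ = fit_effective_kp(course, n_bootstrap=0)
        assert est * 40e-9 * t[-1] < 1e-2  # pinned near zero on the data scale

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_effective_kp(CleavageTimeCourse(np.array([0.0, 60.0]), np.array([1.0, 0.9]), 40e-9))

    def test_csv_reader_round_trip(self, tmp_path):
        course = synthetic_cleavage_course(631.0, 40e-9, np.linspace(0, 3600, 5))
        path = tmp_path / "course.csv"
        path.write_text(
            "time_s,intact_fraction,protease_M\n"
            + "\n".join(
                f"{t},{f},{course.protease_conc}"
                for t, f in zip(course.times, course.intact_fraction)
            )
        )
        loaded = read_time_course_csv(path)
        assert loaded.times == pytest.approx(course.times)
        assert loaded.intact_fraction == pytest.approx(course.intact_fraction)
        assert loaded.protease_conc == course.protease_conc
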