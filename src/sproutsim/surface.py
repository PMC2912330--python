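"""Basement-membrane layer / cell-surface reaction system.

The sprout surface carries VEGFR2 under constant insertion (sR2 = kint *
[R2]_total) and internalisation (kint), binding free VEGF165 and VEGF114
with identical rate constants; only free VEGF interacts with receptors
(HSPG-bound VEGF cannot).  The BM layer additionally hosts its own dense
HSPG pool (13 uM, site-conserved) and, in the tethered-protease mode, a
fixed number of surface-affixed proteases whose effective pore
concentration follows from the tiny BM pore volume (1e5 proteases on one
tip cell are 37.5 uM).

:func:`surface_rhs` evaluates the instantaneous time derivatives of every
surface unknown; at a converged steady state the solver's surface rows
satisfy ``surface_rhs ~ 0``, which the test-suite uses as an independent
consistency check.
"""

from __future__ import annotations

import numpy as np

from .solver import SURF, SproutModel, State

__all__ = ["surface_rhs", "capture_probability", "receptor_occupancy"]


def surface_rhs(model: SproutModel, state: State) -> dict[str, np.ndarray]:
    """Time derivatives of the BM-layer state.

    Concentration species in fluid molar/s, receptor species in
    (mol/1e15 um^2)/s, per BM node (wall nodes then the end cap).
    """
    p = model.params
    k = p.kinetics
    K = p.matrix.K_ECM
    s = state.surface
    f = state.field
    A, Vp = model.bm_area, model.Vp
    exch = model.exch_conductance

    ring = np.empty(model.n_bm)

    def ring_conc(name):
        arr = getattr(f, name)
        ring[: model.n_wall] = arr[model.wall_iz, 1]
        ring[model.cap_index] = arr[model.cap_iz, 0]
        return ring.copy()

    P_tot = s.P + s.P_teth
    H_layer = model.H_tot_layer - s.V165H
    rm = model.receptor_mask
    sR2 = p.sR2 * SURF * rm

    bind_165 = k.kon_R2 * s.V165 * s.R2 - k.koff_R2 * s.V165R2  # mol/1e15um^2/s
    bind_114 = k.kon_R2 * s.V114 * s.R2 - k.koff_R2 * s.V114R2
    hspg_165 = k.kon_H * s.V165 * H_layer - k.koff_H * s.V165H  # M/s

    def exchange(name, c_bm):
        """Radial exchange with the first ECM ring plus axial diffusion along
        the BM sheath (wall chain), as M/s into the BM node."""
        rate = exch * (ring_conc(name) / K - c_bm)
        if model.bm_axial_g.size:
            gax = model.bm_axial_g
            nw = model.n_wall
            rate = rate.copy()
            rate[: nw - 1] += gax * (c_bm[1:nw] - c_bm[: nw - 1])
            rate[1:nw] += gax * (c_bm[: nw - 1] - c_bm[1:nw])
        return rate / Vp

    dV165 = (
        exchange("V165", s.V165)
        - hspg_165
        - k.kP * P_tot * s.V165
        - (A / Vp) * bind_165
    )
    dV114 = (
        exchange("V114", s.V114)
        + k.kP * P_tot * (s.V165 + s.V165H)
        - (A / Vp) * bind_114
    )
    dP = (
        exchange("P", s.P)
        + (A / Vp) * model.secretion_flux
        - k.kdeg * s.P
    )
    dV165H = hspg_165 - k.kP * P_tot * s.V165H
    dR2 = sR2 - k.kint * s.R2 - bind_165 - bind_114
    dV165R2 = bind_165 - k.kint * s.V165R2
    dV114R2 = bind_114 - k.kint * s.V114R2
    return {
        "V165": dV165,
        "V114": dV114,
        "P": dP,
        "V165H": dV165H,
        "R2": dR2,
        "V165R2": dV165R2,
        "V114R2": dV114R2,
    }


def receptor_occupancy(model: SproutModel, state: State) -> dict[str, float]:
    """Tip-averaged receptor pools (mol/1e15 um^2) and the bound fractions."""
    s = state.surface
    m = model.tip_mask & model.receptor_mask
    if not m.any():
        return {"R2": 0.0, "V165R2": 0.0, "V114R2": 0.0, "bound_fraction": 0.0}
    w = model.bm_area[m]

    def avg(x):
        return float(np.sum(x[m] * w) / w.sum())

    r2, v165r2, v114r2 = avg(s.R2), avg(s.V165R2), avg(s.V114R2)
    total = r2 + v165r2 + v114r2
    return {
        "R2": r2,
        "V165R2": v165r2,
        "V114R2": v114r2,
        "bound_fraction": (v165r2 + v114r2) / total if total else 0.0,
    }


def capture_probability(result) -> dict[str, float]:
    """Autocrine capture probability, ``P_cap = 1 - [V]_surface/[V]_farfield``.

    Requires a converged isolated-sprout (case 1) result with a far-field
    Dirichlet clamp.  The surface concentration is the tip-averaged fluid
    concentration in the BM layer.  With VEGFR2 as the only receptor the
    per-receptor-species capture equals the overall capture times the
    fraction of receptor-bound VEGF on VEGFR2, i.e. 1.
    """
    model, state = result.model, result.state
    if model.params.boundary.case != "isolated":
        raise ValueError("capture probability is defined for the isolated case")
    out: dict[str, float] = {}
    far = {"V165": model.params.boundary.V0, "V114": 0.0}
    for name, v0 in far.items():
        if v0 <= 0:
            continue
        surf = model.pericellular(state, name, region="tip")
        out[name] = 1.0 - surf / v0
    if not model.receptor_mask.any():
        out = {k2: 0.0 for k2 in out}
    out["overall"] = out.get("V165", 0.0)
    return out
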