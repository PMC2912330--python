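"""Pointwise reaction laws, closed-form estimators, and proteolysis-rate fitting.

The chemistry, in the interstitial pores:

* ``VEGF165 + HSPG <-> VEGF165.HSPG``  (kon_H / koff_H, Kd ~ 24 nM)
* ``VEGF165 + P -> VEGF114 + P``       (effective one-step cleavage, kP)
* ``VEGF165.HSPG + P -> VEGF114 + P + HSPG``
* protease self-inactivation at kdeg.

Rate constants are free-solution constants, so all bimolecular products are
evaluated with interstitial-fluid concentrations; when states are carried in
the bulk (tissue-averaged) frame the products acquire a 1/K_av factor and the
resulting rates stay in the bulk frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares

from .params import ParameterSet, ValidationError

__all__ = [
    "KP_37C",
    "KP_25C",
    "ReactionRates",
    "CleavageTimeCourse",
    "reaction_terms",
    "hspg_equilibrium",
    "retardation_factor",
    "equilibration_time",
    "conversion_at_clearance",
    "required_protease",
    "kp_from_half_life",
    "simulate_two_step_cleavage",
    "synthetic_cleavage_course",
    "fit_effective_kp",
    "read_time_course_csv",
]

#: effective one-step VEGF165 cleavage rate constants (M^-1 s^-1): the
#: simulator default (37 C, plasmin) and the 25 C preset.
KP_37C = 631.0
KP_25C = 328.0


@dataclass(frozen=True)
class ReactionRates:
    """Net reaction rates (M/s, bulk frame) for the five volumetric species."""

    dV165: float
    dV114: float
    dP: float
    dH: float
    dV165H: float


def reaction_terms(V165, V114, P, H, V165H, params: ParameterSet, K_av: float = 1.0):
    """Volumetric reaction rates at one point (all concentrations bulk molar).

    Accepts scalars or broadcastable arrays.  ``K_av`` is the available
    volume fraction of the compartment; bimolecular products are divided by
    it so that the underlying mass action runs on pore concentrations.
    Protease catalyses cleavage without being consumed, so local VEGF mass
    only moves between the V165, V114 and V165.HSPG pools.
    """
    arrs = [np.asarray(x, dtype=float) for x in (V165, V114, P, H, V165H)]
    for a in arrs:
        if np.any(a < 0):
            raise ValidationError("concentrations must be non-negative")
    V165, V114, P, H, V165H = arrs
    k = params.kinetics
    binding = (k.kon_H * V165 * H) / K_av - k.koff_H * V165H
    cleave_free = k.kP * P * V165 / K_av
    cleave_bound = k.kP * P * V165H / K_av
    return ReactionRates(
        dV165=-binding - cleave_free,
        dV114=cleave_free + cleave_bound,
        dP=-k.kdeg * P,
        dH=-binding + cleave_bound,
        dV165H=binding - cleave_bound,
    )


def hspg_equilibrium(V_free, H_total, Kd):
    """Bound VEGF165 at binding equilibrium: ``V * H_total / (Kd + V)``.

    With 1 pM free VEGF against the basement membrane's 13 uM HSPG
    (Kd = 23.8 nM) this gives the ~540 pM bound pool.
    """
    V_free = np.asarray(V_free, dtype=float)
    if np.any(V_free < 0) or np.any(np.asarray(H_total) < 0):
        raise ValidationError("concentrations must be non-negative")
    if np.any(np.asarray(Kd) <= 0):
        raise ValidationError("Kd must be positive")
    out = V_free * H_total / (Kd + V_free)
    return float(out) if out.ndim == 0 else out


def retardation_factor(H_total: float, Kd: float) -> float:
    """Linear-binding effective-diffusivity divisor ``1 + H_total/Kd``.

    Rapid-equilibrium binding to immobile HSPG slows apparent VEGF165
    transport 32.5-fold at the ECM's 750 nM HSPG.
    """
    if H_total < 0:
        raise ValidationError("H_total must be non-negative")
    if Kd <= 0:
        raise ValidationError("Kd must be positive")
    return 1.0 + H_total / Kd


def equilibration_time(kon_H: float, H_total: float, koff_H: float) -> float:
    """Relaxation time of the VEGF165-HSPG binding reaction,
    ``1/(kon*H_total + koff)``; 3.1 s at ECM conditions."""
    rate = kon_H * H_total + koff_H
    if rate <= 0:
        raise ValidationError("kon*H_total + koff must be positive")
    return 1.0 / rate


def conversion_at_clearance(kP: float, P: float, k_total_clear: float) -> float:
    """Steady tissue-level conversion ``f = kP*P / (kP*P + k_clear)``.

    Competition between first-order cleavage (rate kP*[P] per VEGF molecule)
    and total clearance of VEGF from the tissue.
    """
    if kP < 0 or P < 0:
        raise ValidationError("kP and P must be non-negative")
    if k_total_clear <= 0:
        raise ValidationError("clearance rate must be positive")
    r = kP * P
    return r / (r + k_total_clear)


def required_protease(kP: float, k_total_clear: float, f: float) -> float:
    """Uniform protease level (M) needed for conversion fraction ``f``.

    Inverse of :func:`conversion_at_clearance`: ``(f/(1-f)) * k_clear / kP``.
    At kP = 631 M^-1 s^-1 and a 1 h VEGF half-life, 50% cleavage needs
    ~305 nM protease.
    """
    if not (0.0 <= f < 1.0):
        raise ValidationError(f"target conversion must lie in [0, 1), got {f!r}")
    if kP <= 0 or k_total_clear < 0:
        raise ValidationError("kP must be positive, clearance non-negative")
    return (f / (1.0 - f)) * k_total_clear / kP


def kp_from_half_life(t_half_s: float, P: float) -> float:
    """One-step rate constant implied by an observed cleavage half-life at
    protease concentration ``P``: ``ln 2 / (t_half * P)``."""
    if t_half_s <= 0 or P <= 0:
        raise ValidationError("half-life and protease concentration must be positive")
    return math.log(2.0) / (t_half_s * P)


def simulate_two_step_cleavage(k1: float, k2: float, P: float, times) -> np.ndarray:
    """Fractions (intact dimer, heterodimer intermediate, fully cleaved).

    VEGF165 is a homodimer with two equivalent cleavage sites; the first cut
    (rate 2*k1*P, for the two chains) produces the 165/114 heterodimer, the
    second (k2*P) finishes the conversion:

        d[D]/dt = -2 k1 P [D];  d[I]/dt = 2 k1 P [D] - k2 P [I];
        d[C]/dt = k2 P [I].

    Returns an array of shape (len(times), 3); rows sum to 1.
    """
    if k1 < 0 or k2 < 0 or P < 0:
        raise ValidationError("rates must be non-negative")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    A = np.array(
        [
            [-2.0 * k1 * P, 0.0, 0.0],
            [2.0 * k1 * P, -k2 * P, 0.0],
            [0.0, k2 * P, 0.0],
        ]
    )
    y0 = np.array([1.0, 0.0, 0.0])
    return np.stack([expm(A * t) @ y0 for t in times])


@dataclass(frozen=True)
class CleavageTimeCourse:
    """A measured (or synthetic) cleavage time course.

    ``intact_fraction`` is the fraction of fully-uncleaved dimer remaining at
    each time; the protease concentration is assumed constant (catalytic,
    far below Km).
    """

    times: np.ndarray
    intact_fraction: np.ndarray
    protease_conc: float
    temperature_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.intact_fraction, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intact_fraction", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ValidationError("times and intact_fraction must be 1-D and equal length")
        if self.protease_conc <= 0:
            raise ValidationError("protease concentration must be positive")
        if np.any(f < -0.5) or np.any(f > 1.5):
            raise ValidationError("intact fractions grossly outside [0, 1]")


def synthetic_cleavage_course(
    kp_effective: float,
    P: float,
    times,
    noise_sd: float = 0.0,
    intact_definition: str = "dimer",
    k2_over_k1: float = 1.0,
    rng=None,
    temperature_label: str = "37C",
) -> CleavageTimeCourse:
    """Generate a cleavage time course from the two-step homodimer model.

    ``kp_effective`` sets the first-cut chemistry (k1 = kp_effective/2, so the
    intact dimer decays at exactly ``kp_effective * P``); ``k2_over_k1`` sets
    the second cut.  ``intact_definition`` chooses what the assay counts as
    intact: the fully-uncleaved dimer (``"dimer"``) or anything with at least
    one uncleaved chain (``"dimer+intermediate"``).  Gaussian noise of
    standard deviation ``noise_sd`` emulates densitometry error; real assay
    artefacts (baseline drift, saturation) are not modelled.
    """
    k1 = kp_effective / 2.0
    frac = simulate_two_step_cleavage(k1, k2_over_k1 * k1, P, times)
    if intact_definition == "dimer":
        intact = frac[:, 0]
    elif intact_definition == "dimer+intermediate":
        intact = frac[:, 0] + frac[:, 1]
    else:
        raise ValidationError(f"unknown intact definition {intact_definition!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        intact = np.clip(intact + rng.normal(0.0, noise_sd, intact.shape), 0.0, 1.0)
    return CleavageTimeCourse(np.asarray(times, float), intact, P, temperature_label)


class DegenerateFitWarning(UserWarning):
    pass


def fit_effective_kp(
    course: CleavageTimeCourse,
    n_bootstrap: int = 200,
    seed: int = 1729,
) -> tuple[float, float]:
    """Least-squares estimate of the effective one-step cleavage constant.

    Fits ``intact(t) = exp(-kP * P * t)`` and returns ``(kP, half_width)``
    where the half-width is the 68% case-resampling bootstrap interval
    half-width (0 when bootstrap is disabled with ``n_bootstrap=0``).

    A course that does not decay yields a kP estimate pinned near zero and a
    :class:`DegenerateFitWarning`.
    """
    t, f = course.times, course.intact_fraction
    if t.size < 3:
        raise ValidationError("need at least 3 time points to fit")
    P = course.protease_conc

    def fit_once(ti, fi):
        span = max(float(np.max(ti)), 1.0)
        # crude log-linear start, robust to zeros
        pos = fi > 1e-12
        if pos.sum() >= 2 and np.ptp(ti[pos]) > 0:
            slope = -np.polyfit(ti[pos], np.log(fi[pos]), 1)[0]
            x0 = max(slope / P, 1e-12 / (P * span))
        else:
            x0 = 1.0 / (P * span)
        res = least_squares(
            lambda k: np.exp(-k[0] * P * ti) - fi,
            x0=[x0],
            bounds=([0.0], [np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        return float(res.x[0])

    kp_hat = fit_once(t, f)
    decay = f[0] - f[-1]
    if decay <= 3.0 * (np.std(np.diff(f)) / max(t.size - 1, 1) + 1e-12) and kp_hat * P * t[-1] < 1e-3:
        warnings.warn(
            "time course shows no appreciable decay; kP estimate is degenerate",
            DegenerateFitWarning,
            stacklevel=2,
        )
    half_width = 0.0
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, t.size, t.size)
            if np.unique(t[idx]).size < 2:
                continue
            reps.append(fit_once(t[idx], f[idx]))
        if reps:
            lo, hi = np.percentile(reps, [16.0, 84.0])
            half_width = float((hi - lo) / 2.0)
    return kp_hat, half_width


def read_time_course_csv(path_or_buf) -> CleavageTimeCourse:
    """Read a cleavage time course CSV with columns
    ``time_s, intact_fraction, protease_M`` (protease constant down the file)."""
    df = pd.read_csv(path_or_buf)
    required = {"time_s", "intact_fraction", "protease_M"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"time-course CSV missing columns: {sorted(missing)}")
    P = float(df["protease_M"].iloc[0])
    return CleavageTimeCourse(
        df["time_s"].to_numpy(float), df["intact_fraction"].to_numpy(float), P
    )
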