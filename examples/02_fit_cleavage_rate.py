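"""Estimate the effective one-step cleavage rate constant from a time course.

VEGF165 is a disulfide-linked homodimer: cleavage is really two sequential
cuts through a 165/114 heterodimer intermediate.  This script generates a
synthetic densitometry time course from that two-step model (2% noise) and
fits the effective one-step law intact(t) = exp(-kP [P] t) to it, the same
reduction the simulator uses.
"""

import numpy as np

from sproutsim.kinetics import fit_effective_kp, synthetic_cleavage_course

KP_TRUE = 631.0  # M^-1 s^-1, the 37C simulator default
P = 40e-9  # ~0.01 U/mL plasmin

times = np.linspace(0, 8 * 3600, 10)
course = synthetic_cleavage_course(KP_TRUE, P, times, noise_sd=0.02, rng=11)

print("time (h)  intact fraction")
for t, f in zip(course.times, course.intact_fraction):
    print(f"  {t/3600:5.2f}     {f:.3f}")

kp_hat, half_width = fit_effective_kp(course)
print(f"\nfitted kP = {kp_hat:.0f} +/- {half_width:.0f} M^-1 s^-1 (bootstrap 68%)")
print(f"true value used by the generator: {KP_TRUE:.0f} M^-1 s^-1")
print(
    "\nThe per-molecule cleavage rate at this protease level is "
    f"kP*[P] = {kp_hat*P:.2e} s^-1 - a time constant of "
    f"{1/(kp_hat*P)/3600:.0f} h, which is why nM protease levels barely "
    "touch soluble VEGF."
)
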