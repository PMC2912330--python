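"""Collective proteolysis in a bounded tissue (the many-sprouts case).

The sprout sits in a 100 um-wide corridor of tissue (reflecting radial
boundary), with VEGF secreted across the leading face and cleared behind,
calibrated to a 1 pM mean and a 5%/40 um gradient.  A uniform 10 nM
protease field - the collective secretion of many cells - is then switched
on and the steady state recomputed.

Runs in under a minute on one CPU (20 x 13 finite-volume cells).
"""

from sproutsim.analysis import conversion_metrics
from sproutsim.scenarios import get_preset, run_scenario

res = run_scenario(get_preset("fig5-10nM"))
row = conversion_metrics(res, location="z0")
calib = res.calibration

print("calibrated boundary conditions (from the Dirichlet-stage flux audit):")
print(f"  VEGF secretion flux q = {calib['qV']:.3g} molecules um^-2 s^-1")
print(f"  clearance k_clear     = {calib['kclear']:.3g} um/s "
      f"(overall rate {calib['kclear_over_2L']:.3g} s^-1)")

print("\nsteady state with a uniform 10 nM protease field, at z = 0:")
print(f"  soluble VEGF165: {row.pericellular_V165*1e12:.3g} pM at the tip BM")
print(f"  soluble conversion V114/(V165+V114) = {row.soluble_conversion*100:.1f} %")
print(f"  HSPG-bound VEGF165 depleted by       {row.bound_conversion*100:.1f} %")
print(
    "\nTotal soluble VEGF is unchanged from the protease-free state - "
    "cleavage swaps isoforms without adding soluble ligand - while the "
    "bound pool tracks the shrinking soluble VEGF165."
)
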