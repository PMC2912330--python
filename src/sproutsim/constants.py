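"""Physical constants and unit conversion helpers.

Internal unit system: lengths in micrometres (um), time in seconds,
concentrations in molar (M).  Because 1 M = 1e-15 mol/um^3, a concentration
in molar times a volume in um^3 times ``LITERS_PER_UM3`` gives moles.  Every
concentration is carried in one of two frames:

* ``fluid`` -- intra-pore (interstitial fluid) concentration, what a probe in
  the pore liquid would read;
* ``bulk``  -- tissue-volume-averaged concentration, ``bulk = fluid * K_av``
  where ``K_av`` is the available volume fraction of the porous medium.

Mass-action rate constants are measured in free solution, so bimolecular
products are always evaluated with fluid-frame concentrations.
"""

N_AVOGADRO = 6.02214076e23  # 1/mol
LITERS_PER_UM3 = 1.0e-15
#: converts mol/um^3 to molar
MOLAR_PER_MOL_UM3 = 1.0 / LITERS_PER_UM3
SECONDS_PER_HOUR = 3600.0


def molecules_to_molar(n: float, volume_um3: float) -> float:
    """Concentration in molar of ``n`` molecules dissolved in ``volume_um3``."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return n / (N_AVOGADRO * volume_um3 * LITERS_PER_UM3)


def molar_to_molecules(conc_molar: float, volume_um3: float) -> float:
    return conc_molar * N_AVOGADRO * volume_um3 * LITERS_PER_UM3


def molecules_per_hour_to_mol_flux(rate_per_hour: float, area_um2: float) -> float:
    """Secretion rate in molecules/h spread over ``area_um2`` -> mol um^-2 s^-1."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return rate_per_hour / SECONDS_PER_HOUR / area_um2 / N_AVOGADRO


def mol_flux_to_molecules_per_um2_s(flux_mol_um2_s: float) -> float:
    """mol um^-2 s^-1 -> molecules um^-2 s^-1 (the conventional reporting unit)."""
    return flux_mol_um2_s * N_AVOGADRO
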