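"""Physical constants and thermodynamic conversions.

All energies are in kcal/mol, potentials in volts, temperatures in kelvin.
Reduction potentials are *absolute* (vacuum-referenced) unless explicitly
converted to the standard-hydrogen-electrode scale with
:func:`absolute_to_she`.

Two default temperatures coexist in this package: titration and
protonation-probability work uses 300 K (the continuum-electrostatics
convention), while Eyring/transition-state arithmetic uses 298.15 K (the
quantum-thermochemistry convention). Every function takes an explicit
``temperature`` argument so neither default is load-bearing.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

__all__ = [
    "CONSTANTS",
    "ThermoConstants",
    "potential_from_delta_g",
    "delta_g_from_potential",
    "effective_delta_g",
    "barrier_increase_from_probability",
    "eyring_barrier",
    "eyring_rate",
    "photon_potential_shift",
    "absolute_to_she",
    "kcat_from_specific_activity",
]


@dataclass(frozen=True)
class ThermoConstants:
    """Single source of truth for the physical constants used package-wide."""

    #: Faraday constant, kcal mol^-1 V^-1 (96,485 C/mol expressed in kcal/mol per volt)
    faraday: float = 23.0605
    #: Gas constant, kcal mol^-1 K^-1
    gas_constant: float = 1.98720e-3
    #: k_B/h, s^-1 K^-1 — multiply by T for the Eyring prefactor
    kb_over_h: float = 2.08366e10
    #: hc, eV nm — photon energy is hc/lambda
    hc_ev_nm: float = 1239.84
    #: Solvation free energy of the proton, kcal/mol
    proton_solvation: float = -265.9
    #: Absolute potential of the standard hydrogen electrode, V
    she_absolute: float = 4.43
    #: Default temperature for titration / protonation-probability work, K
    temperature_titration: float = 300.0
    #: Default temperature for kinetics / vibrational thermochemistry, K
    temperature_kinetics: float = 298.15

    def rt(self, temperature: float) -> float:
        """RT in kcal/mol."""
        return self.gas_constant * temperature

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


CONSTANTS = ThermoConstants()

_LN10 = math.log(10.0)


def potential_from_delta_g(delta_g: float, n_electrons: int = 1) -> float:
    """Reduction potential (V) from a reaction free energy via ΔG = −nFΔE.

    ``delta_g`` is the free energy of the reduction (product minus reactant,
    kcal/mol) and ``n_electrons`` the number of electrons transferred.
    """
    if n_electrons < 1:
        raise ValueError(f"n_electrons must be >= 1, got {n_electrons}")
    return -delta_g / (n_electrons * CONSTANTS.faraday)


def delta_g_from_potential(potential: float, n_electrons: int = 1) -> float:
    """Inverse of :func:`potential_from_delta_g` (kcal/mol)."""
    if n_electrons < 1:
        raise ValueError(f"n_electrons must be >= 1, got {n_electrons}")
    return -potential * n_electrons * CONSTANTS.faraday


def effective_delta_g(
    delta_g: float,
    n_protons: int = 0,
    ph: float = 7.0,
    temperature: float = CONSTANTS.temperature_kinetics,
) -> float:
    """pH-effective free energy ΔG_eff = ΔG − RT ln[H+]^n = ΔG + n·RT·ln10·pH.

    Makes reactions consuming different numbers of unmodelled solvent protons
    directly comparable at a common proton activity.
    """
    if not math.isfinite(ph):
        raise ValueError("ph must be finite")
    if n_protons < 0:
        raise ValueError(f"n_protons must be >= 0, got {n_protons}")
    return delta_g + n_protons * CONSTANTS.rt(temperature) * _LN10 * ph


def barrier_increase_from_probability(
    p: float, temperature: float = CONSTANTS.temperature_titration
) -> float:
    """Barrier increase ΔΔG = −RT ln p from a reactant-state probability.

    When the catalytically competent protonation state is found with
    probability ``p`` < 1, the effective activation free energy rises by
    −RT ln p. ``p`` must lie in (0, 1]; p = 0 would be an infinite penalty
    and is rejected rather than returned as ``inf``.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p}")
    return -CONSTANTS.rt(temperature) * math.log(p)


def eyring_barrier(
    rate_constant: float, temperature: float = CONSTANTS.temperature_kinetics
) -> float:
    """Activation free energy (kcal/mol) from a first-order rate constant (s^-1)."""
    if rate_constant <= 0.0:
        raise ValueError(f"rate constant must be positive, got {rate_constant}")
    prefactor = CONSTANTS.kb_over_h * temperature
    return CONSTANTS.rt(temperature) * math.log(prefactor / rate_constant)


def eyring_rate(
    barrier: float, temperature: float = CONSTANTS.temperature_kinetics
) -> float:
    """First-order rate constant (s^-1) from an activation free energy (kcal/mol)."""
    if not math.isfinite(barrier):
        raise ValueError("barrier must be finite")
    prefactor = CONSTANTS.kb_over_h * temperature
    return prefactor * math.exp(-barrier / CONSTANTS.rt(temperature))


def photon_potential_shift(wavelength_nm: float, n_electrons: int = 1) -> float:
    """Increase in reduction potential (V) afforded by absorbing one photon.

    A photon of wavelength λ delivers hc/λ electron-volts; spread over
    ``n_electrons`` transferred electrons this raises the effective
    potential of the excited donor/acceptor pair by (hc/λ)/n volts.
    """
    if wavelength_nm <= 0.0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    if n_electrons < 1:
        raise ValueError(f"n_electrons must be >= 1, got {n_electrons}")
    return CONSTANTS.hc_ev_nm / wavelength_nm / n_electrons


def absolute_to_she(potential: float) -> float:
    """Convert a vacuum-referenced (absolute) potential to the SHE scale."""
    return potential - CONSTANTS.she_absolute


def kcat_from_specific_activity(
    nmol_per_min_per_mg: float, molar_mass_g_mol: float
) -> float:
    """Turnover number k_cat (s^-1) from a specific activity.

    Specific activities are commonly reported as nmol of product per minute
    per mg of enzyme; the conversion to a per-active-site rate needs the
    enzyme's molar mass, which must be supplied explicitly.
    """
    if nmol_per_min_per_mg <= 0 or molar_mass_g_mol <= 0:
        raise ValueError("specific activity and molar mass must be positive")
    mol_per_s_per_g = nmol_per_min_per_mg * 1e-9 / 60.0 / 1e-3
    return mol_per_s_per_g * molar_mass_g_mol
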