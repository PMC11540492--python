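"""Electrode kinetics: Nernst potentials, Butler-Volmer currents, Faradaic fluxes.

The working electrode (WE, anode) oxidizes chloride to hypochlorous acid,

    Cl- + H2O  <->  HOCl + H+ + 2 e-,

and the counter electrode (CE, cathode) hosts the hydrogen evolution reaction,

    2 H+ + 2 e-  <->  H2.

Both are two-electron reactions.  Electrode potentials are held constant
(highly conductive wires) and the solution potential is zero everywhere
(highly conductive saline), so the overpotential is simply the applied
potential minus the local Nernst potential.  Current densities follow the
Butler-Volmer law with an anodic-positive sign convention; the Faradaic
species rate is the reduction-direction rate ``r_e = -i / (2 F)`` so that a
positive anodic current at the WE produces HOCl and H+ and consumes Cl-.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry as chem
from .constants import C_REF, EPS_CONC, EXP_CAP, FARADAY, R_GAS

__all__ = [
    "ElectrodeSpec",
    "ElectrodeState",
    "working_electrode",
    "counter_electrode",
    "nernst_potential",
    "butler_volmer",
    "electrode_state",
]


@dataclass
class ElectrodeSpec:
    """Thermodynamic and kinetic parameters of one electrode reaction.

    ``stoichiometry`` is signed per the *reduction* direction (reduction
    reactants negative, reduction products positive): for the WE reduction
    ``HOCl + H+ + 2e- -> Cl- + H2O`` it maps HOCl -> -1, H+ -> -1,
    Cl- -> +1.  Combined with ``r_e = -i/(2F)`` this yields the oxidation
    products under anodic current.
    """

    role: str                      # "working" | "counter"
    E0: float                      # standard reduction potential, V vs Ag/AgCl
    i0: float                      # exchange current density, A/m^2
    alpha: float                   # transfer coefficient
    phi_applied: float             # applied electrode potential, V vs Ag/AgCl
    stoichiometry: dict = field(default_factory=dict)  # species -> signed int
    n_electrons: int = 2
    c_ref: float = C_REF           # mol/m^3 standard state for Nernst ratios

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.i0 <= 0:
            raise ValueError(f"i0 must be positive, got {self.i0}")
        if self.n_electrons != 2:
            raise ValueError("both electrode reactions transfer 2 electrons")

    @property
    def stoich_vector(self):
        v = np.zeros(chem.N_SPECIES)
        for name, nu in self.stoichiometry.items():
            v[chem.SPECIES_INDEX[name]] = nu
        return v


def working_electrode(phi_applied: float = 1.5, E0: float = 1.297,
                      i0: float = 0.032, alpha: float = 0.95) -> ElectrodeSpec:
    """Chlorine-oxidation anode with the model's default parameters."""
    return ElectrodeSpec(
        role="working", E0=E0, i0=i0, alpha=alpha, phi_applied=phi_applied,
        stoichiometry={"HOCl": -1, "H+": -1, "Cl-": +1},
    )


def counter_electrode(phi_applied: float = -0.6, E0: float = -0.197,
                      i0: float = 0.003, alpha: float = 0.05) -> ElectrodeSpec:
    """Hydrogen-evolution cathode with the model's default parameters."""
    return ElectrodeSpec(
        role="counter", E0=E0, i0=i0, alpha=alpha, phi_applied=phi_applied,
        stoichiometry={"H+": -2, "H2": +1},
    )


@dataclass
class ElectrodeState:
    """Instantaneous electrode response at one or more locations."""

    E: np.ndarray        # Nernst potential, V
    eta: np.ndarray      # overpotential, V
    i: np.ndarray        # current density, A/m^2, anodic positive
    r_e: np.ndarray      # reduction-direction area rate, mol/(m^2 s)
    species_flux: np.ndarray  # (n_species, ...) surface fluxes, mol/(m^2 s)


def _log_ratio(c_row, c_ref):
    return np.log(np.maximum(c_row, EPS_CONC) / c_ref)


def nernst_potential(spec: ElectrodeSpec, c, T):
    """Concentration-corrected redox potential at temperature T.

    WE:  E = E0 - (RT/2F) ln[(cH/cref)^-1 (cHOCl/cref)^-1 (cCl/cref)]
    CE:  E = E0 - (RT/2F) ln[(cH/cref)^-2 (cH2/cref)]

    Concentrations are floored at ``EPS_CONC`` inside the logarithms only.
    """
    c = np.asarray(c, dtype=float)
    rt2f = R_GAS * np.asarray(T, dtype=float) / (2.0 * FARADAY)
    cref = spec.c_ref
    if spec.role == "working":
        ln_q = (
            -_log_ratio(c[chem.I_H], cref)
            - _log_ratio(c[chem.I_HOCL], cref)
            + _log_ratio(c[chem.I_CL], cref)
        )
    elif spec.role == "counter":
        ln_q = -2.0 * _log_ratio(c[chem.I_H], cref) + _log_ratio(c[chem.I_H2], cref)
    else:
        raise ValueError(f"unknown electrode role {spec.role!r}")
    return spec.E0 - rt2f * ln_q


def butler_volmer(spec: ElectrodeSpec, eta, T):
    """Butler-Volmer current density (A/m^2, anodic positive).

    ``i = i0 (exp((1-a) F eta / RT) - exp(-a F eta / RT))``; exponent
    arguments are capped at +/-EXP_CAP to guard against overflow (the cap
    never binds at the model's operating potentials).
    """
    f_rt = FARADAY / (R_GAS * np.asarray(T, dtype=float))
    x = np.asarray(eta, dtype=float) * f_rt
    a = spec.alpha
    anodic = np.exp(np.clip((1.0 - a) * x, -EXP_CAP, EXP_CAP))
    cathodic = np.exp(np.clip(-a * x, -EXP_CAP, EXP_CAP))
    return spec.i0 * (anodic - cathodic)


def electrode_state(spec: ElectrodeSpec, c, T) -> ElectrodeState:
    """Chain Nernst -> overpotential -> current -> Faradaic species fluxes.

    With the solution potential fixed at zero, ``eta = phi_applied - E``.
    The per-species surface flux is ``stoichiometry * r_e`` with
    ``r_e = -i/(2F)`` (Faraday's law, reduction direction).
    """
    c = np.asarray(c, dtype=float)
    E = nernst_potential(spec, c, T)
    eta = spec.phi_applied - E
    i = butler_volmer(spec, eta, T)
    r_e = -i / (spec.n_electrons * FARADAY)
    nu = spec.stoich_vector
    flux = nu.reshape(nu.shape + (1,) * np.ndim(r_e)) * r_e
    return ElectrodeState(E=E, eta=eta, i=i, r_e=r_e, species_flux=flux)
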