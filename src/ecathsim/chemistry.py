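"""Homogeneous solution chemistry of the electrochemically chlorinated saline.

Ten species are tracked: HOCl, ClO-, ClO2-, ClO3-, O2, H+, H2, OH-, Cl-
and Na+.  Two acid-base equilibria (HOCl dissociation and water
autoionization) are treated kinetically with large reversible rate
constants, so the solution relaxes to mass-action equilibrium on a
sub-second timescale while remaining an ODE system.  Four irreversible
reactions degrade HOCl to chloride, chlorite and chlorate:

    HOCl            -> H+ + Cl- + 1/2 O2        r = K0 [HOCl]
    2 HOCl          -> 2 H+ + Cl- + ClO2-       r = K1 [HOCl]^2
    HOCl + ClO2-    -> H+ + Cl- + ClO3-         r = K2 [HOCl][ClO2-]
    HOCl + ClO-     -> H+ + Cl- + ClO2-         r = K3 [HOCl][ClO-]

HCl, HClO2 and HClO3 are strong acids and appear only in dissociated,
ionic form.  Rate constants are stored in their literature units at their
literature reference temperatures and converted to SI once at load time;
an Arrhenius correction moves them to the local cell temperature.

All rate functions accept concentration arrays of shape ``(n_species,)``
or ``(n_species, n_cells)`` (mol/m^3) and broadcast over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MINUTE, R_KCAL

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "CHARGE",
    "CHLORINE_COUNT",
    "D298_DEFAULT",
    "ChemistryParams",
    "ReactionNetwork",
    "arrhenius_adjust",
    "initial_composition",
]

#: Canonical species ordering used by every concentration vector in the package.
SPECIES = ("HOCl", "ClO-", "ClO2-", "ClO3-", "O2", "H+", "H2", "OH-", "Cl-", "Na+")
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

I_HOCL = SPECIES_INDEX["HOCl"]
I_CLO = SPECIES_INDEX["ClO-"]
I_CLO2 = SPECIES_INDEX["ClO2-"]
I_CLO3 = SPECIES_INDEX["ClO3-"]
I_O2 = SPECIES_INDEX["O2"]
I_H = SPECIES_INDEX["H+"]
I_H2 = SPECIES_INDEX["H2"]
I_OH = SPECIES_INDEX["OH-"]
I_CL = SPECIES_INDEX["Cl-"]
I_NA = SPECIES_INDEX["Na+"]

#: Elementary charge per species.
CHARGE = np.array([0, -1, -1, -1, 0, 1, 0, -1, -1, 1], dtype=float)

#: Chlorine atoms per molecule, for conservation audits.
CHLORINE_COUNT = np.array([1, 1, 1, 1, 0, 0, 0, 0, 1, 0], dtype=float)

#: Aqueous diffusion coefficients at 298 K (m^2/s).  O2 is tracked as a
#: degradation product but no coefficient is tabulated with the other
#: species; 2.0e-9 m^2/s, the textbook value for O2 in water at 25 C, is used.
D298_DEFAULT = {
    "HOCl": 1.14e-9,
    "ClO-": 1.0e-9,
    "ClO2-": 1.0e-9,
    "ClO3-": 1.0e-9,
    "O2": 2.0e-9,
    "H+": 9.31e-9,
    "H2": 6.30e-9,
    "OH-": 5.27e-9,
    "Cl-": 1.032e-9,
    "Na+": 1.334e-9,
}


def arrhenius_adjust(k_ref: float, Ea_kcal: float, T_ref: float, T) -> float:
    """Move a rate constant from its reference temperature to ``T``.

    Uses ``k(T) = k_ref * exp(-(Ea/R) * (1/T - 1/T_ref))`` with the
    activation energy in kcal/mol.  Identity when ``T == T_ref``.

    Parameters
    ----------
    k_ref : rate constant at ``T_ref`` (any units; returned in the same).
    Ea_kcal : activation energy, kcal/mol.
    T_ref, T : temperatures in K; must lie in (250, 400).
    """
    T = np.asarray(T, dtype=float)
    if k_ref <= 0:
        raise ValueError(f"rate constant must be positive, got {k_ref}")
    if not (250.0 < T_ref < 400.0) or np.any(T <= 250.0) or np.any(T >= 400.0):
        raise ValueError("temperatures must lie in (250, 400) K")
    out = k_ref * np.exp(-(Ea_kcal / R_KCAL) * (1.0 / T - 1.0 / T_ref))
    return float(out) if out.ndim == 0 else out


@dataclass
class ChemistryParams:
    """Kinetic and equilibrium parameters of the solution chemistry.

    Values default to the model's parameter table; degradation constants are
    given in their literature units (1/min or L/(mol min)) at the cited
    reference temperatures and converted to SI by :class:`ReactionNetwork`.
    """

    ka: float = 1000.0           # 1/s, HOCl dissociation relaxation rate
    ka_star: float = 1000.0      # mol/(m^3 s), water autoionization relaxation
    Ka_HOCl: float = 3.16e-5     # mol/m^3
    Ka_H2O: float = 1e-8         # mol^2/m^6

    K0: float = 4.65e-4          # 1/min at 30 C
    K1: float = 4.5e-1           # L/(mol min) at 30 C
    K2: float = 3e-3             # L/(mol min) at 30 C
    K3: float = 7.5e-6           # L/(mol min) at 60 C
    Ea_K0: float = 19.0          # kcal/mol
    Ea_K1: float = 15.0
    Ea_K2: float = 15.0
    Ea_K3: float = 15.0
    Tref_K0: float = 303.15      # K
    Tref_K1: float = 303.15
    Tref_K2: float = 303.15
    Tref_K3: float = 333.15

    # Tabulated alternative speciation rate constants (m^3/(mol s) at 25 C).
    # Parsed and stored for completeness but not used by the default model.
    k_HOCl: float = 3.4
    k_ClO: float = 44000.0
    Ea_HOCl: float = 7.7         # kcal/mol
    Ea_ClO: float = 11.6

    D298: dict = field(default_factory=lambda: dict(D298_DEFAULT))


# Stoichiometry of the four degradation reactions, one column per reaction
# (K0, K1, K2, K3), rows in SPECIES order.  Chlorine atoms balance in
# every column.
_DEGRADATION_STOICH = np.zeros((N_SPECIES, 4))
_DEGRADATION_STOICH[:, 0][[I_HOCL, I_H, I_CL, I_O2]] = [-1, 1, 1, 0.5]
_DEGRADATION_STOICH[:, 1][[I_HOCL, I_H, I_CL, I_CLO2]] = [-2, 2, 1, 1]
_DEGRADATION_STOICH[:, 2][[I_HOCL, I_CLO2, I_H, I_CL, I_CLO3]] = [-1, -1, 1, 1, 1]
_DEGRADATION_STOICH[:, 3][[I_HOCL, I_CLO, I_H, I_CL, I_CLO2]] = [-1, -1, 1, 1, 1]


class ReactionNetwork:
    """Evaluates homogeneous reaction rates for a :class:`ChemistryParams` set.

    SI conversion of the tabulated constants happens once here:
    1/min -> 1/s and L/(mol min) -> m^3/(mol s).
    """

    #: signed stoichiometry, species x reaction, for the degradation network
    degradation_stoich = _DEGRADATION_STOICH

    def __init__(self, params: ChemistryParams | None = None):
        self.params = params or ChemistryParams()
        p = self.params
        # SI rate constants at their reference temperatures.
        self.K0_si = p.K0 / MINUTE                   # 1/s
        self.K1_si = p.K1 * 1e-3 / MINUTE            # m^3/(mol s)
        self.K2_si = p.K2 * 1e-3 / MINUTE
        self.K3_si = p.K3 * 1e-3 / MINUTE

    def degradation_constants_at(self, T):
        """SI degradation rate constants Arrhenius-adjusted to temperature T."""
        p = self.params
        return (
            arrhenius_adjust(self.K0_si, p.Ea_K0, p.Tref_K0, T),
            arrhenius_adjust(self.K1_si, p.Ea_K1, p.Tref_K1, T),
            arrhenius_adjust(self.K2_si, p.Ea_K2, p.Tref_K2, T),
            arrhenius_adjust(self.K3_si, p.Ea_K3, p.Tref_K3, T),
        )

    def equilibrium_rates(self, c, T=None):
        """Per-species rates (mol/(m^3 s)) from the two kinetic equilibria.

        Zero exactly when both mass-action quotients equal their constants.
        ``T`` is accepted for interface symmetry; the equilibrium parameters
        carry no temperature dependence.
        """
        c = np.asarray(c, dtype=float)
        p = self.params
        r_hocl = p.ka * (c[I_HOCL] - c[I_CLO] * c[I_H] / p.Ka_HOCl)
        r_h2o = p.ka_star * (1.0 - c[I_OH] * c[I_H] / p.Ka_H2O)
        out = np.zeros_like(c)
        out[I_HOCL] = -r_hocl
        out[I_CLO] = r_hocl
        out[I_H] = r_hocl + r_h2o
        out[I_OH] = r_h2o
        return out

    def degradation_rates(self, c, T):
        """Net per-species rates (mol/(m^3 s)) of the degradation network at T."""
        c = np.asarray(c, dtype=float)
        cp = np.maximum(c, 0.0)  # rate laws see nonnegative concentrations
        K0, K1, K2, K3 = self.degradation_constants_at(T)
        r = np.stack(
            [
                K0 * cp[I_HOCL],
                K1 * cp[I_HOCL] ** 2,
                K2 * cp[I_HOCL] * cp[I_CLO2],
                K3 * cp[I_HOCL] * cp[I_CLO],
            ]
        )
        return np.tensordot(self.degradation_stoich, r, axes=(1, 0))

    def net_rates(self, c, T):
        """Total homogeneous chemistry: equilibria plus degradation."""
        return self.equilibrium_rates(c, T) + self.degradation_rates(c, T)


def initial_composition(pH0: float, C_NaCl: float, params: ChemistryParams | None = None):
    """Initial concentration vector from initial pH and NaCl loading.

    Solves the mole balances, water mass-action law and charge balance for
    the four background ions, with the acidity supplied as fully
    dissociated HCl:

    * ``c_H+  = 1000 * 10**(-pH0)`` (pH defined on mol/L),
    * ``c_OH- = Ka_H2O / c_H+``,
    * ``c_Na+ = C_NaCl``,
    * ``c_Cl- = c_Na+ + c_H+ - c_OH-``  (electroneutrality).

    All chlorine oxyspecies, O2 and H2 start at zero.
    """
    if not (0.0 < pH0 < 14.0):
        raise ValueError(f"pH0 must lie in (0, 14), got {pH0}")
    if C_NaCl <= 0:
        raise ValueError(f"C_NaCl must be positive, got {C_NaCl}")
    p = params or ChemistryParams()
    c = np.zeros(N_SPECIES)
    c[I_H] = 1000.0 * 10.0 ** (-pH0)
    c[I_OH] = p.Ka_H2O / c[I_H]
    c[I_NA] = C_NaCl
    c[I_CL] = c[I_NA] + c[I_H] - c[I_OH]
    return c
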