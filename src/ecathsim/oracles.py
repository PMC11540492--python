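"""Independent verification machinery for the test suite.

Contains a closed-form semi-infinite diffusion solution, a deliberately
naive fixed-step explicit integrator for the well-mixed (0D) chemistry,
and conservation audits on simulation results.  Nothing here shares code
with the main solver, so agreement between the two is evidence rather
than tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from . import chemistry as chem
from .chemistry import ReactionNetwork
from .constants import FARADAY

__all__ = [
    "erfc_diffusion_reference",
    "batch_chemistry_oracle",
    "conservation_audit",
    "AuditReport",
]


def erfc_diffusion_reference(D: float, c_left: float, x, t: float):
    """Semi-infinite diffusion from a fixed boundary concentration.

    ``c(x, t) = c_left * erfc(x / (2 sqrt(D t)))`` — the reference solution
    for pure diffusion into an initially empty half-space, valid for the
    finite grid until the far boundary is felt.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    x = np.asarray(x, dtype=float)
    return c_left * erfc(x / (2.0 * np.sqrt(D * t)))


def batch_chemistry_oracle(
    c0,
    T: float,
    t_end: float,
    network: ReactionNetwork | None = None,
    include_equilibria: bool = True,
    include_degradation: bool = True,
    rel_tol: float = 1e-8,
    n_steps0: int = 256,
    max_doublings: int = 16,
):
    """Well-mixed chemistry endpoint by brute-force explicit integration.

    Classical fixed-step RK4, with the step count doubled until two
    successive refinements agree to ``rel_tol`` relative (on an absolute
    scale of 1e-12 mol/m^3).  Independent of the implicit main solver.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    network = network or ReactionNetwork()
    c0 = np.asarray(c0, dtype=float)

    def f(c):
        dc = np.zeros_like(c)
        if include_equilibria:
            dc += network.equilibrium_rates(c, T)
        if include_degradation:
            dc += network.degradation_rates(c, T)
        return dc

    def run(n):
        h = t_end / n
        c = c0.copy()
        with np.errstate(all="ignore"):  # unstable trial steps are detected, not raised
            for _ in range(n):
                k1 = f(c)
                k2 = f(c + 0.5 * h * k1)
                k3 = f(c + 0.5 * h * k2)
                k4 = f(c + h * k3)
                c = c + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                if not np.all(np.isfinite(c)):
                    return None
        return c

    prev = run(n_steps0)
    n = n_steps0
    for _ in range(max_doublings):
        n *= 2
        cur = run(n)
        if cur is not None and prev is not None:
            scale = np.maximum(np.abs(cur), 1e-12)
            if np.max(np.abs(cur - prev) / scale) < rel_tol:
                return cur
        prev = cur
    raise RuntimeError(
        f"oracle did not converge to {rel_tol} relative within {n} steps"
    )


@dataclass
class AuditReport:
    """Conservation residuals for a finished run."""

    chlorine_drift: float        # max relative drift of total Cl atoms
    sodium_drift: float          # max relative drift of total Na+
    charge_residual: float       # relative mismatch of charge vs integrated current
    flagged: bool
    tolerance: float

    def as_dict(self) -> dict:
        return {
            "chlorine_drift": self.chlorine_drift,
            "sodium_drift": self.sodium_drift,
            "charge_residual": self.charge_residual,
            "flagged": self.flagged,
            "tolerance": self.tolerance,
        }

    def __str__(self) -> str:
        lines = [
            "conservation audit",
            f"  chlorine drift (rel): {self.chlorine_drift:.3e}",
            f"  sodium drift (rel):   {self.sodium_drift:.3e}",
            f"  charge residual (rel): {self.charge_residual:.3e}",
            f"  flagged: {self.flagged} (tolerance {self.tolerance:.1e})",
        ]
        return "\n".join(lines)


def conservation_audit(result, tolerance: float = 1e-4,
                       charge_tolerance: float = 1e-6) -> AuditReport:
    """Check chlorine/sodium conservation and the charge-current ledger.

    Total chlorine atoms and total sodium must stay constant over the run
    (electrode reactions only interconvert chlorine species).  The charge
    ledger is an exact instantaneous identity — homogeneous chemistry and
    diffusion are charge-neutral, so ``d/dt sum_i z_i c_i V`` must equal
    ``(I_we + I_ce)/F`` — and is verified at every snapshot by
    re-evaluating the model right-hand side on the stored field.
    """
    if result.times.size < 2:
        raise ValueError("audit needs at least two snapshots")
    cl_total = result.total_moles(chem.CHLORINE_COUNT)
    na_total = result.total_moles()[:, chem.I_NA]
    chlorine_drift = float(np.max(np.abs(cl_total - cl_total[0])) / cl_total[0])
    sodium_drift = float(np.max(np.abs(na_total - na_total[0])) / na_total[0])

    charge_residual = _charge_ledger_residual(result)

    flagged = (
        chlorine_drift > tolerance
        or sodium_drift > tolerance
        or charge_residual > charge_tolerance
    )
    return AuditReport(
        chlorine_drift=chlorine_drift,
        sodium_drift=sodium_drift,
        charge_residual=charge_residual,
        flagged=flagged,
        tolerance=tolerance,
    )


def _charge_ledger_residual(result) -> float:
    """Max relative mismatch of d(total charge)/dt against (sum I)/F."""
    from .solver import _active_electrodes, _phase_at, assemble_rhs

    if result.network is None or result.schedule is None:
        return 0.0
    residual = 0.0
    for ti, t in enumerate(result.times):
        phase = _phase_at(result.schedule, float(t))
        active = _active_electrodes(result.electrodes, phase)
        dcdt = assemble_rhs(result.fields[ti], result.grid, result.network, active)
        dq_dt = float(chem.CHARGE @ (dcdt * result.grid.volume).sum(axis=1))
        i_total = sum(float(series[ti]) for series in result.currents.values())
        scale = max(abs(i_total / FARADAY), 1e-12)
        residual = max(residual, abs(dq_dt - i_total / FARADAY) / scale)
    return residual
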