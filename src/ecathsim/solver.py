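"""Method-of-lines reaction-diffusion solver over the catheter grid.

Each species obeys a diffusion balance with net homogeneous reaction rates
and, on wire-bearing cells during polarized phases, Faradaic source terms:

    d c_i / dt = (1/V_k) sum_faces A_f D_f (c_neighbor - c_k)/dx
                 + R_i(c, T_k)
                 + sum_electrodes nu_i r_e(c_k) a_k / V_k

Both domain ends are no-flux.  The kinetically treated acid-base
equilibria make the system stiff (relaxation rates ~1e5 1/s against run
times of days), so integration uses an implicit variable-order BDF scheme
with a sparse Jacobian pattern: a dense species block per cell plus
per-species diffusive coupling to neighbor cells.  Polarization phase
boundaries are hard integrator restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import coo_matrix

from . import chemistry as chem
from .chemistry import ReactionNetwork
from .constants import EPS_CONC, HOUR
from .electrodes import ElectrodeSpec, electrode_state
from .geometry import CatheterGrid, surface_to_volume

__all__ = [
    "Phase",
    "Schedule",
    "SimulationResult",
    "assemble_rhs",
    "integrate",
    "ph_field",
    "volume_average",
]


@dataclass
class Phase:
    """One polarization interval: potentials in V vs Ag/AgCl, or None for off."""

    t_start: float
    t_end: float
    we_potential: float | None = None
    ce_potential: float | None = None

    @property
    def polarized(self) -> bool:
        return self.we_potential is not None or self.ce_potential is not None


@dataclass
class Schedule:
    """Contiguous, non-overlapping polarization phases starting at t = 0."""

    phases: list

    def __post_init__(self):
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        if abs(self.phases[0].t_start) > 0:
            raise ValueError("schedule must start at t = 0")
        for a, b in zip(self.phases, self.phases[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise ValueError("phases must be contiguous and non-overlapping")
            if a.t_end <= a.t_start:
                raise ValueError("phases must have positive duration")

    @property
    def t_end(self) -> float:
        return self.phases[-1].t_end


def ph_field(c) -> np.ndarray:
    """Per-cell pH, ``-log10(c_H+ / 1000)`` with c_H+ in mol/m^3."""
    c = np.asarray(c, dtype=float)
    ch = np.maximum(c[chem.I_H], EPS_CONC)
    return -np.log10(ch / 1000.0)


def _active_electrodes(electrodes, phase: Phase):
    """Electrode specs with phase potentials applied; empty when off."""
    if phase is None or not phase.polarized:
        return []
    active = []
    for spec in electrodes:
        phi = phase.we_potential if spec.role == "working" else phase.ce_potential
        if phi is None:
            continue
        active.append(
            ElectrodeSpec(
                role=spec.role, E0=spec.E0, i0=spec.i0, alpha=spec.alpha,
                phi_applied=phi, stoichiometry=dict(spec.stoichiometry),
                c_ref=spec.c_ref,
            )
        )
    return active


def assemble_rhs(
    c: np.ndarray,
    grid: CatheterGrid,
    network: ReactionNetwork,
    electrodes=(),
) -> np.ndarray:
    """Time derivative of the concentration field (n_species, n_cells).

    ``electrodes`` holds the *active* electrode specs for the current
    phase; pass an empty sequence for open circuit.  Raises on NaN input
    with the offending species/cell named.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (chem.N_SPECIES, grid.n_cells):
        raise ValueError(
            f"state shape {c.shape} != ({chem.N_SPECIES}, {grid.n_cells})"
        )
    if not np.all(np.isfinite(c)):
        i, k = np.argwhere(~np.isfinite(c))[0]
        raise FloatingPointError(
            f"non-finite concentration: species {chem.SPECIES[i]}, cell {k}"
        )

    D = grid.diffusivity  # (ns, nk)
    # Two-point flux with each half-cell contributing its own diffusive
    # resistance (dx/2)/(A D); exact for piecewise-linear steady profiles
    # across segment junctions, where the area jumps.  Within a uniform
    # segment this reduces to the standard A D dc/dx face flux.
    r_left = (0.5 * grid.dx[:-1] / grid.area[:-1]) / D[:, :-1]
    r_right = (0.5 * grid.dx[1:] / grid.area[1:]) / D[:, 1:]
    flux = (c[:, 1:] - c[:, :-1]) / (r_left + r_right)  # mol/s into cell k from k+1
    dcdt = np.zeros_like(c)
    dcdt[:, :-1] += flux / grid.volume[:-1]
    dcdt[:, 1:] -= flux / grid.volume[1:]

    dcdt += network.net_rates(c, grid.temperature)

    for spec in electrodes:
        a_over_v = surface_to_volume(grid, spec.role)
        mask = a_over_v > 0
        if not mask.any():
            continue
        state = electrode_state(spec, c[:, mask], grid.temperature[mask])
        dcdt[:, mask] += state.species_flux * a_over_v[mask]
    return dcdt


def _jacobian_sparsity(grid: CatheterGrid):
    """Sparsity pattern of the RHS Jacobian in raveled (species, cell) order.

    Dense species-species block within each cell (chemistry + electrode
    coupling) plus same-species coupling to adjacent cells (diffusion).
    """
    ns, nk = chem.N_SPECIES, grid.n_cells
    rows, cols = [], []
    k = np.arange(nk)
    for i in range(ns):
        for j in range(ns):
            rows.append(i * nk + k)
            cols.append(j * nk + k)
        rows.append(i * nk + k[:-1])
        cols.append(i * nk + k[1:])
        rows.append(i * nk + k[1:])
        cols.append(i * nk + k[:-1])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones_like(rows, dtype=np.int8)
    return coo_matrix((data, (rows, cols)), shape=(ns * nk, ns * nk)).tocsr()


@dataclass
class SimulationResult:
    """Concentration snapshots plus derived reports for one run."""

    grid: CatheterGrid
    times: np.ndarray                  # snapshot times, s
    fields: np.ndarray                 # (n_times, n_species, n_cells), mol/m^3
    currents: dict = field(default_factory=dict)  # role -> (n_times,), A
    solver_stats: list = field(default_factory=list)
    network: ReactionNetwork | None = None
    electrodes: tuple = ()
    schedule: Schedule | None = None

    def snapshot_index(self, t: float) -> int:
        idx = np.nonzero(np.isclose(self.times, t, rtol=1e-9, atol=1e-6))[0]
        if idx.size == 0:
            raise KeyError(f"t = {t} s is not among the stored snapshots")
        return int(idx[0])

    def ph(self, t: float) -> np.ndarray:
        return ph_field(self.fields[self.snapshot_index(t)])

    def volume_average(self, compartment: str, species: str, t: float | None = None):
        """Volume-weighted mean concentration over a compartment.

        With ``t=None`` returns the full time series.
        """
        mask = self.grid.cells_in(compartment)
        i = chem.SPECIES_INDEX[species]
        w = self.grid.volume[mask]
        series = self.fields[:, i, :][:, mask] @ w / w.sum()
        if t is None:
            return series
        return float(series[self.snapshot_index(t)])

    def extremum(self, species: str, t: float, compartment: str = "all",
                 kind: str = "max") -> float:
        mask = self.grid.cells_in(compartment)
        i = chem.SPECIES_INDEX[species]
        values = self.fields[self.snapshot_index(t), i, mask]
        return float(values.max() if kind == "max" else values.min())

    def total_moles(self, weights=None) -> np.ndarray:
        """Volume-integrated, per-snapshot total of ``weights . c`` (mol).

        ``weights=None`` totals each species separately, returning
        (n_times, n_species); a weight vector (e.g. chlorine counts or
        charges) returns (n_times,).
        """
        per_species = np.einsum("tik,k->ti", self.fields, self.grid.volume)
        if weights is None:
            return per_species
        return per_species @ np.asarray(weights, dtype=float)

    def profiles_frame(self) -> pd.DataFrame:
        """Long-format per-cell profiles: one row per (time, cell)."""
        records = []
        for ti, t in enumerate(self.times):
            frame = pd.DataFrame(
                {name: self.fields[ti, i] for i, name in enumerate(chem.SPECIES)}
            )
            frame.insert(0, "time_s", t)
            frame.insert(1, "x_m", self.grid.x)
            frame.insert(2, "compartment", self.grid.labels)
            frame["pH"] = ph_field(self.fields[ti])
            records.append(frame)
        return pd.concat(records, ignore_index=True)

    def volume_average_frame(self) -> pd.DataFrame:
        """Tidy volume averages: (time_s, compartment, species, volume_avg_mol_m3)."""
        rows = []
        for comp in self.grid.compartments + ["all"]:
            for name in chem.SPECIES:
                series = self.volume_average(comp, name)
                for t, v in zip(self.times, series):
                    rows.append((float(t), comp, name, float(v)))
        return pd.DataFrame(
            rows, columns=["time_s", "compartment", "species", "volume_avg_mol_m3"]
        )


def integrate(
    c0: np.ndarray,
    grid: CatheterGrid,
    network: ReactionNetwork,
    electrodes=(),
    schedule: Schedule | None = None,
    snapshots=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "BDF",
) -> SimulationResult:
    """Integrate the model through a polarization schedule.

    Parameters
    ----------
    c0 : initial concentration field, (n_species, n_cells) or (n_species,)
        (a vector is broadcast to a uniform field).
    electrodes : electrode specs; per-phase potentials come from ``schedule``.
    schedule : polarization schedule; default is one open-circuit phase
        covering the snapshot span.
    snapshots : output times in seconds (default: hourly to schedule end).

    Returns a :class:`SimulationResult` with electrode total currents
    recomputed at every snapshot.  Raises ``RuntimeError`` naming the
    failing phase if the integrator does not converge.
    """
    c0 = np.asarray(c0, dtype=float)
    if c0.ndim == 1:
        c0 = np.repeat(c0[:, None], grid.n_cells, axis=1)
    if snapshots is None:
        t_end = schedule.t_end if schedule else 48 * HOUR
        snapshots = np.arange(0.0, t_end + 0.5 * HOUR, HOUR)
    snapshots = np.asarray(sorted(snapshots), dtype=float)
    if schedule is None:
        schedule = Schedule([Phase(0.0, float(snapshots[-1]) or 1.0)])
    if snapshots[-1] > schedule.t_end * (1 + 1e-12):
        raise ValueError("snapshots extend past the end of the schedule")

    sparsity = _jacobian_sparsity(grid)
    ns, nk = chem.N_SPECIES, grid.n_cells
    fields = np.empty((snapshots.size, ns, nk))
    stats = []

    # negatives beyond this mark a genuinely broken run, not solver noise
    neg_floor = -10.0 * atol

    state = c0.copy()
    if np.isclose(snapshots[0], 0.0):
        fields[0] = state
        out_idx = 1
    else:
        out_idx = 0

    t_stop = float(snapshots[-1])  # no need to integrate past the last output
    for phase in schedule.phases:
        if phase.t_start >= t_stop:
            break
        phase_end = min(phase.t_end, t_stop)
        active = _active_electrodes(electrodes, phase)

        def rhs(t, y):
            return assemble_rhs(y.reshape(ns, nk), grid, network, active).ravel()

        t_eval = snapshots[(snapshots > phase.t_start + 1e-9) & (snapshots <= phase_end + 1e-9)]
        sol = solve_ivp(
            rhs,
            (phase.t_start, phase_end),
            state.ravel(),
            method=method,
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
            jac_sparsity=sparsity,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed in phase [{phase.t_start}, {phase.t_end}] s "
                f"(rtol={rtol}, atol={atol}): {sol.message}"
            )
        if t_eval.size:
            fields[out_idx : out_idx + t_eval.size] = sol.y.T.reshape(-1, ns, nk)
            out_idx += t_eval.size
        state = sol.y[:, -1].reshape(ns, nk) if sol.y.size else state
        if state.min() < neg_floor:
            i, k = np.unravel_index(np.argmin(state), state.shape)
            raise RuntimeError(
                f"persistent negative concentration {state[i, k]:.3e} mol/m^3 "
                f"for {chem.SPECIES[i]} in cell {k}"
            )
        stats.append(
            {
                "t_start": phase.t_start,
                "t_end": phase.t_end,
                "polarized": phase.polarized,
                "n_steps": int(sol.t.size),
                "nfev": int(sol.nfev),
                "njev": int(sol.njev),
            }
        )

    currents = _snapshot_currents(fields, snapshots, grid, electrodes, schedule)
    return SimulationResult(
        grid=grid, times=snapshots, fields=fields, currents=currents,
        solver_stats=stats, network=network, electrodes=tuple(electrodes),
        schedule=schedule,
    )


def _snapshot_currents(fields, times, grid, electrodes, schedule):
    """Total electrode currents (A) recomputed from each stored snapshot."""
    roles = [spec.role for spec in electrodes]
    out = {role: np.zeros(times.size) for role in roles}
    for ti, t in enumerate(times):
        phase = _phase_at(schedule, t)
        for spec in _active_electrodes(electrodes, phase):
            a = grid.wire_area[spec.role]
            mask = a > 0
            state = electrode_state(spec, fields[ti][:, mask], grid.temperature[mask])
            out[spec.role][ti] = float(np.sum(state.i * a[mask]))
    return out


def _phase_at(schedule: Schedule, t: float) -> Phase | None:
    for phase in schedule.phases:
        # a snapshot exactly on a boundary belongs to the phase that produced it
        if phase.t_start < t <= phase.t_end or (t == 0.0 and phase.t_start == 0.0):
            return phase
    return None


def volume_average(result: SimulationResult, compartment: str, species: str,
                   t: float | None = None):
    """Functional alias for :meth:`SimulationResult.volume_average`."""
    return result.volume_average(compartment, species, t)
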