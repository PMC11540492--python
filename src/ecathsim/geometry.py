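"""Reduced-dimension catheter geometry and finite-volume grid.

The catheter is a stack of four cylindrical segments — hub, Luer-lock top,
Luer-lock bottom, and tube — each with its own inner diameter, temperature
and (optionally) electrode wire diameters.  The dominant concentration
gradient runs along the catheter axis, so the lumen is discretized as a 1D
chain of finite-volume cells with variable fluid cross-section (lumen area
minus wire area).  Electrode wires enter the balance through their lateral
surface area per cell, which converts electrode surface fluxes into
volumetric sources.

Axial coordinate x runs from 0 at the top of the hub to 0.3512 m at the
bottom of the tube.  Temperatures are segment-wise constant (25 C in hub
and connectors, 37 C in the implanted tube); diffusivities scale with
temperature as ``D = D298 (T / 298 K)^(3/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry as chem
from .constants import T_HUB_DEFAULT, T_REF_DIFFUSION, T_TUBE_DEFAULT

__all__ = [
    "Segment",
    "CatheterGrid",
    "default_segments",
    "build_grid",
    "diffusivity_at",
    "surface_to_volume",
    "well_mixed_grid",
    "DEFAULT_CELLS",
    "TOTAL_LENGTH",
]

#: Default cells per segment (hub, luer_top, luer_bottom, tube).
DEFAULT_CELLS = {"hub": 30, "luer_top": 5, "luer_bottom": 10, "tube": 200}

#: Total catheter length with the default segment stack (m).
TOTAL_LENGTH = 0.3512


@dataclass
class Segment:
    """One cylindrical section of the catheter lumen."""

    name: str
    length: float          # m
    diameter: float        # inner diameter, m
    temperature: float     # K
    d_we: float = 0.0      # working-electrode wire diameter here, m (0 = absent)
    d_ce: float = 0.0      # counter-electrode wire diameter here, m

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be positive")
        if self.diameter <= 0:
            raise ValueError(f"segment {self.name!r}: diameter must be positive")
        if self.d_we < 0 or self.d_ce < 0:
            raise ValueError(f"segment {self.name!r}: wire diameters must be >= 0")
        if self.d_we >= self.diameter or self.d_ce >= self.diameter:
            raise ValueError(
                f"segment {self.name!r}: wire diameter must be smaller than the lumen"
            )
        if self.fluid_area <= 0:
            raise ValueError(f"segment {self.name!r}: wires fill the lumen")

    @property
    def lumen_area(self) -> float:
        return np.pi / 4.0 * self.diameter**2

    @property
    def fluid_area(self) -> float:
        """Cross-section open to fluid: lumen minus both wire cross-sections."""
        return self.lumen_area - np.pi / 4.0 * (self.d_we**2 + self.d_ce**2)


def default_segments(
    d_we_hub: float = 2.45e-4,
    d_ce_hub: float = 2.45e-4,
    d_we_luer: float = 0.0,
    d_we_tube: float = 0.0,
) -> list[Segment]:
    """The catheter's standard four-segment stack.

    Electrode layout is controlled by the wire diameters: the CE always
    sits in the hub; the WE sits in the hub and optionally continues
    through the connectors and tube.
    """
    return [
        Segment("hub", 3.26e-2, 5.4e-3, T_HUB_DEFAULT, d_we=d_we_hub, d_ce=d_ce_hub),
        Segment("luer_top", 6.4e-3, 4.0e-3, T_HUB_DEFAULT, d_we=d_we_luer),
        Segment("luer_bottom", 1.22e-2, 1.6e-3, T_HUB_DEFAULT, d_we=d_we_luer),
        Segment("tube", 0.3, 1.6e-3, T_TUBE_DEFAULT, d_we=d_we_tube),
    ]


def diffusivity_at(D298, T):
    """Temperature-scaled diffusivity ``D = D298 (T/298)^(3/2)``."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    out = np.asarray(D298, dtype=float) * (T / T_REF_DIFFUSION) ** 1.5
    return float(out) if out.ndim == 0 else out


@dataclass
class CatheterGrid:
    """Discretized axial geometry with per-cell metrics.

    Faces between cells carry the smaller of the two adjoining fluid
    cross-sections (no flaring at segment junctions).  ``wire_area`` maps
    electrode role ("working"/"counter") to the wire lateral area per cell.
    """

    segments: list
    x: np.ndarray              # cell centers, m
    dx: np.ndarray             # cell widths, m
    volume: np.ndarray         # fluid volume per cell, m^3
    area: np.ndarray           # fluid cross-section per cell, m^2
    face_area: np.ndarray      # (n_cells - 1,) interior face areas, m^2
    face_dx: np.ndarray        # (n_cells - 1,) center-to-center spacing, m
    temperature: np.ndarray    # per-cell, K
    labels: np.ndarray         # per-cell segment name
    wire_area: dict = field(default_factory=dict)  # role -> (n_cells,) m^2
    diffusivity: np.ndarray | None = None  # (n_species, n_cells), m^2/s

    @property
    def n_cells(self) -> int:
        return self.x.size

    @property
    def length(self) -> float:
        return float(self.dx.sum())

    @property
    def compartments(self) -> list[str]:
        seen = []
        for name in self.labels:
            if name not in seen:
                seen.append(name)
        return seen

    def cells_in(self, compartment: str) -> np.ndarray:
        """Boolean mask of cells belonging to a compartment label."""
        if compartment == "all":
            return np.ones(self.n_cells, dtype=bool)
        mask = self.labels == compartment
        if not mask.any():
            raise KeyError(f"unknown compartment {compartment!r}")
        return mask


def build_grid(
    segments: list[Segment] | None = None,
    cells_per_segment: dict | None = None,
    D298: dict | None = None,
) -> CatheterGrid:
    """Build the finite-volume grid for a segment stack.

    Each segment is divided into equal-width cells (>= 2 per segment).
    Wire lateral area in a cell is ``pi * d_wire * dx``; face areas take
    the minimum of the adjoining fluid cross-sections.
    """
    segments = segments if segments is not None else default_segments()
    counts = dict(DEFAULT_CELLS)
    if cells_per_segment:
        counts.update(cells_per_segment)
    D298 = D298 or chem.D298_DEFAULT

    xs, dxs, areas, temps, labels = [], [], [], [], []
    a_we, a_ce = [], []
    x0 = 0.0
    for seg in segments:
        n = int(counts.get(seg.name, 10))
        if n < 2:
            raise ValueError(f"segment {seg.name!r}: need >= 2 cells, got {n}")
        dx = seg.length / n
        centers = x0 + dx * (np.arange(n) + 0.5)
        xs.append(centers)
        dxs.append(np.full(n, dx))
        areas.append(np.full(n, seg.fluid_area))
        temps.append(np.full(n, seg.temperature))
        labels.extend([seg.name] * n)
        a_we.append(np.full(n, np.pi * seg.d_we * dx))
        a_ce.append(np.full(n, np.pi * seg.d_ce * dx))
        x0 += seg.length

    x = np.concatenate(xs)
    dx = np.concatenate(dxs)
    area = np.concatenate(areas)
    temperature = np.concatenate(temps)
    volume = area * dx
    face_area = np.minimum(area[:-1], area[1:])
    face_dx = np.diff(x)

    D298_vec = np.array([D298[name] for name in chem.SPECIES])
    diffusivity = diffusivity_at(D298_vec[:, None], temperature[None, :])

    return CatheterGrid(
        segments=list(segments),
        x=x,
        dx=dx,
        volume=volume,
        area=area,
        face_area=face_area,
        face_dx=face_dx,
        temperature=temperature,
        labels=np.array(labels),
        wire_area={"working": np.concatenate(a_we), "counter": np.concatenate(a_ce)},
        diffusivity=diffusivity,
    )


def well_mixed_grid(
    volume: float = 1e-6,
    temperature: float = T_HUB_DEFAULT,
    wire_area: float = 0.0,
    D298: dict | None = None,
) -> CatheterGrid:
    """Single-cell grid for well-mixed (0D) batch runs.

    Diffusion vanishes identically; only chemistry and, if ``wire_area``
    is given, electrode sources act.  Both electrode roles share the wire
    area (use one electrode at a time, or accept co-located wires).
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    D298 = D298 or chem.D298_DEFAULT
    D298_vec = np.array([D298[name] for name in chem.SPECIES])
    temp = np.array([float(temperature)])
    a = np.array([wire_area])
    return CatheterGrid(
        segments=[],
        x=np.array([0.5]),
        dx=np.array([1.0]),
        volume=np.array([volume]),
        area=np.array([volume]),  # nominal unit length
        face_area=np.zeros(0),
        face_dx=np.zeros(0),
        temperature=temp,
        labels=np.array(["batch"]),
        wire_area={"working": a.copy(), "counter": a.copy()},
        diffusivity=diffusivity_at(D298_vec[:, None], temp[None, :]),
    )


def surface_to_volume(grid: CatheterGrid, role: str) -> np.ndarray:
    """Wire lateral area per fluid volume (1/m) per cell for one electrode.

    Converts electrode surface fluxes (mol/(m^2 s)) into volumetric sources
    (mol/(m^3 s)); zero on cells the wire does not reach.
    """
    if role not in grid.wire_area:
        raise KeyError(f"unknown electrode role {role!r}")
    return grid.wire_area[role] / grid.volume
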