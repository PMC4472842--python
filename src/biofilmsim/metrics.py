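"""Morphology metrics: coverage-vs-depth, biomass, depth, convex-hull density.

These are the simulation-side analogues of COMSTAT-style biofilm statistics:
coverage is the fraction of a horizontal plane occupied by biomass, biomass
(in the COMSTAT sense) is biovolume per substratum area i.e. mean thickness,
and convex-hull density (occupied fraction of the biofilm's convex hull) is
an inverse proxy for porosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .lattice import BiofilmState

__all__ = [
    "CoverageProfile",
    "coverage_by_depth",
    "total_biomass",
    "mean_thickness",
    "mean_cell_depth",
    "convex_hull_density",
    "nutrient_scarcity",
    "inverse_nutrient_scarcity",
]


@dataclass
class CoverageProfile:
    """Fraction of each horizontal plane occupied by biomass, coverslip first.

    ``dz`` is the physical spacing between consecutive planes in um.
    """

    values: np.ndarray
    dz: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("coverage values must lie in [0, 1]")

    @property
    def depths(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dz

    def sample(self, depths_um) -> np.ndarray:
        """Linearly interpolate coverage at arbitrary depths (um)."""
        return np.interp(depths_um, self.depths, self.values)


def coverage_by_depth(state: BiofilmState) -> CoverageProfile:
    return CoverageProfile(state.occ.mean(axis=1), dz=1.0)


def total_biomass(state: BiofilmState) -> int:
    return state.biomass


def mean_thickness(state: BiofilmState) -> float:
    """Biomass cell count per unit grid width: mean biofilm thickness in um."""
    return state.biomass / state.config.width


def mean_cell_depth(state: BiofilmState) -> float:
    """Mean distance of biomass cells from the coverslip (um)."""
    if state.biomass == 0:
        raise ValueError("mean cell depth is undefined for an empty biofilm")
    zz, _ = np.nonzero(state.occ)
    return float(zz.mean())


def convex_hull_density(state: BiofilmState) -> float:
    """Biomass count over the area of the convex hull of the occupied cells.

    The hull is taken over the four corners of each occupied unit cell (not
    the centres), so solid convex shapes score exactly 1 and a single cell is
    well-defined with density 1.
    """
    if state.biomass == 0:
        raise ValueError("convex-hull density is undefined for an empty biofilm")
    zz, xx = np.nonzero(state.occ)
    corners = np.empty((4 * len(xx), 2), dtype=float)
    for i, (ddx, ddz) in enumerate(((0, 0), (1, 0), (0, 1), (1, 1))):
        corners[i :: 4, 0] = xx + ddx
        corners[i :: 4, 1] = zz + ddz
    area = ConvexHull(np.unique(corners, axis=0)).volume  # 2D hull: .volume is area
    return float(len(xx) / area)


def nutrient_scarcity(b: float, r: float) -> float:
    """Dimensionless nutrient scarcity ``n_s = 1 / (b^2 r)``.

    Approximately the equilibrium concentration an isolated cell sees
    relative to the bulk; small values mean nutrient-deprived regimes.
    """
    if r <= 0:
        raise ValueError("nutrient scarcity is undefined for r <= 0")
    if b < 1:
        raise ValueError("boundary-layer thickness b must be >= 1")
    return 1.0 / (b * b * r)


def inverse_nutrient_scarcity(b: float, r: float) -> float:
    """``1 / n_s = b^2 r``; defined for all r >= 0."""
    if r < 0 or b < 1:
        raise ValueError("require r >= 0 and b >= 1")
    return b * b * r
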