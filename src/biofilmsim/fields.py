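"""Continuum fields over the biofilm lattice: nutrient concentration and light.

The nutrient field solves the equilibrium reaction-diffusion problem
``lap(n) = r * c * n`` on the biofilm and its diffusive boundary layer, with
``n = 1`` clamped in the well-mixed bulk and zero-flux (mirror) conditions at
the coverslip, the sides, and the top of the grid.  ``r = u0 / D`` is the
uptake-diffusion ratio; the diffusion constant and uptake rate never appear
separately.  Concentrations are relative to the bulk value, so ``n`` lies in
``[0, 1]``.

Light enters at the coverslip pointing in +z and attenuates exponentially
through biomass (Beer-Lambert law with characteristic penetration depth
``p``): ``I[x, z] = exp(-(1/p) * sum_{i<=z} c[x, i])`` with the incident
intensity normalised to 1 (it is absorbed into the light Monod parameter).
The column sum includes row ``z`` itself, so a biomass cell shades itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import distance_transform_edt
from scipy.sparse.linalg import spsolve

from .lattice import BiofilmState, GridConfig

__all__ = [
    "ScalarField",
    "DomainMask",
    "BIOMASS",
    "BOUNDARY_LAYER",
    "BULK",
    "compute_domain_mask",
    "solve_nutrient_field",
    "compute_light_field",
]

BIOMASS = 0
BOUNDARY_LAYER = 1
BULK = 2


@dataclass
class ScalarField:
    """One real value per grid cell, tagged by meaning (nutrient | light | probability)."""

    config: GridConfig
    values: np.ndarray  # shape (depth, width), indexed [z, x]
    kind: str = "nutrient"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.config.depth, self.config.width):
            raise ValueError("field shape does not match grid")


@dataclass
class DomainMask:
    """Per-cell region label: biomass (0), boundary-layer media (1), bulk media (2)."""

    config: GridConfig
    labels: np.ndarray  # shape (depth, width)


def compute_domain_mask(state: BiofilmState, b: float, periodic_x: bool = False) -> DomainMask:
    """Label each cell biomass / boundary-layer / bulk.

    The boundary layer is a circular dilation of the biomass by radius ``b``:
    media cells whose Euclidean centre-to-centre distance to the nearest
    biomass cell is <= ``b``.  With no biomass, every cell is bulk.
    """
    if b < 1:
        raise ValueError(f"boundary-layer thickness b={b} must be >= 1")
    labels = np.full(state.occ.shape, BULK, dtype=np.uint8)
    if state.biomass == 0:
        return DomainMask(state.config, labels)
    if periodic_x:
        w = state.config.width
        tiled = np.tile(state.occ == 0, (1, 3))
        dist = distance_transform_edt(tiled)[:, w : 2 * w]
    else:
        dist = distance_transform_edt(state.occ == 0)
    labels[(state.occ == 0) & (dist <= b)] = BOUNDARY_LAYER
    labels[state.occ == 1] = BIOMASS
    return DomainMask(state.config, labels)


def solve_nutrient_field(
    state: BiofilmState, mask: DomainMask, r: float, periodic_x: bool = False
) -> ScalarField:
    """Equilibrium nutrient concentration on the grid.

    Discretises ``lap(n) = r*c*n`` with the standard 5-point stencil at unit
    spacing over the biomass and boundary-layer cells, Dirichlet ``n = 1`` on
    bulk cells, and mirrored ghost cells (zero flux) at all four grid borders.
    Only the non-bulk cells enter the sparse linear system; bulk neighbours
    contribute their clamped value to the right-hand side.
    """
    if r < 0:
        raise ValueError(f"uptake-diffusion ratio r={r} must be >= 0")
    d, w = state.occ.shape
    n = np.ones((d, w), dtype=float)
    unknown = mask.labels != BULK
    if r == 0.0 or not unknown.any():
        return ScalarField(state.config, n, kind="nutrient")

    idx = -np.ones((d, w), dtype=np.int64)
    uz, ux = np.nonzero(unknown)
    m = uz.size
    idx[uz, ux] = np.arange(m)

    diag = -(r * state.occ[uz, ux].astype(float))
    rhs = np.zeros(m)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for dz, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        nz, nx = uz + dz, ux + dx
        if periodic_x and dx != 0:
            nx = nx % w
        ingrid = (nz >= 0) & (nz < d) & (nx >= 0) & (nx < w)
        # mirrored ghost at the border: the missing neighbour equals the cell
        # itself and its stencil term vanishes, so only in-grid neighbours count
        diag[ingrid] -= 1.0
        nzi, nxi = nz[ingrid], nx[ingrid]
        nbr_idx = idx[nzi, nxi]
        interior = nbr_idx >= 0
        rows.append(np.nonzero(ingrid)[0][interior])
        cols.append(nbr_idx[interior])
        vals.append(np.ones(int(interior.sum())))
        # bulk neighbour: Dirichlet value 1 moves to the right-hand side
        bulk_rows = np.nonzero(ingrid)[0][~interior]
        np.add.at(rhs, bulk_rows, -1.0)

    A = sparse.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (np.concatenate(rows + [np.arange(m)]), np.concatenate(cols + [np.arange(m)])),
        ),
        shape=(m, m),
    ).tocsc()
    sol = spsolve(A, rhs)
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("nutrient solve produced non-finite values (singular system?)")
    n[uz, ux] = sol
    # clip away solver round-off; the discrete maximum principle bounds n in [0, 1]
    np.clip(n, 0.0, 1.0, out=n)
    return ScalarField(state.config, n, kind="nutrient")


def compute_light_field(state: BiofilmState, p: float) -> ScalarField:
    """Beer-Lambert light intensity, incident intensity 1 at the coverslip."""
    if p <= 0:
        raise ValueError(f"light penetration depth p={p} must be > 0")
    shading = np.cumsum(state.occ, axis=0, dtype=float)  # inclusive of row z
    values = np.exp(-shading / p)
    return ScalarField(state.config, values, kind="light")
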