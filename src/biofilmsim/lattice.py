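"""Occupancy lattice for the cellular-automaton biofilm.

The biofilm lives on a ``w x d`` grid of square cells (one cell ~ 1 um x 1 um).
Each cell is either biomass-filled (1) or media-filled (0).  Coordinates are
0-based ``(x, z)`` with ``z = 0`` the coverslip row and ``z`` increasing away
from the substratum.  Internally occupancy is stored as a ``(d, w)`` uint8
array indexed ``occ[z, x]``.

Biomass only ever appears adjacent to existing biomass (daughter placement) or
on the coverslip (inoculation), and never disappears: the biofilm stays
4-connected to the coverslip and occupancy transitions are monotone 0 -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridConfig",
    "BiofilmState",
    "inoculate",
    "neighbors4",
    "perimeter",
    "delta_perimeter",
    "save_state_csv",
    "load_state_csv",
]


@dataclass(frozen=True)
class GridConfig:
    """Lattice dimensions: ``width`` columns (x) by ``depth`` rows (z)."""

    width: int = 128
    depth: int = 40

    def __post_init__(self) -> None:
        if self.width < 1 or self.depth < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.width}x{self.depth}")


@dataclass
class BiofilmState:
    """Binary occupancy grid plus a monotone step counter.

    ``occ[z, x] == 1`` marks a biomass-filled cell.
    """

    config: GridConfig
    occ: np.ndarray = field(default=None)  # type: ignore[assignment]
    step: int = 0

    def __post_init__(self) -> None:
        if self.occ is None:
            self.occ = np.zeros((self.config.depth, self.config.width), dtype=np.uint8)
        else:
            self.occ = np.asarray(self.occ, dtype=np.uint8)
            if self.occ.shape != (self.config.depth, self.config.width):
                raise ValueError(
                    f"occupancy shape {self.occ.shape} does not match grid "
                    f"({self.config.depth}, {self.config.width})"
                )

    @property
    def biomass(self) -> int:
        """Number of biomass-filled cells."""
        return int(self.occ.sum())

    def copy(self) -> "BiofilmState":
        return BiofilmState(self.config, self.occ.copy(), self.step)

    def is_connected_to_coverslip(self) -> bool:
        """Flood-fill check that every biomass cell reaches row z=0 through biomass."""
        from scipy.ndimage import label

        if self.biomass == 0:
            return True
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        labels, _ = label(self.occ, structure=structure)
        rooted = np.unique(labels[0][self.occ[0] > 0])
        return bool(np.isin(labels[self.occ > 0], rooted).all())


def inoculate(config: GridConfig, s: int) -> BiofilmState:
    """Seed the coverslip row with biomass cells spaced ``s`` apart.

    Cells are placed at ``z = 0``, ``x = 0, s, 2s, ...`` for as long as the
    positions fall inside the grid, giving ``ceil(w / s)`` founder cells.
    """
    if s < 1 or s > config.width:
        raise ValueError(f"inoculation separation s={s} outside [1, {config.width}]")
    state = BiofilmState(config)
    state.occ[0, 0 :: s] = 1
    return state


def neighbors4(
    coord: tuple[int, int], config: GridConfig, periodic_x: bool = False
) -> list[tuple[int, int]]:
    """Edge-adjacent neighbors of ``(x, z)``, clipped at the borders.

    With ``periodic_x`` the side borders wrap instead of clipping.
    """
    x, z = coord
    out = []
    for dx, dz in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nx, nz = x + dx, z + dz
        if periodic_x:
            nx %= config.width
        if 0 <= nx < config.width and 0 <= nz < config.depth:
            out.append((nx, nz))
    return out


def perimeter(
    state: BiofilmState,
    region: tuple[int, int, int, int] | None = None,
) -> int:
    """Biomass-media interface length for a rectangular region.

    Counts lattice edges incident to at least one cell of ``region = (x0,
    x1, z0, z1)`` (half-open bounds; ``None`` means the full grid) whose two
    sides differ in biomass/media state.  Everything outside the grid is
    treated as media, so the exposed edges of biomass cells on the grid
    border count toward the perimeter.
    """
    occ = state.occ
    d, w = occ.shape
    if region is None:
        region = (0, w, 0, d)
    x0, x1, z0, z1 = region
    # pad with media: grid borders and cells just outside the region both
    # contribute interface edges against the region's biomass cells
    xp0, xp1 = max(0, x0 - 1), min(w, x1 + 1)
    zp0, zp1 = max(0, z0 - 1), min(d, z1 + 1)
    sub = occ[zp0:zp1, xp0:xp1]
    padded = np.pad(sub, 1, constant_values=0)
    # offsets of the region inside the padded array
    ox, oz = x0 - xp0 + 1, z0 - zp0 + 1
    nx_, nz_ = x1 - x0, z1 - z0
    total = 0
    inr = np.zeros_like(padded, dtype=bool)
    inr[oz : oz + nz_, ox : ox + nx_] = True
    diff_h = padded[:, 1:] != padded[:, :-1]
    keep_h = inr[:, 1:] | inr[:, :-1]
    diff_v = padded[1:, :] != padded[:-1, :]
    keep_v = inr[1:, :] | inr[:-1, :]
    total = int(np.count_nonzero(diff_h & keep_h)) + int(np.count_nonzero(diff_v & keep_v))
    return total


def delta_perimeter(
    state: BiofilmState, candidate: tuple[int, int], periodic_x: bool = False
) -> int:
    """Perimeter change from filling the media cell ``candidate`` with biomass.

    Local rule: ``dL = 4 - 2k`` where ``k`` is the number of biomass
    4-neighbors.  Exact for 4-connectivity: each of the candidate's four
    edges becomes a new interface edge unless it faces biomass, in which
    case an existing interface edge is also removed.  Out-of-grid counts as
    media (wrapped neighbours are real cells in periodic-x mode), so the
    rule is uniform across the grid, including the borders.
    """
    x, z = candidate
    if state.occ[z, x]:
        raise ValueError(f"candidate cell {candidate} is already biomass")
    nbrs = neighbors4(candidate, state.config, periodic_x=periodic_x)
    k = sum(int(state.occ[nz, nx]) for nx, nz in nbrs)
    return 4 - 2 * k


def save_state_csv(state: BiofilmState, path) -> None:
    """Write occupancy as a plain-text 0/1 matrix, one grid row per line (z=0 first)."""
    np.savetxt(path, state.occ, fmt="%d", delimiter=",")


def load_state_csv(path, step: int = 0) -> BiofilmState:
    occ = np.loadtxt(path, dtype=np.uint8, delimiter=",", ndmin=2)
    config = GridConfig(width=occ.shape[1], depth=occ.shape[0])
    return BiofilmState(config, occ, step=step)
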