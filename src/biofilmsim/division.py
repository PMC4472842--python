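"""Cell division kinetics and daughter-cell placement.

Division: each biomass cell divides in a time step with probability given by
Monod kinetics, ``K(y, y_half) = y / (y + y_half)``, evaluated on the local
nutrient concentration and, for light-dependent biofilms, multiplied by the
same factor on the local light intensity.  A cell divides when its
probability strictly exceeds an independent uniform draw.

Placement: a daughter cell goes to a media cell within the N-by-N block
centred on the parent, restricted to cells edge-adjacent to existing biomass
(the biofilm stays connected).  Candidate weights combine a distance factor
``R = 1 / ((x - x0)^2 + (z - z0)^2)`` raised to ``alpha`` and a surface-energy
factor ``S = exp(-dL)`` raised to ``beta``, where ``dL`` is the perimeter
change the daughter would cause.  Surface tension and kT are folded into
``beta``; the square-root of the Euclidean distance is folded into ``alpha``,
so ``R`` is the reciprocal of the *squared* distance as written.  The
normalisation ``A = 1 / sum(R^alpha * S^beta)`` is capped at ``A_max``:
parents whose candidates are all essentially unreachable (deep interior
divisions) place no daughter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ScalarField
from .lattice import BiofilmState, delta_perimeter

__all__ = [
    "KineticsParams",
    "PlacementParams",
    "PlacementDistribution",
    "monod",
    "division_probabilities",
    "draw_dividing_cells",
    "placement_distribution",
    "place_daughters",
]


@dataclass(frozen=True)
class KineticsParams:
    """Monod half-saturation parameters for division probability.

    ``n_half`` and ``i_half`` are the nutrient concentration and light
    intensity (relative to bulk / incident) at which a cell divides with
    probability 1/2 per step when the other factor is unity.
    """

    n_half: float = 0.25
    i_half: float = 0.5
    light_dependent: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.n_half <= 1.0):
            raise ValueError(f"n_half={self.n_half} outside [0, 1]")
        if not (0.0 <= self.i_half <= 1.0):
            raise ValueError(f"i_half={self.i_half} outside [0, 1]")


@dataclass(frozen=True)
class PlacementParams:
    """Daughter-placement weights: block size N, distance weight alpha,
    surface-energy weight beta, and the normalisation cutoff A_max."""

    block: int = 11
    alpha: float = 2.0
    beta: float = 1.0
    a_max: float = 1e12

    def __post_init__(self) -> None:
        if self.block < 3 or self.block % 2 == 0:
            raise ValueError(f"block length N={self.block} must be odd and >= 3")
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")


@dataclass
class PlacementDistribution:
    parent: tuple[int, int]
    candidates: list[tuple[int, int]] = field(default_factory=list)
    probabilities: np.ndarray = field(default_factory=lambda: np.zeros(0))
    normalization: float = float("inf")
    skipped: bool = True


def monod(y: float, y_half: float) -> float:
    """Saturating Monod factor ``y / (y + y_half)``."""
    if y < 0 or y_half < 0:
        raise ValueError("monod arguments must be non-negative")
    if y == 0 and y_half == 0:
        raise ValueError("monod(0, 0) is undefined")
    return y / (y + y_half)


def division_probabilities(
    state: BiofilmState,
    nutrient: ScalarField,
    light: ScalarField | None,
    kinetics: KineticsParams,
) -> ScalarField:
    """Per-cell division probability field; media cells get probability 0."""
    if nutrient.values.shape != state.occ.shape:
        raise ValueError("nutrient field does not match state grid")
    occ = state.occ.astype(bool)
    prob = np.zeros(state.occ.shape, dtype=float)
    denom = nutrient.values + kinetics.n_half
    np.divide(nutrient.values, denom, out=prob, where=occ & (denom > 0))
    if kinetics.light_dependent:
        if light is None:
            raise ValueError("light-dependent kinetics require a light field")
        if light.values.shape != state.occ.shape:
            raise ValueError("light field does not match state grid")
        lden = light.values + kinetics.i_half
        lfac = np.ones_like(prob)
        np.divide(light.values, lden, out=lfac, where=lden > 0)
        prob *= lfac
    return ScalarField(state.config, prob, kind="probability")


def draw_dividing_cells(prob: ScalarField, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Cells whose probability strictly exceeds an independent U[0,1) draw.

    One uniform is drawn per grid cell in a fixed layout, so the consumed
    random stream is independent of the biofilm shape; returned coordinates
    are in row-major (z, x) scan order.
    """
    v = rng.random(prob.values.shape)
    zz, xx = np.nonzero(prob.values > v)
    return [(int(x), int(z)) for x, z in zip(xx, zz)]


def placement_distribution(
    state: BiofilmState,
    parent: tuple[int, int],
    params: PlacementParams,
    periodic_x: bool = False,
) -> PlacementDistribution:
    """Daughter-placement distribution over the N-by-N block around ``parent``.

    Biomass cells and media cells with no biomass 4-neighbour get probability
    zero; remaining candidates get ``P = A * R^alpha * S^beta``.  ``skipped``
    is set when no candidate exists or the normalisation exceeds ``A_max``.
    The block is clipped at the grid borders (wrapped in x when periodic).
    """
    x0, z0 = parent
    if not state.occ[z0, x0]:
        raise ValueError(f"parent {parent} is not a biomass cell")
    d, w = state.occ.shape
    half = params.block // 2
    zlo, zhi = max(0, z0 - half), min(d, z0 + half + 1)
    if periodic_x and w > params.block:
        xoffsets = range(-half, half + 1)
    else:
        xoffsets = range(max(0, x0 - half) - x0, min(w, x0 + half + 1) - x0)

    occ = state.occ
    candidates: list[tuple[int, int]] = []
    weights: list[float] = []
    for z in range(zlo, zhi):
        for dx in xoffsets:
            x = (x0 + dx) % w if periodic_x else x0 + dx
            if occ[z, x]:
                continue
            if periodic_x:
                k = (
                    occ[z, (x - 1) % w]
                    + occ[z, (x + 1) % w]
                    + (z > 0 and occ[z - 1, x])
                    + (z < d - 1 and occ[z + 1, x])
                )
            else:
                k = (
                    (x > 0 and occ[z, x - 1])
                    + (x < w - 1 and occ[z, x + 1])
                    + (z > 0 and occ[z - 1, x])
                    + (z < d - 1 and occ[z + 1, x])
                )
            if not k:
                continue
            dist_sq = dx * dx + (z - z0) ** 2
            dl = delta_perimeter(state, (x, z), periodic_x=periodic_x)
            weights.append((1.0 / dist_sq) ** params.alpha * np.exp(-params.beta * dl))
            candidates.append((x, z))

    if not candidates:
        return PlacementDistribution(parent)
    total = float(np.sum(weights))
    a = 1.0 / total
    if a > params.a_max:
        return PlacementDistribution(parent, candidates, normalization=a, skipped=True)
    probs = np.asarray(weights) * a
    return PlacementDistribution(parent, candidates, probs, a, skipped=False)


def place_daughters(
    state: BiofilmState,
    dividing: list[tuple[int, int]],
    params: PlacementParams,
    rng: np.random.Generator,
    biomass_cap: int | None = None,
    periodic_x: bool = False,
) -> tuple[BiofilmState, list[dict]]:
    """Place one daughter per dividing cell, iterating in uniformly random order.

    Placement distributions are computed against the continuously updated
    state, so daughters placed earlier in the step are visible to later
    parents.  ``biomass_cap`` truncates the step exactly at a prescribed
    total biomass.  Returns the updated state and an event log (parent,
    daughter, skipped flag per processed division).
    """
    new = state.copy()
    events: list[dict] = []
    order = rng.permutation(len(dividing))
    count = new.biomass
    for i in order:
        if biomass_cap is not None and count >= biomass_cap:
            break
        parent = dividing[i]
        dist = placement_distribution(new, parent, params, periodic_x=periodic_x)
        if dist.skipped:
            events.append({"parent": parent, "daughter": None, "skipped": True})
            continue
        j = rng.choice(len(dist.candidates), p=dist.probabilities)
        dx, dz = dist.candidates[j]
        new.occ[dz, dx] = 1
        count += 1
        events.append({"parent": parent, "daughter": (dx, dz), "skipped": False})
    return new, events
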