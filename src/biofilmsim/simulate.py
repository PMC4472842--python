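"""Time-stepping orchestration, run configuration, and parameter sweeps.

Each time step has two phases: (1) the domain mask, equilibrium nutrient
field, and (for light-dependent biofilms) light field are computed from the
pre-step state; (2) biomass cells divide stochastically against those fields
and daughters are placed.  A run starts from an evenly spaced coverslip
inoculation and advances until a prescribed biomass count is reached (with
exact-target truncation), the maximum division probability becomes
negligible, or a step ceiling is hit.

All randomness in a run flows from a single seeded generator consumed in a
fixed order (division draws over the whole grid in array layout, then the
placement iteration order, then one candidate draw per placed daughter), so
a seed fully determines the trajectory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .division import (
    KineticsParams,
    PlacementParams,
    division_probabilities,
    draw_dividing_cells,
    place_daughters,
)
from .fields import compute_domain_mask, compute_light_field, solve_nutrient_field
from .lattice import BiofilmState, GridConfig, inoculate

__all__ = ["SimulationParams", "Trajectory", "step", "run", "sweep", "TABLE_RANGES"]

# Explored parameter ranges: (low, high) per symbol.
TABLE_RANGES: dict[str, tuple[float, float]] = {
    "s": (1, 64),
    "b": (1, 16),
    "r": (0.0, 5.0),
    "p": (0.0, 30.0),
    "i_half": (0.0, 1.0),
    "n_half": (0.0, 1.0),
    "alpha": (0.0, 3.0),
    "beta": (0.0, 3.0),
}


@dataclass(frozen=True)
class SimulationParams:
    """Full configuration of one simulation run.

    Geometry (w, d), inoculation separation ``s``, boundary-layer thickness
    ``b``, uptake-diffusion ratio ``r``, light penetration depth ``p`` with
    the light-dependence flag, Monod parameters, placement weights, and the
    stop criteria.  Lengths are in grid cells (~1 um each).
    """

    width: int = 128
    depth: int = 40
    s: int = 8
    b: float = 7.0
    r: float = 0.5
    p: float = 2.0
    light_dependent: bool = False
    i_half: float = 0.5
    n_half: float = 0.25
    block: int = 11
    alpha: float = 2.0
    beta: float = 1.0
    a_max: float = 1e12
    target_biomass: int = 2000
    max_steps: int = 20000
    prob_threshold: float = 1e-6
    periodic_x: bool = False
    seed: int = 0

    def validate_ranges(self) -> None:
        """Check every parameter against the explored ranges."""
        for name, (lo, hi) in TABLE_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside explored range [{lo}, {hi}]")
        if self.block != 11:
            raise ValueError("explored configuration uses block length N=11")

    @property
    def grid(self) -> GridConfig:
        return GridConfig(self.width, self.depth)

    @property
    def kinetics(self) -> KineticsParams:
        return KineticsParams(self.n_half, self.i_half, self.light_dependent)

    @property
    def placement(self) -> PlacementParams:
        return PlacementParams(self.block, self.alpha, self.beta, self.a_max)

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)


@dataclass
class Trajectory:
    """Recorded outcome of a run: per-step metrics, final state, stop reason."""

    params: SimulationParams
    final_state: BiofilmState
    records: pd.DataFrame
    stop_reason: str
    states: list[BiofilmState] = field(default_factory=list)


def _advance(
    state: BiofilmState,
    params: SimulationParams,
    rng: np.random.Generator,
    biomass_cap: int | None,
) -> tuple[BiofilmState, float, list[dict]]:
    """One two-phase step; returns (new state, max division probability, events)."""
    mask = compute_domain_mask(state, params.b, periodic_x=params.periodic_x)
    nutrient = solve_nutrient_field(state, mask, params.r, periodic_x=params.periodic_x)
    light = None
    if params.light_dependent and params.p > 0:
        light = compute_light_field(state, params.p)
    prob = division_probabilities(state, nutrient, light, params.kinetics)
    max_prob = float(prob.values.max()) if state.biomass else 0.0
    dividing = draw_dividing_cells(prob, rng)
    new, events = place_daughters(
        state, dividing, params.placement, rng,
        biomass_cap=biomass_cap, periodic_x=params.periodic_x,
    )
    new.step = state.step + 1
    return new, max_prob, events


def step(
    state: BiofilmState,
    params: SimulationParams,
    rng: np.random.Generator,
    biomass_cap: int | None = None,
) -> BiofilmState:
    """Advance the biofilm by one time step."""
    new, _, _ = _advance(state, params, rng, biomass_cap)
    return new


def run(
    params: SimulationParams,
    record_states: bool = False,
    record_every: int = 1,
) -> Trajectory:
    """Simulate from inoculation until a stop criterion fires.

    Stop reasons: ``"target"`` (biomass reached ``target_biomass``, truncated
    exactly), ``"stalled"`` (max division probability below
    ``prob_threshold``), ``"max_steps"``.
    """
    rng = np.random.default_rng(params.seed)
    state = inoculate(params.grid, params.s)
    rows = []
    states: list[BiofilmState] = []

    def record(st: BiofilmState) -> None:
        rows.append(
            {
                "step": st.step,
                "biomass": st.biomass,
                "mean_thickness": _metrics.mean_thickness(st),
                "mean_cell_depth": _metrics.mean_cell_depth(st) if st.biomass else np.nan,
            }
        )
        if record_states and st.step % record_every == 0:
            states.append(st.copy())

    record(state)
    stop = "max_steps"
    if state.biomass >= params.target_biomass:
        stop = "target"
    else:
        while state.step < params.max_steps:
            state, max_prob, _ = _advance(state, params, rng, params.target_biomass)
            record(state)
            if state.biomass >= params.target_biomass:
                stop = "target"
                break
            if max_prob < params.prob_threshold:
                stop = "stalled"
                break
    return Trajectory(params, state, pd.DataFrame(rows), stop, states)


def _sample_value(spec, rng: np.random.Generator):
    """Draw one value from a sampler spec entry.

    A scalar is fixed; ``(lo, hi)`` is uniform; ``("loguniform", lo, hi)``
    samples uniformly in log space; ``("uniform", lo, hi)`` is explicit.
    """
    if np.isscalar(spec):
        return spec
    if len(spec) == 2:
        lo, hi = spec
        return rng.uniform(lo, hi)
    kind, lo, hi = spec
    if kind == "uniform":
        return rng.uniform(lo, hi)
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    raise ValueError(f"unknown sampler kind {kind!r}")


#: coverage features recorded per sweep sample (depths in um)
SWEEP_COVERAGE_DEPTHS = tuple(range(0, 21))


def sweep(
    sampler: dict,
    n_samples: int,
    seed: int,
    base: SimulationParams | None = None,
    thickness_range: tuple[float, float] = (0.0, 40.0),
) -> pd.DataFrame:
    """Run ``n_samples`` simulations with parameters drawn from ``sampler``.

    ``sampler`` maps SimulationParams field names to sampler specs (see
    ``_sample_value``); unspecified fields keep their ``base`` values.  The
    target biomass of each sample is drawn uniformly as a mean thickness from
    ``thickness_range`` (um) and converted to a cell count, unless the
    sampler pins ``target_biomass`` directly.  Returns one row per sample
    with the drawn parameters, the derived nutrient scarcity ``inv_ns =
    b^2 r``, final morphology metrics, and the coverage profile sampled
    every 1 um from 0 to 20 um.  Per-sample failures are recorded in the
    ``error`` column rather than raised.
    """
    base = base or SimulationParams()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        draws = {k: _sample_value(v, rng) for k, v in sampler.items()}
        if "s" in draws:
            draws["s"] = int(max(1, round(draws["s"])))
        if "target_biomass" not in draws:
            thickness = rng.uniform(*thickness_range)
            draws["target_biomass"] = max(
                int(round(thickness * base.width)), int(np.ceil(base.width / draws.get("s", base.s)))
            )
        draws["target_biomass"] = int(draws["target_biomass"])
        run_seed = int(rng.integers(0, 2**31 - 1))
        params = base.replace(seed=run_seed, **draws)
        row = {
            "sample": i,
            **{k: getattr(params, k) for k in (
                "s", "b", "r", "p", "light_dependent", "i_half", "n_half",
                "alpha", "beta", "target_biomass", "seed",
            )},
            "inv_ns": _metrics.inverse_nutrient_scarcity(params.b, params.r),
            "error": "",
        }
        try:
            traj = run(params)
            st = traj.final_state
            cov = _metrics.coverage_by_depth(st)
            row.update(
                stop_reason=traj.stop_reason,
                steps=st.step,
                biomass=st.biomass,
                mean_thickness=_metrics.mean_thickness(st),
                mean_cell_depth=_metrics.mean_cell_depth(st),
                hull_density=_metrics.convex_hull_density(st),
            )
            for depth, val in zip(SWEEP_COVERAGE_DEPTHS, cov.sample(SWEEP_COVERAGE_DEPTHS)):
                row[f"cov_{depth}"] = val
        except Exception as exc:  # per-sample failures are data, not crashes
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
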