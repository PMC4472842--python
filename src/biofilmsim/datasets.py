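"""Ready-made synthetic datasets tying the pipeline stages together.

The experimental confocal stacks behind the original morphology classifier
are not publicly deposited, so classifier workflows here train on synthetic
stacks rendered by :mod:`biofilmsim.imaging`: laminar films stand in for the
dense heterotrophic-like morphology and mushroom-capped pillars for the
photoheterotrophic-like one.  Each rendered stack passes through the full
quantification path (attenuation, noise, adaptive threshold, binarisation)
before its coverage features are extracted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import (
    SynthSpec,
    binarize_stack,
    make_threshold_schedule,
    stack_biomass,
    stack_coverage_by_depth,
    synth_stack,
)
from .metrics import CoverageProfile

__all__ = ["synthetic_stack_training_set", "sweep_coverage_profiles"]


def synthetic_stack_training_set(
    n_per_class: int = 40,
    seed: int = 0,
    shape: tuple[int, int, int] = (26, 48, 48),
    attenuation_length: float = 10.0,
    noise_sigma: float = 0.03,
) -> tuple[list[CoverageProfile], list[float], list[str]]:
    """Labelled coverage curves from rendered laminar vs mushroom stacks.

    Geometry varies per stack (film heights 8-21 um; stems 2-4 um radius
    with caps of radius 7-11 starting 4-7 um up).  Stacks are rendered with
    depth attenuation and noise, then segmented with a threshold schedule
    that tracks the attenuated foreground/background midpoint.  Returns
    (coverage curves, biomass in um, labels).
    """
    rng = np.random.default_rng(seed)
    nz = shape[0]
    mid = 0.6  # midpoint of the rendered fg (1.0) and bg (0.2) levels
    anchors = [(z, mid * np.exp(-z / attenuation_length)) for z in (0, nz // 2, nz - 1)]
    schedule = make_threshold_schedule(anchors)

    curves: list[CoverageProfile] = []
    biomasses: list[float] = []
    labels: list[str] = []

    def render(spec: SynthSpec) -> None:
        stack, _ = synth_stack(
            spec,
            noise_sigma=noise_sigma,
            attenuation_length=attenuation_length,
            seed=int(rng.integers(2**31)),
        )
        binary = binarize_stack(stack, schedule)
        curves.append(stack_coverage_by_depth(binary, dz=spec.voxel[2]))
        biomasses.append(stack_biomass(binary, spec.voxel))

    for _ in range(n_per_class):
        render(
            SynthSpec(
                "laminar", shape=shape, column_height=int(rng.integers(8, 22)), bg=0.2
            )
        )
        labels.append("heterotrophic")
        cap_start = int(rng.integers(4, 8))
        render(
            SynthSpec(
                "mushroom",
                shape=shape,
                n_columns=5,
                stem_radius=float(rng.uniform(2, 4)),
                cap_radius=float(rng.uniform(7, 11)),
                cap_start=cap_start,
                cap_end=cap_start + int(rng.integers(4, 8)),
                bg=0.2,
            )
        )
        labels.append("photoheterotrophic")
    return curves, biomasses, labels


def sweep_coverage_profiles(table: pd.DataFrame) -> list[CoverageProfile]:
    """Coverage profiles (0-20 um at 1 um spacing) from a sweep table's rows."""
    cols = [f"cov_{i}" for i in range(21)]
    return [CoverageProfile(row[cols].to_numpy(dtype=float)) for _, row in table.iterrows()]
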