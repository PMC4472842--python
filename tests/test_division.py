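import math

import numpy as np
import pytest

from biofilmsim.division import (
    KineticsParams,
    PlacementParams,
    division_probabilities,
    draw_dividing_cells,
    monod,
    place_daughters,
    placement_distribution,
)
from biofilmsim.fields import ScalarField, compute_domain_mask, compute_light_field, solve_nutrient_field
from biofilmsim.lattice import BiofilmState, GridConfig, perimeter
from conftest import random_state


class TestMonod:
    @pytest.mark.parametrize(
        "y, y_half, expected",
        [(0.25, 0.25, 0.5), (0.0, 0.3, 0.0), (3.0, 1.0, 0.75), (1.0, 0.0, 1.0)],
    )
    def test_values(self, y, y_half, expected):
        assert monod(y, y_half) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            monod(0.0, 0.0)


class TestDivisionProbabilities:
    def test_light_independent_uniform_nutrient(self):
        st = BiofilmState(GridConfig(6, 4))
        st.occ[0, :] = 1
        n = ScalarField(st.config, np.ones(st.occ.shape))
        prob = division_probabilities(st, n, None, KineticsParams(n_half=0.25))
        assert np.allclose(prob.values[0, :], 0.8)
        assert np.all(prob.values[1:, :] == 0.0)

    def test_zero_light_half_reduces_to_light_independent(self):
        st = random_state(4, width=8, depth=6, density=0.4)
        n = ScalarField(st.config, np.full(st.occ.shape, 0.6))
        light = compute_light_field(st, p=2.0)
        li = division_probabilities(st, n, None, KineticsParams(n_half=0.3))
        ld = division_probabilities(
            st, n, light, KineticsParams(n_half=0.3, i_half=0.0, light_dependent=True)
        )
        np.testing.assert_allclose(ld.values, li.values)

    def test_single_coverslip_cell_light_dependent(self):
        # self-shading column of one cell: I = exp(-1/p), P = K(I, 1/2) * K(1, 1/4)
        st = BiofilmState(GridConfig(5, 5))
        st.occ[0, 2] = 1
        n = ScalarField(st.config, np.ones(st.occ.shape))
        light = compute_light_field(st, p=2.0)
        prob = division_probabilities(
            st, n, light, KineticsParams(n_half=0.25, i_half=0.5, light_dependent=True)
        )
        i_val = math.exp(-0.5)
        assert prob.values[0, 2] == pytest.approx(i_val / (i_val + 0.5) * 0.8)

    def test_light_mode_requires_light_field(self):
        st = BiofilmState(GridConfig(4, 4))
        st.occ[0, 0] = 1
        n = ScalarField(st.config, np.ones(st.occ.shape))
        with pytest.raises(ValueError):
            division_probabilities(st, n, None, KineticsParams(light_dependent=True))


class TestDrawDividingCells:
    def test_zero_probability_divides_nothing(self, rng):
        st = random_state(1, density=0.5)
        prob = ScalarField(st.config, np.zeros(st.occ.shape), "probability")
        assert draw_dividing_cells(prob, rng) == []

    def test_unit_probability_divides_everything(self, rng):
        st = random_state(2, density=0.5)
        vals = np.where(st.occ > 0, 1.0, 0.0)
        prob = ScalarField(st.config, vals, "probability")
        assert len(draw_dividing_cells(prob, rng)) == st.biomass

    def test_half_probability_binomial_fraction(self, rng):
        st = BiofilmState(GridConfig(100, 100))
        st.occ[:] = 1
        prob = ScalarField(st.config, np.full(st.occ.shape, 0.5), "probability")
        frac = len(draw_dividing_cells(prob, rng)) / 1e4
        sigma = math.sqrt(0.25 / 1e4)
        assert abs(frac - 0.5) < 3 * sigma


def brute_force_distribution(state, parent, params):
    """Independent enumeration of the placement weights over the N x N block,
    with dL computed by whole-grid perimeter recomputation."""
    x0, z0 = parent
    d, w = state.occ.shape
    half = params.block // 2
    weights = {}
    for z in range(max(0, z0 - half), min(d, z0 + half + 1)):
        for x in range(max(0, x0 - half), min(w, x0 + half + 1)):
            if state.occ[z, x]:
                continue
            has_biomass_nb = any(
                0 <= x + dx < w and 0 <= z + dz < d and state.occ[z + dz, x + dx]
                for dx, dz in ((1, 0), (-1, 0), (0, 1), (0, -1))
            )
            if not has_biomass_nb:
                continue
            after = state.copy()
            after.occ[z, x] = 1
            dl = perimeter(after) - perimeter(state)
            r_factor = 1.0 / ((x - x0) ** 2 + (z - z0) ** 2)
            weights[(x, z)] = r_factor**params.alpha * math.exp(-params.beta * dl)
    total = sum(weights.values())
    return {c: v / total for c, v in weights.items()} if total else {}


class TestPlacementDistribution:
    def test_isolated_interior_parent_uniform_quarter(self):
        st = BiofilmState(GridConfig(21, 21))
        st.occ[10, 10] = 1
        dist = placement_distribution(st, (10, 10), PlacementParams(alpha=2, beta=1))
        assert len(dist.candidates) == 4
        np.testing.assert_allclose(dist.probabilities, 0.25)

    def test_isolated_coverslip_parent_uniform_third(self):
        st = BiofilmState(GridConfig(21, 21))
        st.occ[0, 10] = 1
        dist = placement_distribution(st, (10, 0), PlacementParams(alpha=2, beta=1))
        assert len(dist.candidates) == 3
        np.testing.assert_allclose(dist.probabilities, 1 / 3)

    def test_two_cell_film_matches_enumeration(self):
        st = BiofilmState(GridConfig(15, 15))
        st.occ[7, 6] = st.occ[7, 7] = 1
        params = PlacementParams(alpha=2, beta=1)
        dist = placement_distribution(st, (6, 7), params)
        oracle = brute_force_distribution(st, (6, 7), params)
        assert set(dist.candidates) == set(oracle)
        for c, prob in zip(dist.candidates, dist.probabilities):
            assert prob == pytest.approx(oracle[c], abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_randomized_states_match_enumeration(self, seed):
        st = random_state(seed, width=15, depth=15, density=0.3)
        zz, xx = np.nonzero(st.occ)
        if not len(xx):
            return
        rng = np.random.default_rng(seed + 1000)
        params = PlacementParams(
            alpha=float(rng.uniform(0, 3)), beta=float(rng.uniform(0, 3))
        )
        i = rng.integers(0, len(xx))
        parent = (int(xx[i]), int(zz[i]))
        dist = placement_distribution(st, parent, params)
        oracle = brute_force_distribution(st, parent, params)
        if dist.skipped:
            assert not oracle or 1.0 / sum(oracle.values()) > params.a_max
            return
        assert set(dist.candidates) == set(oracle)
        for c, prob in zip(dist.candidates, dist.probabilities):
            assert prob == pytest.approx(oracle[c], abs=1e-12)

    def test_probabilities_sum_to_one(self):
        for seed in range(8):
            st = random_state(seed, width=12, depth=12, density=0.4)
            zz, xx = np.nonzero(st.occ)
            if not len(xx):
                continue
            dist = placement_distribution(st, (int(xx[0]), int(zz[0])), PlacementParams())
            if not dist.skipped:
                assert abs(dist.probabilities.sum() - 1.0) < 1e-12

    def test_degenerate_weights_give_uniform(self):
        st = random_state(5, width=12, depth=12, density=0.35)
        zz, xx = np.nonzero(st.occ)
        dist = placement_distribution(
            st, (int(xx[3]), int(zz[3])), PlacementParams(alpha=0, beta=0)
        )
        assert not dist.skipped
        np.testing.assert_allclose(dist.probabilities, 1.0 / len(dist.candidates))

    def test_larger_beta_favors_smaller_perimeter_change(self):
        from biofilmsim.lattice import delta_perimeter

        st = random_state(11, width=13, depth=13, density=0.35)
        zz, xx = np.nonzero(st.occ)
        parent = (int(xx[0]), int(zz[0]))
        lo = placement_distribution(st, parent, PlacementParams(alpha=1, beta=0.2))
        hi = placement_distribution(st, parent, PlacementParams(alpha=1, beta=2.5))
        dls = np.array([delta_perimeter(st, c) for c in lo.candidates])
        mean_dl_lo = float((dls * lo.probabilities).sum())
        mean_dl_hi = float((dls * hi.probabilities).sum())
        assert mean_dl_hi < mean_dl_lo

    def test_sampling_frequencies_match_probabilities(self, rng):
        st = BiofilmState(GridConfig(15, 15))
        st.occ[7, 6] = st.occ[7, 7] = st.occ[6, 7] = 1
        dist = placement_distribution(st, (7, 7), PlacementParams(alpha=2, beta=1))
        n = 100_000
        draws = rng.choice(len(dist.candidates), size=n, p=dist.probabilities)
        counts = np.bincount(draws, minlength=len(dist.candidates))
        for c, prob in zip(counts, dist.probabilities):
            sigma = math.sqrt(prob * (1 - prob) / n)
            assert abs(c / n - prob) < 3 * sigma + 1e-4

    def test_parent_must_be_biomass(self):
        st = BiofilmState(GridConfig(5, 5))
        st.occ[0, 0] = 1
        with pytest.raises(ValueError):
            placement_distribution(st, (2, 2), PlacementParams())


class TestPlaceDaughters:
    def test_empty_dividing_set_noop(self, rng):
        st = random_state(3, density=0.3)
        new, events = place_daughters(st, [], PlacementParams(), rng)
        np.testing.assert_array_equal(new.occ, st.occ)
        assert events == []

    def test_single_division_adds_one_cell(self, rng):
        st = BiofilmState(GridConfig(9, 9))
        st.occ[4, 4] = 1
        new, events = place_daughters(st, [(4, 4)], PlacementParams(), rng)
        assert new.biomass == 2
        assert len(events) == 1 and not events[0]["skipped"]

    @pytest.mark.parametrize("seed", range(5))
    def test_biomass_bookkeeping(self, seed):
        st = random_state(seed, width=14, depth=12, density=0.25)
        zz, xx = np.nonzero(st.occ)
        dividing = [(int(x), int(z)) for x, z in zip(xx, zz)][:6]
        rng = np.random.default_rng(seed)
        new, events = place_daughters(st, dividing, PlacementParams(), rng)
        placed = sum(1 for e in events if not e["skipped"])
        assert new.biomass == st.biomass + placed
        assert len(events) == len(dividing)

    def test_daughters_touch_preexisting_biomass(self, rng):
        st = random_state(8, width=14, depth=12, density=0.3)
        zz, xx = np.nonzero(st.occ)
        dividing = [(int(x), int(z)) for x, z in zip(xx, zz)]
        new, events = place_daughters(st, dividing, PlacementParams(), rng)
        d, w = new.occ.shape
        for e in events:
            if e["skipped"]:
                continue
            x, z = e["daughter"]
            assert any(
                0 <= x + dx < w and 0 <= z + dz < d and new.occ[z + dz, x + dx]
                for dx, dz in ((1, 0), (-1, 0), (0, 1), (0, -1))
            )

    def test_biomass_cap_truncates_exactly(self, rng):
        st = BiofilmState(GridConfig(20, 10))
        st.occ[0, :] = 1
        dividing = [(x, 0) for x in range(20)]
        new, _ = place_daughters(st, dividing, PlacementParams(), rng, biomass_cap=25)
        assert new.biomass == 25
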