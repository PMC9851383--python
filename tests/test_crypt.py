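"""Unit and property tests for the agent-based crypt model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryptsim.crypt import (
    CANCER,
    PHENOTYPES,
    Cell,
    CryptConfigError,
    CryptGeometry,
    GradientParams,
    calibrate_gradients,
    census,
    die_probability,
    divide_probability,
    estimate_division_ratio,
    init_crypt,
    introduce_mutants,
    step_crypt,
)


def make_cell(label, height, gradients):
    return Cell(
        position=(0, 0),
        height_norm=height,
        compartment=gradients.compartment(height),
        phenotype=PHENOTYPES[label],
    )


class TestGeometryValidation:
    def test_capacity_below_target_rejected(self):
        with pytest.raises(CryptConfigError):
            CryptGeometry(
                circumference=10, height=10, homeostatic_target=2000,
                min_viable_cells=100,
            )

    def test_floor_above_target_rejected(self):
        with pytest.raises(CryptConfigError):
            CryptGeometry(homeostatic_target=1000, min_viable_cells=1399)

    @pytest.mark.parametrize("bad", [
        dict(divide_max=1.5),
        dict(divide_max=0.1, divide_min=0.2),
        dict(niche_fraction=0.0),
        dict(niche_fraction=0.8, differentiated_fraction=0.5),
        dict(resistant_exposure=0.0),
    ])
    def test_invalid_gradients_rejected(self, bad):
        with pytest.raises(CryptConfigError):
            GradientParams(**bad)


class TestInitCrypt:
    def test_populates_to_target_all_normal(self, gradients):
        geom = CryptGeometry(
            circumference=25, height=80, homeostatic_target=2000,
            min_viable_cells=1399,
        )
        state = init_crypt(geom, gradients, seed=1)
        c = census(state)
        assert c.total == 2000
        assert c.phenotype_total("normal") == 2000
        assert c.cancer_fraction == 0.0

    def test_same_seed_bit_identical(self, reduced_geometry, gradients):
        a = init_crypt(reduced_geometry, gradients, seed=7)
        b = init_crypt(reduced_geometry, gradients, seed=7)
        assert np.array_equal(a.grid, b.grid)
        assert np.array_equal(a.lineage, b.lineage)


class TestPerCellProbabilities:
    def test_phenotype_divide_ratios(self, gradients):
        """Cancer divides 1.16x and resistant 1.08x a normal cell at the
        same position (exact, pre-clamp)."""
        h = 0.4
        p = {
            lab: divide_probability(make_cell(lab, h, gradients), gradients)
            for lab in ("normal", "cancer", "resistant")
        }
        assert p["cancer"] / p["normal"] == pytest.approx(1.16)
        assert p["resistant"] / p["normal"] == pytest.approx(1.08)

    def test_phenotype_die_ratios_without_drugs(self, gradients):
        h = 0.4
        p = {
            lab: die_probability(make_cell(lab, h, gradients), gradients)
            for lab in ("normal", "cancer", "resistant")
        }
        assert p["cancer"] / p["normal"] == pytest.approx(1.10)
        assert p["resistant"] / p["normal"] == pytest.approx(1.05)

    def test_divide_zero_at_top_with_zero_floor(self, gradients):
        cell = make_cell("normal", 1.0, gradients)
        assert divide_probability(cell, gradients) == 0.0

    def test_divide_clamped_to_one(self):
        g = GradientParams(divide_max=0.9)
        cell = make_cell("cancer", 0.0, g)
        # quiescent unless released; released stem divides at the clamp
        assert divide_probability(cell, g, awake=True) == 1.0

    def test_quiescent_stem_gated_by_release(self, gradients):
        cell = make_cell("normal", 0.05, gradients)
        assert cell.compartment == "quiescent_stem"
        assert divide_probability(cell, gradients, awake=False) == 0.0
        assert divide_probability(cell, gradients, awake=True) > 0.0

    def test_lethality_scales_normal_cell_death(self, gradients):
        cell = make_cell("normal", 0.4, gradients)
        base = die_probability(cell, gradients)
        dosed = die_probability(cell, gradients, lethality=5.75)
        assert dosed == pytest.approx(5.75 * base)

    def test_identity_factors_leave_baseline(self, gradients):
        cell = make_cell("cancer", 0.5, gradients)
        assert die_probability(cell, gradients, 1.0, 1.0) == pytest.approx(
            gradients.die_base(0.5) * 1.10
        )

    def test_apoptotic_targets_top_zone_only(self, gradients):
        top = make_cell("normal", 0.9, gradients)
        mid = make_cell("normal", 0.4, gradients)
        assert die_probability(
            top, gradients, apoptotic_intensity=3.5
        ) == pytest.approx(3.5 * gradients.die_base(0.9))
        assert die_probability(
            mid, gradients, apoptotic_intensity=3.5
        ) == pytest.approx(gradients.die_base(0.4))

    def test_negative_intensity_rejected(self, gradients):
        cell = make_cell("normal", 0.4, gradients)
        with pytest.raises(ValueError):
            die_probability(cell, gradients, lethality=-1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        h=st.floats(0.0, 1.0),
        lethality=st.floats(1.0, 40.0),
        apoptotic=st.floats(1.0, 40.0),
        label=st.sampled_from(["normal", "cancer", "resistant"]),
    )
    def test_probabilities_clamped_and_monotone(self, h, lethality, apoptotic, label):
        """All probabilities stay in [0,1]; death is non-decreasing in both
        drug intensities."""
        g = GradientParams()
        cell = make_cell(label, h, g)
        for awake in (False, True):
            p0 = die_probability(cell, g, 1.0, 1.0, awake=awake)
            p1 = die_probability(cell, g, lethality, apoptotic, awake=awake)
            p2 = die_probability(cell, g, 2 * lethality, 2 * apoptotic, awake=awake)
            assert 0.0 <= p0 <= p1 <= p2 <= 1.0
            assert 0.0 <= divide_probability(cell, g, awake=awake) <= 1.0


class TestMonteCarloDivisionRatio:
    def test_recovers_phenotype_kinetics(self):
        assert estimate_division_ratio("cancer", "normal", seed=3) == pytest.approx(
            1.16, abs=0.01
        )
        assert estimate_division_ratio("resistant", "normal", seed=3) == pytest.approx(
            1.08, abs=0.01
        )


class TestStepCrypt:
    def test_conservation_per_tick(self, settled_tiny_crypt):
        state = settled_tiny_crypt
        for _ in range(50):
            before = state.total_cells()
            step_crypt(state)
            s = state.last_stats
            assert s.births >= 0 and s.deaths >= 0 and s.removals >= 0
            assert state.total_cells() == before + s.births - s.deaths - s.removals

    def test_determinism_from_identical_state(self, tiny_geometry, gradients):
        a = init_crypt(tiny_geometry, gradients, seed=5)
        b = init_crypt(tiny_geometry, gradients, seed=5)
        for _ in range(100):
            step_crypt(a)
            step_crypt(b)
        assert np.array_equal(a.grid, b.grid)
        assert np.array_equal(a.lineage, b.lineage)

    def test_copy_isolated_from_original(self, settled_tiny_crypt):
        clone = settled_tiny_crypt.copy()
        step_crypt(settled_tiny_crypt)
        step_crypt(clone)
        assert np.array_equal(settled_tiny_crypt.grid, clone.grid)
        # diverge the copy; original must not follow
        step_crypt(clone, lethality=50.0)
        assert not np.array_equal(settled_tiny_crypt.grid, clone.grid)

    def test_sustained_massive_lethality_extinguishes(self, tiny_geometry, gradients):
        state = init_crypt(tiny_geometry, gradients, seed=2)
        for _ in range(50):
            step_crypt(state)
        for _ in range(200):
            step_crypt(state, lethality=1000.0)
            if state.total_cells() == 0:
                break
        assert state.total_cells() == 0  # extinguished crypt is a legal state
        c = census(state)
        assert c.total == 0 and c.cancer_fraction == 0.0

    def test_homeostasis_tiny_crypt(self, tiny_geometry, gradients):
        state = init_crypt(tiny_geometry, gradients, seed=9)
        totals = []
        for t in range(600):
            step_crypt(state)
            if t >= 100:
                totals.append(state.total_cells())
        assert np.mean(totals) == pytest.approx(
            tiny_geometry.homeostatic_target, rel=0.10
        )


class TestIntroduceMutants:
    def test_first_mutant_at_requested_step(self, reduced_geometry, gradients):
        state = init_crypt(reduced_geometry, gradients, seed=3)
        for _ in range(200):
            step_crypt(state)
        assert state.cancer_cells() == 0
        introduce_mutants(state, "cancer", n_cells=4, position="lower_third")
        assert state.cancer_cells() == 4
        assert state.step_index == 200

    def test_mutants_share_one_lineage(self, settled_tiny_crypt):
        state = settled_tiny_crypt
        introduce_mutants(state, "resistant", n_cells=3, position="lower_third")
        tags = state.lineage[state.grid == 3]
        assert np.unique(tags).size == 1

    def test_empty_region_warns_and_noop(self, tiny_geometry, gradients):
        state = init_crypt(tiny_geometry, gradients, seed=1)
        state.grid[:] = 0
        state.lineage[:] = 0
        with pytest.warns(UserWarning):
            introduce_mutants(state, "cancer")
        assert state.total_cells() == 0

    def test_unknown_phenotype_rejected(self, settled_tiny_crypt):
        with pytest.raises(ValueError):
            introduce_mutants(settled_tiny_crypt, "normal")

    def test_adenoma_forms_untreated(self, reduced_geometry, gradients):
        """A bottom-seeded cancer clone fills the crypt (adenoma) in a
        majority of replicates when left untreated."""
        took_over = 0
        for seed in range(6):
            state = init_crypt(reduced_geometry, gradients, seed=seed)
            for _ in range(200):
                step_crypt(state)
            introduce_mutants(state, "cancer", n_cells=14, position="bottom")
            for _ in range(1300):
                step_crypt(state)
                if state.cancer_fraction() >= 0.8:
                    took_over += 1
                    break
        assert took_over >= 4

    def test_mutants_never_enter_niche(self, reduced_geometry, gradients):
        state = init_crypt(reduced_geometry, gradients, seed=4)
        for _ in range(200):
            step_crypt(state)
        introduce_mutants(state, "cancer", n_cells=14, position="bottom")
        niche_rows = state._row_masks()[0]
        for _ in range(400):
            step_crypt(state)
            assert not ((state.grid[niche_rows, :] == CANCER).any())


class TestCensus:
    def test_counts_sum_to_total(self, settled_tiny_crypt):
        c = census(settled_tiny_crypt)
        assert sum(c.counts.values()) == c.total == settled_tiny_crypt.total_cells()

    def test_all_mutant_crypt_fraction_one(self, settled_tiny_crypt):
        state = settled_tiny_crypt
        state.grid[state.grid > 0] = CANCER
        assert census(state).cancer_fraction == 1.0


class TestCalibration:
    def test_zero_budget_returns_initial(self, tiny_geometry, gradients):
        targets = {
            "quiescent_stem": (5.0, 1.0),
            "proliferating": (27.0, 4.0),
            "differentiated": (15.0, 4.0),
        }
        result = calibrate_gradients(
            targets, search_budget=0, seed=1, geometry=tiny_geometry,
            initial=gradients, sim_steps=120, burn_in=40,
        )
        assert result.params == gradients
        assert result.error >= 0.0

    def test_infeasible_targets_rejected(self, tiny_geometry):
        targets = {"proliferating": (1e6, 1.0)}
        with pytest.raises(CryptConfigError):
            calibrate_gradients(targets, 1, 0, geometry=tiny_geometry)

    def test_recovers_means_of_known_parameters(self, tiny_geometry, gradients):
        """Self-consistency: targets simulated from known parameters are
        reproduced by the calibrated parameters within 5%."""
        from cryptsim.crypt import _compartment_stats

        truth = _compartment_stats(
            tiny_geometry, gradients, steps=250, burn_in=80, seed=123
        )
        result = calibrate_gradients(
            truth, search_budget=6, seed=5, geometry=tiny_geometry,
            sim_steps=250, burn_in=80,
        )
        fitted = _compartment_stats(
            tiny_geometry, result.params, steps=250, burn_in=80, seed=321
        )
        for comp, (target_mean, _) in truth.items():
            assert fitted[comp][0] == pytest.approx(target_mean, rel=0.05)


class TestNeutralDrift:
    def test_monoclonal_conversion_small_crypt(self, tiny_geometry, gradients):
        """A neutral crypt fixes to a single lineage (monoclonal
        conversion by drift) in nearly all replicates."""
        mono = 0
        for seed in range(8):
            state = init_crypt(tiny_geometry, gradients, seed=seed)
            for t in range(4000):
                step_crypt(state)
                if t % 100 == 0:
                    tags = state.lineage[state.grid > 0]
                    if np.unique(tags).size == 1:
                        mono += 1
                        break
        assert mono >= 6
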