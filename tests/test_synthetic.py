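import math

import numpy as np
import pytest
from scipy import ndimage, stats

from hybridrange import (
    DomainError,
    NicheSpec,
    ScenarioDelta,
    StudyDesign,
    apply_scenario,
    make_climate,
    make_study,
    sample_occurrences,
    true_suitability,
)
from hybridrange.grids import DEFAULT_VARIABLES, cells_of
from hybridrange.synthetic import gradient_component

from conftest import make_flat_stack


class TestMakeClimate:
    def test_deterministic_given_seed(self):
        a = make_climate(20, 20, seed=11)
        b = make_climate(20, 20, seed=11)
        assert np.array_equal(a.land_mask, b.land_mask)
        for name in a.layers:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_temperature_gradient_decreases_with_latitude(self):
        # row 0 is northernmost: pre-noise row means must rise southward
        for name in ("BIO5", "BIO6"):
            rows = gradient_component(name, 30, 30).mean(axis=1)
            assert np.all(np.diff(rows) > 0)

    def test_noise_free_stack_equals_gradients_on_land(self):
        stack = make_climate(20, 20, seed=2, noise_scale=0.0)
        grad = gradient_component("BIO5", 20, 20)
        land = stack.land_mask
        np.testing.assert_allclose(stack.layers["BIO5"][land], grad[land])

    def test_layer_variance_positive_over_land(self):
        stack = make_climate(30, 30, seed=4)
        for name, arr in stack.layers.items():
            assert np.nanvar(arr) > 0, name

    def test_land_mask_contiguous_and_in_range(self):
        for seed in (0, 1, 2):
            stack = make_climate(40, 40, seed=seed)
            frac = stack.land_mask.mean()
            assert 0.70 <= frac <= 0.95
            _, n = ndimage.label(stack.land_mask)
            assert n == 1

    def test_rejects_tiny_grids(self):
        with pytest.raises(DomainError):
            make_climate(5, 50)


class TestApplyScenario:
    def test_zero_delta_is_identity(self):
        stack = make_climate(15, 15, seed=0)
        out = apply_scenario(stack, ScenarioDelta({}, label="NOOP"))
        for name in stack.layers:
            np.testing.assert_array_equal(out.layers[name], stack.layers[name])
        assert out.scenario_id == "NOOP"

    def test_additive_shift_exact_and_composes(self):
        stack = make_climate(15, 15, seed=0)
        once = apply_scenario(stack, ScenarioDelta({"BIO5": 2.0}, "P2"))
        land = stack.land_mask
        np.testing.assert_allclose(
            once.layers["BIO5"][land], stack.layers["BIO5"][land] + 2.0
        )
        twice = apply_scenario(
            apply_scenario(stack, ScenarioDelta({"BIO5": 1.0}, "P1")),
            ScenarioDelta({"BIO5": 1.0}, "P2"),
        )
        np.testing.assert_allclose(
            twice.layers["BIO5"][land], once.layers["BIO5"][land]
        )
        assert np.array_equal(once.land_mask, stack.land_mask)

    def test_unknown_layer_rejected(self):
        stack = make_climate(15, 15, seed=0)
        with pytest.raises(DomainError):
            apply_scenario(stack, ScenarioDelta({"BIO99": 1.0}, "X"))


class TestTrueSuitability:
    def _stack(self):
        rng = np.random.default_rng(0)
        return make_flat_stack(
            10, layers={"T": rng.normal(20, 4, (10, 10)), "P": rng.normal(100, 20, (10, 10))}
        )

    def test_kernel_maximum_at_optimum(self):
        stack = self._stack()
        t0 = stack.layers["T"][3, 4]
        p0 = stack.layers["P"][3, 4]
        niche = NicheSpec({"T": t0, "P": p0}, {"T": 2.0, "P": 10.0})
        smap = true_suitability(niche, stack)
        assert smap.values[3, 4] == pytest.approx(1.0)

    def test_one_sigma_displacement(self):
        stack = self._stack()
        t0 = stack.layers["T"][3, 4]
        p0 = stack.layers["P"][3, 4]
        niche = NicheSpec({"T": t0 + 2.0, "P": p0}, {"T": 2.0, "P": 10.0})
        smap = true_suitability(niche, stack)
        assert smap.values[3, 4] == pytest.approx(math.exp(-0.5))

    def test_bounded_by_s_max_and_permutation_invariant(self):
        stack = self._stack()
        n1 = NicheSpec({"T": 20.0, "P": 100.0}, {"T": 2.0, "P": 10.0}, s_max=0.7)
        n2 = NicheSpec({"P": 100.0, "T": 20.0}, {"P": 10.0, "T": 2.0}, s_max=0.7)
        m1 = true_suitability(n1, stack)
        m2 = true_suitability(n2, stack)
        assert np.nanmax(m1.values) <= 0.7 + 1e-12
        np.testing.assert_allclose(m1.values, m2.values)

    def test_missing_variable_rejected(self):
        stack = self._stack()
        with pytest.raises(DomainError):
            true_suitability(NicheSpec({"X": 0.0}, {"X": 1.0}), stack)


class TestSampleOccurrences:
    def test_deterministic_given_seed(self):
        stack = make_climate(20, 20, seed=1)
        frame = stack.land_frame()
        niche = NicheSpec(
            {v: float(frame[v].mean()) for v in DEFAULT_VARIABLES},
            {v: float(frame[v].std()) for v in DEFAULT_VARIABLES},
        )
        a = sample_occurrences(niche, stack, 100, seed=5)
        b = sample_occurrences(niche, stack, 100, seed=5)
        assert a.records.equals(b.records)

    def test_degenerate_support_confines_records(self):
        vals = np.full((10, 10), 1000.0)
        vals[4, 6] = 0.0
        stack = make_flat_stack(10, layers={"T": vals})
        niche = NicheSpec({"T": 0.0}, {"T": 1.0})  # zero suitability off (4,6)
        occ = sample_occurrences(niche, stack, 50, seed=0)
        rows, cols = cells_of(
            occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy(), stack
        )
        assert set(zip(rows, cols)) == {(4, 6)}

    def test_uniform_suitability_gives_uniform_cells(self):
        stack = make_flat_stack(10)  # constant layer -> flat suitability
        niche = NicheSpec({"TEMP": 20.0}, {"TEMP": 5.0})
        occ = sample_occurrences(niche, stack, 10_000, seed=3)
        rows, cols = cells_of(
            occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy(), stack
        )
        counts = np.bincount(rows * 10 + cols, minlength=100)
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3

    def test_zero_suitability_everywhere_rejected(self):
        stack = make_flat_stack(10)
        niche = NicheSpec({"TEMP": 1e6}, {"TEMP": 1.0})
        with pytest.raises(DomainError):
            sample_occurrences(niche, stack, 10, seed=0)


class TestMakeStudy:
    def test_counts_and_bookkeeping(self):
        stack = make_climate(60, 60, seed=9)
        design = StudyDesign(
            n_genera=2, gardens_per_genus=1, congeners_per_genus=2,
            n_occ=60, nrows=60, ncols=60, seed=3, min_range_cells=20,
        )
        study = make_study(design, stack)
        assert len(study.taxa) == 6
        assert set(study.occurrences) == set(study.taxa["species_id"])
        assert set(study.niches) == set(study.truth) == set(study.taxa["species_id"])
        assert (study.taxa.groupby("genus")["group"].nunique() == 2).all()

    def test_warm_bias_shifts_garden_optima(self):
        stack = make_climate(60, 60, seed=9)
        design = StudyDesign(
            n_genera=3, gardens_per_genus=2, congeners_per_genus=3,
            n_occ=60, nrows=60, ncols=60, seed=3, warm_bias=True,
            min_range_cells=20,
        )
        study = make_study(design, stack)
        opt = {
            sp: study.niches[sp].optima["BIO5"] for sp in study.taxa["species_id"]
        }
        gardens = study.taxa[study.taxa.group == "garden"]["species_id"]
        congeners = study.taxa[study.taxa.group == "congener"]["species_id"]
        assert np.mean([opt[s] for s in gardens]) > np.mean(
            [opt[s] for s in congeners]
        )

    def test_truth_ranges_meet_minimum(self):
        stack = make_climate(60, 60, seed=9)
        design = StudyDesign(
            n_genera=2, gardens_per_genus=1, congeners_per_genus=2,
            n_occ=60, nrows=60, ncols=60, seed=3, min_range_cells=30,
        )
        study = make_study(design, stack)
        for sp, tmap in study.truth.items():
            assert np.nansum(tmap.values >= 0.5) >= 30, sp
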