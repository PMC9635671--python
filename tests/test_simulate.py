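"""Simulator: strain collections, lineage dynamics, curve rendering, layouts."""

import numpy as np
import pandas as pd
import pytest

from aletrack import (ConfigError, CurveNoiseConfig, LayoutError, MutationClass,
                      SimulationConfig, build_strain_collection,
                      genotype_doubling_time, make_gradient_field,
                      make_plate_layout, render_growth_curve,
                      simulate_experiment, simulate_serial_transfer)


def one_class_config(phi, rate, **kw):
    defaults = dict(n_strains=3, replicates_per_strain=1, seed=9)
    defaults.update(kw)
    return SimulationConfig(
        mutation_classes=(MutationClass("mut", rate_per_division=rate,
                                        rescue_fraction=phi),), **defaults)


class TestStrainCollection:
    def test_zero_deficit_range_gives_basal_stress_D(self):
        cfg = SimulationConfig(n_strains=3, deficit_range_h=(0.0, 0.0), seed=1)
        s = build_strain_collection(cfg)
        assert np.allclose(s["stress_D_h"], cfg.basal_doubling_time_h)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_strains=200, deficit_range_h=(0.5, 4.0), seed=5)
        pd.testing.assert_frame_equal(build_strain_collection(cfg),
                                      build_strain_collection(cfg))

    def test_uniform_deficit_moments(self):
        cfg = SimulationConfig(n_strains=1000, deficit_range_h=(0.5, 4.0), seed=2)
        d = build_strain_collection(cfg)["deficit_h"].to_numpy()
        se = (4.0 - 0.5) / np.sqrt(12) / np.sqrt(1000)
        assert abs(d.mean() - 2.25) < 3 * se
        # oracle: the sample mean of the drawn values is the reported mean
        assert d.mean() == pytest.approx(np.mean(d))

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(deficit_range_h=(2.0, 1.0))


class TestSerialTransfer:
    def test_no_mutation_null_keeps_D_constant(self):
        cfg = one_class_config(phi=0.9, rate=0.0)
        strain = {"strain_id": "s", "basal_D_h": 2.27, "deficit_h": 3.0}
        traj = simulate_serial_transfer(strain, cfg, rng=0)
        assert np.allclose(traj.effective_D, 2.27 + 3.0, atol=1e-12)
        assert np.allclose(traj.adaptation, 0.0, atol=1e-12)

    def test_full_rescue_limit_reaches_basal(self):
        cfg = one_class_config(phi=1.0, rate=5e-4)  # fixation by cycle ~2
        strain = {"strain_id": "s", "basal_D_h": 2.0, "deficit_h": 3.0}
        traj = simulate_serial_transfer(strain, cfg, rng=0)
        assert traj.effective_D[-1] == pytest.approx(2.0, abs=1e-9)

    def test_partial_rescue_closed_form(self):
        # oracle: D_new = D_basal + (1 - phi) * deficit
        cfg = one_class_config(phi=0.9, rate=5e-4)
        strain = {"strain_id": "s", "basal_D_h": 2.27, "deficit_h": 3.0}
        traj = simulate_serial_transfer(strain, cfg, rng=0)
        assert traj.effective_D[-1] == pytest.approx(2.27 + 0.3, abs=1e-6)

    def test_frequencies_sum_to_one_every_cycle(self, small_config):
        strains = build_strain_collection(small_config)
        traj = simulate_serial_transfer(strains.iloc[0], small_config, rng=3)
        for state in traj.cycles:
            assert state.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_D_never_below_basal_and_nonincreasing_in_expectation(self,
                                                                  small_config):
        strains = build_strain_collection(small_config)
        deltas = []
        for i in range(len(strains)):
            traj = simulate_serial_transfer(strains.iloc[i], small_config, rng=i)
            assert np.all(traj.effective_D >= traj.basal_D - 1e-12)
            deltas.append(np.diff(traj.effective_D).mean())
        assert np.mean(deltas) <= 0

    def test_generations_within_log2_size_bounds(self, small_config):
        strains = build_strain_collection(small_config)
        lo = np.log2(2e6 / 5e4)
        hi = np.log2(4e6 / 5e4)
        for i in range(4):
            traj = simulate_serial_transfer(strains.iloc[i], small_config, rng=i)
            # oracle: G per cycle is exactly log2 of the realized size ratio
            for state in traj.cycles:
                assert state.generations == pytest.approx(
                    np.log2(state.final_size / state.start_cells.sum()), abs=1e-9)
                assert lo - 1e-9 <= state.generations <= hi + 1e-9


class TestEffectComposition:
    def test_order_invariance_for_equal_and_unequal_phis(self):
        classes = {
            "a": MutationClass("a", 1e-5, 0.9),
            "b": MutationClass("b", 1e-5, 0.3),
            "c": MutationClass("c", 1e-5, 0.6),
        }
        import itertools
        ds = set()
        for order in itertools.permutations("abc"):
            remaining = 3.0
            for name in order:
                remaining *= 1 - classes[name].rescue_fraction
            ds.add(round(2.27 + remaining, 12))
        assert len(ds) == 1
        assert genotype_doubling_time(2.27, 3.0, frozenset("abc"), classes) \
            == pytest.approx(2.27 + 3.0 * 0.1 * 0.7 * 0.4)


class TestRenderCurve:
    def test_noiseless_single_lineage_log_linear(self, noiseless_curve_config):
        rng = np.random.default_rng(0)
        curve = render_growth_curve(np.array([5e4]), np.array([2.0]), 1e9,
                                    noiseless_curve_config, rng)
        exponential = curve.cells < 1e9  # before the capacity cap
        slopes = (np.diff(np.log2(curve.cells[exponential]))
                  / np.diff(curve.times[exponential]))
        assert len(slopes) > 40
        assert np.allclose(slopes, 0.5, atol=1e-9)

    def test_spike_bookkeeping_matches_generator(self):
        noise = CurveNoiseConfig(spike_probability=0.02,
                                 multiplicative_noise_sd=0.0, lag_h=0.0)
        counts = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            curve = render_growth_curve(np.array([5e4]), np.array([2.0]), 3e6,
                                        noise, rng)
            counts.append(len(curve.spike_indices))
            # injected spikes are exactly the points raised above the signal
            signal = np.minimum(5e4 * 2 ** (curve.times / 2.0), 3e6)
            spiked = np.flatnonzero(curve.cells > signal * 1.01)
            assert np.array_equal(spiked, curve.spike_indices)
        assert np.mean(counts) == pytest.approx(0.02 * noise.n_points, rel=0.35)

    def test_two_lineage_mixture_slope_bracketed(self, noiseless_curve_config):
        rng = np.random.default_rng(0)
        curve = render_growth_curve(np.array([2.5e4, 2.5e4]),
                                    np.array([2.0, 4.0]), 1e12,
                                    noiseless_curve_config, rng)
        early = slice(0, 30)
        slopes = np.diff(np.log2(curve.cells[early])) / np.diff(curve.times[early])
        assert np.all(slopes > 0.25) and np.all(slopes < 0.5)

    def test_saturation_at_carrying_capacity(self, noiseless_curve_config):
        rng = np.random.default_rng(0)
        curve = render_growth_curve(np.array([5e4]), np.array([1.0]), 2e6,
                                    noiseless_curve_config, rng)
        assert curve.cells.max() == pytest.approx(2e6)
        assert curve.cells[-1] == pytest.approx(2e6)


class TestLayout:
    def test_1536_plate_has_384_reference_positions(self):
        layout = make_plate_layout(32, 48, [])
        assert (layout["role"] == "reference").sum() == 384

    def test_zero_gradient_amplitude_is_flat(self):
        g = make_gradient_field(16, 24, 0.0, np.random.default_rng(0))
        assert np.all(g == 0.0)

    def test_gradient_peak_equals_amplitude(self):
        g = make_gradient_field(16, 24, 0.07, np.random.default_rng(1))
        assert np.abs(g).max() == pytest.approx(0.07)

    def test_assignment_bijection_on_subgrid(self):
        # 12 strains x 3 replicates on a 48-position subgrid (8 x 6)
        pops = [(f"s{i}", r) for i in range(12) for r in range(3)]
        layout = make_plate_layout(8, 6, pops)
        strain_pos = layout[layout["role"] == "strain"]
        # exhaustive audit: every population appears exactly once, and only
        # non-reference positions are used
        assigned = set(zip(strain_pos["strain_id"], strain_pos["replicate"]))
        assert assigned == set(pops)
        assert len(strain_pos) == len(pops)
        assert not ((strain_pos["row"] % 2 == 0)
                    & (strain_pos["col"] % 2 == 0)).any()

    def test_capacity_exceeded_raises(self):
        pops = [(f"s{i}", 0) for i in range(37)]  # 48-position grid holds 36
        with pytest.raises(LayoutError):
            make_plate_layout(8, 6, pops)


@pytest.fixture(scope="module")
def tiny_bundle_pair():
    cfg = SimulationConfig(n_strains=4, replicates_per_strain=3,
                           plate_rows=4, plate_cols=6, n_cycles=5, seed=11)
    return simulate_experiment(cfg), simulate_experiment(cfg)


class TestExperimentBundle:

    def test_fixed_seed_gives_identical_bundle(self, tiny_bundle_pair):
        b1, b2 = tiny_bundle_pair
        pd.testing.assert_frame_equal(b1.curves, b2.curves)
        pd.testing.assert_frame_equal(b1.truth, b2.truth)
        pd.testing.assert_frame_equal(b1.layout, b2.layout)

    def test_reference_positions_every_fourth(self, tiny_bundle_pair):
        layout = tiny_bundle_pair[0].layout
        refs = layout[layout["role"] == "reference"]
        assert len(refs) == 4 * 6 // 4
        assert ((refs["row"] % 2 == 0) & (refs["col"] % 2 == 0)).all()

    def test_truth_contains_adaptation_per_cycle(self, tiny_bundle_pair):
        truth = tiny_bundle_pair[0].truth
        evolved = truth[truth["cycle"] >= 1]
        assert evolved["true_adaptation_h"].notna().all()
        # adaptation at cycle 1 is zero by definition
        assert np.allclose(evolved.loc[evolved["cycle"] == 1,
                                       "true_adaptation_h"], 0.0)

    def test_gradient_free_references_identical(self):
        cfg = SimulationConfig(n_strains=2, replicates_per_strain=2,
                               plate_rows=4, plate_cols=4, n_cycles=2,
                               gradient_amplitude_log2=0.0, seed=13,
                               curve_noise=CurveNoiseConfig(
                                   spike_probability=0.0,
                                   multiplicative_noise_sd=0.0))
        bundle = simulate_experiment(cfg)
        refs = bundle.layout[bundle.layout["role"] == "reference"]
        curves = bundle.curves
        # all reference colonies in one cycle share the exact same rendered
        # doubling time when the plate gradient and noise are off
        maxima = []
        for pos in refs.itertuples(index=False):
            sel = curves[(curves["row"] == pos.row) & (curves["col"] == pos.col)
                         & (curves["cycle"] == 1)]
            y = np.log2(sel["cells"].to_numpy())
            t = sel["time_h"].to_numpy()
            maxima.append(np.max(np.diff(y) / np.diff(t)))
        assert np.allclose(maxima, maxima[0], atol=1e-9)
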