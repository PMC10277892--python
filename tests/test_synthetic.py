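import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import strindex as sx
from strindex.errors import InvalidParameterError, ValidationError


def dist_mean(dist):
    return sum(r * w for r, w in dist.items())


class TestExpansionModel:
    def test_zero_rates_give_point_mass(self):
        p = sx.ExpansionModelParams(inherited_repeat=110, months=2.0, n_cells=5000)
        assert sx.simulate_cell_population(p) == {110: 1.0}

    def test_poisson_mean_recovered(self):
        # compound-Poisson limit (every cell competent): mean = 110 + 1.5*2
        p = sx.ExpansionModelParams(
            inherited_repeat=110, expansion_rate=1.5, months=2.0,
            n_cells=100_000, expanding_fraction=1.0, seed=42,
        )
        mean = dist_mean(sx.simulate_cell_population(p))
        se = np.sqrt(3.0 / 100_000)
        assert abs(mean - 113.0) <= 3 * se

    def test_mosaic_true_mean_gain(self):
        p = sx.ExpansionModelParams(
            inherited_repeat=110, expansion_rate=4.0, months=2.0,
            n_cells=200_000, expanding_fraction=0.5, seed=1,
        )
        assert p.true_mean_gain == pytest.approx(4.0)
        mean = dist_mean(sx.simulate_cell_population(p))
        assert mean == pytest.approx(114.0, abs=0.05)

    def test_repeat_floor_at_one(self):
        p = sx.ExpansionModelParams(
            inherited_repeat=2, contraction_rate=5.0, months=2.0,
            n_cells=20_000, expanding_fraction=1.0, seed=3,
        )
        assert min(sx.simulate_cell_population(p)) >= 1

    def test_reproducible_for_fixed_seed(self):
        p = sx.ExpansionModelParams(
            inherited_repeat=110, expansion_rate=2.0, months=2.0, n_cells=5000, seed=9
        )
        assert sx.simulate_cell_population(p) == sx.simulate_cell_population(p)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(inherited_repeat=0),
            dict(inherited_repeat=110, expansion_rate=-1.0),
            dict(inherited_repeat=110, contraction_rate=-0.1),
            dict(inherited_repeat=110, months=-2.0),
            dict(inherited_repeat=110, n_cells=0),
            dict(inherited_repeat=110, expanding_fraction=1.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            sx.ExpansionModelParams(**kwargs)


class TestStutter:
    def test_zero_ratios_identity(self):
        dist = {108: 0.25, 110: 0.75}
        assert sx.apply_stutter(dist, sx.StutterParams(0.0, 0.0, 4)) == dist

    def test_geometric_hand_example(self):
        out = sx.apply_stutter({110: 1.0}, sx.StutterParams(0.2, 0.0, 2))
        assert out[108] == pytest.approx(0.04 / 1.24, abs=1e-12)
        assert out[109] == pytest.approx(0.2 / 1.24, abs=1e-12)
        assert out[110] == pytest.approx(1.0 / 1.24, abs=1e-12)

    def test_ratio_at_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            sx.StutterParams(minus_ratio=1.0)

    @given(
        weights=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=6),
        minus=st.floats(0.0, 0.5),
        plus=st.floats(0.0, 0.3),
        steps=st.integers(0, 4),
    )
    def test_normalization_and_support_widening(self, weights, minus, plus, steps):
        dist = {100 + 2 * i: w for i, w in enumerate(weights)}
        out = sx.apply_stutter(dist, sx.StutterParams(minus, plus, steps))
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)
        assert min(out) >= min(dist) - steps
        assert max(out) <= max(dist) + steps

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValidationError):
            sx.apply_stutter({}, sx.StutterParams())


class TestRender:
    def test_noiseless_point_mass_apex_placement(self, locus):
        rp = sx.TraceRenderParams(size_jitter_sd_bp=0.0, baseline_sd=0.0)
        tr = sx.render_trace({110: 1.0}, locus, rp)
        apex = tr.x[np.argmax(tr.y)]
        assert apex == pytest.approx(locus.flank_bp + 330.0, abs=0.051)
        assert tr.y.max() == pytest.approx(rp.amplitude, rel=1e-6)

    def test_equal_alleles_equal_apexes(self, locus):
        rp = sx.TraceRenderParams(size_jitter_sd_bp=0.0, baseline_sd=0.0)
        tr = sx.render_trace({110: 0.5, 120: 0.5}, locus, rp)
        h1 = tr.y[np.abs(tr.x - locus.size_of(110)) < 1.0].max()
        h2 = tr.y[np.abs(tr.x - locus.size_of(120)) < 1.0].max()
        assert h1 == pytest.approx(h2, rel=1e-3)

    def test_apex_heights_proportional_to_abundance(self, locus):
        rp = sx.TraceRenderParams(size_jitter_sd_bp=0.0, baseline_sd=0.0)
        tr = sx.render_trace({110: 0.25, 115: 0.75}, locus, rp)
        h1 = tr.y[np.abs(tr.x - locus.size_of(110)) < 1.0].max()
        h2 = tr.y[np.abs(tr.x - locus.size_of(115)) < 1.0].max()
        assert h1 / h2 == pytest.approx(1.0 / 3.0, rel=1e-3)

    def test_empty_distribution_rejected(self, locus):
        with pytest.raises(ValidationError):
            sx.render_trace({}, locus)

    def test_round_trip_support_recovery(self, locus):
        p = sx.ExpansionModelParams(
            inherited_repeat=110, expansion_rate=0.75, months=2.0,
            n_cells=400, expanding_fraction=1.0, seed=5,
        )
        dist = sx.simulate_cell_population(p)
        rp = sx.TraceRenderParams(size_jitter_sd_bp=0.0, baseline_sd=0.0)
        tr = sx.render_trace(dist, locus, rp)
        rps = sx.bin_to_repeats(sx.call_peaks(tr, min_height=8, min_prominence=4), locus)
        assert set(rps.heights) == set(dist)


class TestCohort:
    def zero_noise_design(self, seed=0):
        g = sx.GroupSpec(
            label="baseline",
            n_animals=1,
            expansion=sx.ExpansionModelParams(inherited_repeat=110, months=2.0, n_cells=1000),
            stutter=sx.StutterParams(0.0, 0.0, 0),
            render=sx.TraceRenderParams(size_jitter_sd_bp=0.0, baseline_sd=0.0),
        )
        return sx.CohortDesign(groups=(g,), seed=seed)

    def test_minimal_design_point_mass_truth_zero(self):
        peak_sets, truth = sx.simulate_cohort(self.zero_noise_design())
        assert len(peak_sets) == 1
        assert list(peak_sets[0].heights) == [110]
        assert truth.per_group == {"baseline": 0.0}
        assert truth.per_animal.true_gain.tolist() == [0.0]

    def test_zero_rate_zero_noise_cohort_indexes_to_zero(self):
        peak_sets, _ = sx.simulate_cohort(self.zero_noise_design())
        res = sx.instability_index(peak_sets[0])
        assert res.instability_index == 0.0
        assert res.expansion_index == 0.0
        assert res.contraction_index == 0.0

    def test_bit_reproducible_for_fixed_seed(self):
        d = sx.blocked_expansion_design(n_cells=2000, seed=13)
        a, ta = sx.simulate_cohort(d)
        b, tb = sx.simulate_cohort(d)
        assert [s.heights for s in a] == [s.heights for s in b]
        assert ta.per_animal.equals(tb.per_animal)

    def test_seed_changes_output(self):
        a, _ = sx.simulate_cohort(sx.blocked_expansion_design(n_cells=2000, seed=1))
        b, _ = sx.simulate_cohort(sx.blocked_expansion_design(n_cells=2000, seed=2))
        assert [s.heights for s in a] != [s.heights for s in b]

    def test_duplicate_labels_rejected(self):
        g = self.zero_noise_design().groups[0]
        with pytest.raises(InvalidParameterError):
            sx.CohortDesign(groups=(g, g))

    def test_group_labels_carried_on_samples(self):
        d = sx.blocked_expansion_design(n_animals=2, n_cells=1000, seed=4)
        peak_sets, truth = sx.simulate_cohort(d)
        ids = [s.sample_id for s in peak_sets]
        assert ids == truth.per_animal.animal.tolist()
        assert all(i.rsplit("_", 1)[0] in truth.per_group for i in ids)

    def test_traces_output_mode(self):
        d = self.zero_noise_design()
        traces, _ = sx.simulate_cohort(d, output="traces")
        assert isinstance(traces[0], sx.Trace)

    def test_derive_seed_stable_and_distinct(self):
        a = sx.derive_seed(1, "NTC", 0)
        assert a == sx.derive_seed(1, "NTC", 0)
        assert a != sx.derive_seed(1, "NTC", 1)
        assert a != sx.derive_seed(1, "PBS", 0)
        assert 0 <= a < 2**31
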