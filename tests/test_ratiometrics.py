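import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hric import (
    CellTypeProfile,
    FlowSample,
    LogRatioTransform,
    RatioTable,
    Sensor,
    SensorSet,
    SpilloverCompensator,
    SpilloverMatrix,
    compensate,
    count_modes,
    fold_change,
    peak_width,
    per_event_ratios,
    simulate_flow,
    translational_efficiency,
)
from conftest import default_config


def make_sample(events, channels=("FL1", "FL2"), labels=None):
    return FlowSample(list(channels), np.asarray(events, dtype=float), labels=labels)


class TestCompensation:
    def test_identity_matrix_is_noop(self):
        sample = make_sample([[10.0, 20.0], [5.0, 1.0]])
        out = compensate(sample, SpilloverMatrix.identity(2))
        np.testing.assert_allclose(out.events, sample.events)

    def test_hand_solved_two_channel_example(self):
        # S = [[1, .1], [0, 1]]: observed (1.1, 1.0) came from true (1.0, 1.0)
        S = SpilloverMatrix(np.array([[1.0, 0.1], [0.0, 1.0]]))
        out = compensate(make_sample([[1.1, 1.0]]), S)
        np.testing.assert_allclose(out.events, [[1.0, 1.0]], atol=1e-12)

    def test_negative_results_clipped_and_counted(self):
        S = SpilloverMatrix(np.array([[1.0, 0.5], [0.0, 1.0]]))
        out = compensate(make_sample([[0.0, 10.0]]), S)
        assert out.events.min() == 0.0
        assert out.meta["n_clipped"] == 1

    def test_dimension_mismatch_raises(self):
        sample = make_sample([[1.0, 2.0]])
        with pytest.raises(ValueError, match="channels"):
            compensate(sample, SpilloverMatrix.identity(3))

    def test_labels_preserved(self):
        sample = make_sample([[1.0, 2.0]], labels=np.array(["A"], dtype=object))
        out = compensate(sample, SpilloverMatrix.identity(2))
        assert out.labels[0] == "A"

    def test_estimator_round_trips_random_events(self):
        rng = np.random.default_rng(0)
        true = rng.uniform(1, 100, size=(50, 3))
        S = SpilloverMatrix(
            np.array([[1.0, 0.2, 0.05], [0.1, 1.0, 0.1], [0.0, 0.3, 1.0]])
        )
        observed = true @ S.matrix.T
        comp = SpilloverCompensator(S).fit(observed)
        np.testing.assert_allclose(comp.transform(observed), true, rtol=1e-9)


class TestPerEventRatios:
    def test_simple_ratio(self):
        table = per_event_ratios(make_sample([[100.0, 400.0]]), "FL2", "FL1")
        assert table.values()[0] == pytest.approx(4.0)

    def test_zero_denominator_events_excluded(self):
        table = per_event_ratios(make_sample([[0.0, 1.0], [0.0, 2.0]]), "FL2", "FL1")
        assert table.n_events == 0
        assert table.n_excluded == 2

    def test_equal_channels_give_unit_ratio(self):
        table = per_event_ratios(make_sample([[3.0, 3.0], [7.0, 7.0]]), "FL2", "FL1")
        np.testing.assert_allclose(table.values(), 1.0)

    def test_same_channel_twice_rejected(self):
        with pytest.raises(ValueError):
            per_event_ratios(make_sample([[1.0, 2.0]]), "FL1", "FL1")

    def test_log_ratio_transform_preserves_row_count(self):
        X = np.array([[10.0, 20.0], [0.0, 5.0], [4.0, 2.0]])
        t = LogRatioTransform(denominator=0).fit(X)
        out = t.transform(X)
        assert out.shape == (3, 1)
        assert np.isnan(out[1, 0])
        np.testing.assert_allclose(out[[0, 2], 0], [np.log10(2), np.log10(0.5)])


class TestTranslationalEfficiency:
    def test_sample_against_itself_is_one(self):
        rng = np.random.default_rng(1)
        events = rng.uniform(10, 100, size=(200, 2))
        sample = make_sample(events)
        est = translational_efficiency(sample, sample, "FL2", "FL1")
        assert est.value == pytest.approx(1.0)

    def test_recovers_simulated_knockdown(self, control_pair):
        cfg = default_config()
        reporter_sensors = SensorSet(
            [Sensor("FL1"), Sensor("FL2", target="m1")], "FL1"
        )
        profile = CellTypeProfile("A", {"m1": 0.5})
        reporter = simulate_flow([(profile, 1.0)], reporter_sensors, cfg)
        control = simulate_flow([(profile, 1.0)], control_pair, cfg)
        est = translational_efficiency(reporter, control, "FL2", "FL1", seed=5)
        assert abs(est.value - 0.5) < 3 * est.se
        assert est.se < 0.01

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(2)
        rep = make_sample(rng.uniform(10, 100, size=(300, 2)))
        ctl = make_sample(rng.uniform(10, 100, size=(300, 2)))
        base = translational_efficiency(rep, ctl, "FL2", "FL1", seed=3)
        scaled = translational_efficiency(
            make_sample(rep.events * 37.0),
            make_sample(ctl.events * 37.0),
            "FL2",
            "FL1",
            seed=3,
        )
        assert scaled.value == pytest.approx(base.value)

    def test_empty_gated_sample_fails(self):
        sample = make_sample([[0.5, 1.0]])
        with pytest.raises(ValueError, match="gating"):
            translational_efficiency(sample, sample, "FL2", "FL1", gate_min=10.0)

    def test_fold_between_profiles_recovers_activity_difference(self, control_pair):
        """Two lines whose target-miRNA activity differs 1.3-fold."""
        cfg = default_config()
        sensors = SensorSet([Sensor("FL1"), Sensor("FL2", target="m1")], "FL1")
        hela_like = CellTypeProfile("H", {"m1": 0.50})
        mcf_like = CellTypeProfile("M", {"m1": 0.65})
        ests = []
        for profile in (hela_like, mcf_like):
            rep = simulate_flow([(profile, 1.0)], sensors, cfg)
            ctl = simulate_flow([(profile, 1.0)], control_pair, cfg)
            ests.append(
                translational_efficiency(rep, ctl, "FL2", "FL1", seed=7)
            )
        fc = fold_change(ests[0], ests[1])
        assert fc.larger == "b"
        assert abs(fc.fold - 1.3) < 3 * fc.se


class TestFoldChange:
    def test_equal_estimates_give_unit_fold(self):
        from hric import EfficiencyEstimate

        a = EfficiencyEstimate(0.7, 0.01, 100, 100)
        fc = fold_change(a, a)
        assert fc.fold == 1.0
        assert fc.larger == "equal"

    def test_simple_arithmetic(self):
        from hric import EfficiencyEstimate

        a = EfficiencyEstimate(0.6, 0.01, 100, 100)
        b = EfficiencyEstimate(0.9, 0.01, 100, 100)
        fc = fold_change(a, b)
        assert fc.fold == pytest.approx(1.5)
        assert fc.larger == "b"


class TestPeakWidth:
    def test_constant_ratios_have_unit_width(self):
        assert peak_width(np.full(50, 2.5)) == pytest.approx(1.0)

    def test_matches_normal_closed_form(self):
        """log10 R ~ N(0, 0.1536) has a central-95% fold-width of ~4."""
        rng = np.random.default_rng(3)
        ratios = 10.0 ** rng.normal(0.0, 0.1536, 200_000)
        expected = 10.0 ** (2 * 1.96 * 0.1536)  # 3.999
        assert peak_width(ratios) == pytest.approx(expected, rel=0.02)

    def test_brute_force_quantile_oracle(self):
        rng = np.random.default_rng(4)
        ratios = rng.lognormal(0.0, 0.4, 5000)
        lo, hi = np.quantile(ratios, [0.025, 0.975])
        assert peak_width(ratios) == pytest.approx(hi / lo)

    def test_scale_invariance_and_coverage_monotonicity(self):
        rng = np.random.default_rng(5)
        ratios = rng.lognormal(0.0, 0.3, 2000)
        assert peak_width(ratios * 100) == pytest.approx(peak_width(ratios))
        widths = [peak_width(ratios, c) for c in (0.5, 0.8, 0.95, 0.99)]
        assert all(a <= b for a, b in zip(widths, widths[1:]))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="20"):
            peak_width(np.ones(10))


class TestCountModes:
    def test_single_lognormal_population_is_unimodal(self):
        rng = np.random.default_rng(6)
        assert count_modes(rng.lognormal(0, 0.25, 5000)).n_modes == 1

    def test_fourfold_separated_populations_are_bimodal(self):
        """Centers 4-fold apart with narrow peaks: two modes, at the centers."""
        rng = np.random.default_rng(7)
        a = 10.0 ** rng.normal(0.0, 0.11, 5000)
        b = 10.0 ** rng.normal(np.log10(4.0), 0.11, 5000)
        result = count_modes(np.concatenate([a, b]))
        assert result.n_modes == 2
        np.testing.assert_allclose(
            np.sort(np.log10(result.locations)), [0.0, np.log10(4.0)], atol=0.05
        )

    def test_histogram_oracle_agrees_on_separated_mixture(self):
        """Coarse-histogram local maxima find the same two modes as the KDE."""
        rng = np.random.default_rng(8)
        x = np.concatenate(
            [rng.normal(0.0, 0.1, 4000), rng.normal(0.6, 0.1, 4000)]
        )
        counts, _ = np.histogram(x, bins=30)
        interior = counts[1:-1]
        oracle_modes = int(
            np.sum((interior > counts[:-2]) & (interior >= counts[2:]))
        )
        assert count_modes(10.0**x).n_modes == oracle_modes == 2

    def test_degenerate_input_counts_one_mode(self):
        assert count_modes(np.full(100, 3.0)).n_modes == 1

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="50"):
            count_modes(np.ones(10) * 2.0)


@given(st.floats(min_value=0.05, max_value=0.5))
def test_peak_width_closed_form_any_sigma(sigma):
    """Width of an exact log-normal matches 10^(2*1.96*sigma) analytically."""
    from scipy import stats

    n = 20_001
    grid = stats.norm.ppf((np.arange(n) + 0.5) / n, scale=sigma)
    width = peak_width(10.0**grid)
    assert width == pytest.approx(10.0 ** (2 * 1.959964 * sigma), rel=0.005)
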