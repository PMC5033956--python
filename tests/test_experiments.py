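"""Experiment-layer tests: sweeps, classification rules and
depolarization-block region scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ganglion.experiments import (
    BlockBounds,
    BlockNotApplicableError,
    CLASSIFY_TIMING,
    SweepResult,
    UnclassifiableError,
    classify_excitability,
    depolarization_block_bounds,
    excitability_profile,
    fI_curve,
    freq_preference,
    latency_curve,
    periodic_response_cell,
    periodic_response_grid,
)
from ganglion.forcing import StimulusTiming

SHORT = StimulusTiming(t_on=30.0, duration=300.0)


def count_curve(counts, amps=None, duration=500.0):
    counts = np.asarray(counts, dtype=float)
    if amps is None:
        amps = np.arange(len(counts), dtype=float)
    return SweepResult(
        model_id="synthetic",
        measure="spike_count",
        amps=np.asarray(amps, dtype=float),
        values=counts,
        defined=np.ones(len(counts), dtype=bool),
        timing={"duration": duration, "t_on": 50.0},
    )


class TestFICurve:
    def test_zero_amplitude_never_spikes(self, repetitive, ml3):
        for params in (repetitive, ml3):
            curve = fI_curve(params, [0.0], SHORT)
            assert curve.values[0] == 0

    def test_counts_increase_with_drive_for_repetitive(self, repetitive):
        curve = fI_curve(repetitive, [0.0, 2.0, 5.0], SHORT)
        assert curve.values[0] == 0
        assert curve.values[1] > 0
        assert curve.values[2] > curve.values[1]

    def test_amplitude_validation(self, repetitive):
        with pytest.raises(ValueError):
            fI_curve(repetitive, [])
        with pytest.raises(ValueError):
            fI_curve(repetitive, [-1.0])


class TestLatencyCurve:
    def test_undefined_below_threshold_and_shrinking_above(self, repetitive):
        curve = latency_curve(repetitive, [0.0, 1.4, 2.5], SHORT)
        assert not curve.defined[0] and np.isnan(curve.values[0])
        assert curve.defined[1] and curve.defined[2]
        # latency at ~2x onset is shorter than just above onset
        assert curve.values[2] < curve.values[1]


class TestClassification:
    def test_onset_spiking_only_is_class_iii(self):
        call = classify_excitability(count_curve([0, 0, 1, 1, 2, 2]))
        assert call.class_label == "III"
        assert call.max_count == 2

    def test_discontinuous_onset_is_class_ii(self):
        call = classify_excitability(count_curve([0, 0, 25, 40, 60, 70]))
        assert call.class_label == "II"
        assert call.onset_rate_hz == pytest.approx(50.0)  # 25 spikes / 0.5 s

    def test_continuous_onset_is_class_i(self):
        call = classify_excitability(count_curve([0, 1, 3, 10, 30, 50], duration=1000.0))
        assert call.class_label == "I"
        assert call.onset_rate_hz == pytest.approx(3.0)

    def test_single_spike_transient_band_not_mistaken_for_onset(self):
        """One or two onset spikes just above threshold are transients;
        the sustained-firing onset decides the class."""
        call = classify_excitability(count_curve([0, 1, 2, 30, 45, 60]))
        assert call.class_label == "II"
        assert call.onset_amp == 3.0

    def test_entirely_subthreshold_curve_unclassifiable(self):
        with pytest.raises(UnclassifiableError):
            classify_excitability(count_curve([0, 0, 0]))

    def test_requires_count_measure(self):
        curve = count_curve([0, 1, 5])
        curve.measure = "first_spike_latency"
        with pytest.raises(ValueError):
            classify_excitability(curve)

    def test_ml_class_i_profile_stable_across_cutoffs(self, ml1):
        curve, call = excitability_profile(ml1)
        assert call.class_label == "I"
        for cutoff in (5.0, 20.0):
            assert classify_excitability(curve, continuity_cutoff_hz=cutoff).class_label == "I"


def brute_force_block_regions(counts, amps, fraction):
    """Enumeration oracle: all contiguous runs at/above the level, the
    one containing the (first) argmax, then the collapsed amps above."""
    counts = np.asarray(counts, dtype=float)
    level = fraction * counts.max()
    peak = int(np.argmax(counts))
    runs = []
    i = 0
    while i < len(counts):
        if counts[i] >= level:
            j = i
            while j + 1 < len(counts) and counts[j + 1] >= level:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    run = next(r for r in runs if r[0] <= peak <= r[1])
    low_idx = [
        k for k in range(run[1] + 1, len(counts)) if 0 < counts[k] < level
    ]
    low = (amps[low_idx[0]], amps[low_idx[-1]]) if low_idx else None
    return (amps[run[0]], amps[run[1]]), low


class TestBlockBounds:
    def test_synthetic_collapse_curve(self):
        counts = [0, 0, 8, 9, 10, 9, 2, 1]
        curve = count_curve(counts)
        bounds = depolarization_block_bounds(curve, 0.5)
        assert bounds.high == (2.0, 5.0)
        assert bounds.low == (6.0, 7.0)
        oracle = brute_force_block_regions(counts, curve.amps, 0.5)
        assert (bounds.high, bounds.low) == oracle

    def test_monotone_curve_has_no_collapsed_region(self):
        bounds = depolarization_block_bounds(count_curve([0, 1, 4, 8, 10]))
        assert bounds.low is None
        assert bounds.high == (3.0, 4.0)

    def test_all_silent_curve_not_applicable(self):
        with pytest.raises(BlockNotApplicableError):
            depolarization_block_bounds(count_curve([0, 0, 0]))

    def test_fraction_validated(self):
        with pytest.raises(ValueError):
            depolarization_block_bounds(count_curve([0, 1, 5]), fraction=1.5)

    @given(
        counts=st.lists(st.integers(0, 12), min_size=2, max_size=12).filter(
            lambda c: max(c) > 0
        ),
        fraction=st.sampled_from([0.3, 0.5, 0.7]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, counts, fraction):
        curve = count_curve(counts)
        bounds = depolarization_block_bounds(curve, fraction)
        oracle = brute_force_block_regions(counts, curve.amps, fraction)
        assert (bounds.high, bounds.low) == oracle


class TestPeriodicGrid:
    def test_grid_matches_single_cell_evaluation(self, tonic):
        timing = StimulusTiming(t_on=30.0, duration=400.0)
        grid = periodic_response_grid(tonic, [5.0, 10.0], [1.0, 2.0], timing=timing)
        for i, amp in enumerate([1.0, 2.0]):
            for j, f in enumerate([5.0, 10.0]):
                cell = periodic_response_cell(tonic, f, amp, timing=timing)
                assert grid.values[i, j] == cell.value

    def test_zero_amplitude_row_is_silent(self, ml3):
        timing = StimulusTiming(t_on=30.0, duration=400.0)
        rate = periodic_response_grid(ml3, [10.0, 50.0], [0.0], timing=timing)
        assert np.all(rate.values[0] == 0.0)
        lat = periodic_response_grid(
            ml3, [10.0, 50.0], [0.0], measure="first_spike_latency", timing=timing
        )
        assert not lat.defined.any()

    def test_unknown_measure_rejected(self, ml3):
        with pytest.raises(ValueError):
            periodic_response_grid(ml3, [10.0], [1.0], measure="vector_strength")

    def test_rerun_is_deterministic(self, phasic):
        timing = StimulusTiming(t_on=30.0, duration=300.0)
        a = periodic_response_grid(phasic, [10.0, 20.0], [4.0, 6.0], timing=timing)
        b = periodic_response_grid(phasic, [10.0, 20.0], [4.0, 6.0], timing=timing)
        np.testing.assert_array_equal(a.values, b.values)


class TestFreqPreference:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([5, 3, 1], "low"),
            ([1, 5, 1], "interior"),
            ([0, 0, 1], "high"),
            ([0, 1.0, 1.0], "interior"),  # ties resolve to lowest frequency
        ],
    )
    def test_argmax_position(self, row, expected):
        assert freq_preference(np.asarray(row, dtype=float)) == expected

    def test_silent_row_rejected(self):
        with pytest.raises(ValueError):
            freq_preference(np.zeros(4))
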