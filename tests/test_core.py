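"""Spike-train containers, ISI metrics and eligibility gates."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spikepattern import (
    ISISeries,
    InsufficientSpikesError,
    InvalidTrainError,
    SpikeTrain,
    compute_isis,
    cv_isi,
    eligibility,
    firing_rate,
)


class TestSpikeTrain:
    def test_rejects_unsorted_timestamps(self):
        with pytest.raises(InvalidTrainError, match="strictly increasing"):
            SpikeTrain("n", [0.5, 0.2], 1.0)

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(InvalidTrainError, match="duration"):
            SpikeTrain("n", [0.1], 0.0)

    def test_rejects_timestamps_outside_recording(self):
        with pytest.raises(InvalidTrainError, match="within"):
            SpikeTrain("n", [0.1, 2.5], 2.0)


class TestIsis:
    @pytest.mark.parametrize(
        "timestamps, expected",
        [
            ([0.0, 0.5, 1.0], [0.5, 0.5]),
            ([0.0, 0.1, 0.4], [0.1, 0.3]),
        ],
    )
    def test_direct_differencing(self, timestamps, expected):
        isis = compute_isis(SpikeTrain("n", timestamps, 1.0))
        np.testing.assert_allclose(isis.intervals, expected)
        assert isis.n == len(timestamps) - 1

    def test_single_spike_is_an_error(self):
        with pytest.raises(InsufficientSpikesError):
            compute_isis(SpikeTrain("n", [0.2], 1.0))


class TestFiringRate:
    def test_count_over_duration(self):
        ts = np.linspace(0.1, 179.9, 600)
        train = SpikeTrain("n", ts, 180.0)
        assert firing_rate(train) == pytest.approx(600 / 180.0)
        # rate * duration recovers the count exactly
        assert firing_rate(train) * train.duration == train.n_spikes

    def test_sparse_train_fails_rate_gate(self):
        train = SpikeTrain("n", [10.0, 100.0], 180.0)
        assert firing_rate(train) == pytest.approx(2 / 180.0)
        assert not eligibility(train).is_putative_da

    def test_generator_hits_target_rate(self, regular_train):
        # gamma-renewal generator at 3.3 Hz, 300 s
        assert firing_rate(regular_train) == pytest.approx(3.3, abs=0.3)


class TestCvIsi:
    def test_periodic_train_has_zero_cv(self):
        isis = ISISeries(np.full(100, 0.25))
        assert cv_isi(isis) == 0.0

    def test_two_interval_hand_oracle(self):
        # mean 0.2, sample SD sqrt(0.02)/sqrt(1) = 0.141421
        assert cv_isi(ISISeries([0.1, 0.3])) == pytest.approx(70.7107, abs=1e-3)

    def test_exponential_isis_converge_to_100(self):
        rng = np.random.default_rng(1)
        isis = ISISeries(rng.exponential(0.3, size=100_000))
        assert cv_isi(isis) == pytest.approx(100.0, abs=1.0)

    def test_literal_variant_inverts_ratio(self):
        isis = ISISeries([0.1, 0.3])
        assert cv_isi(isis, literal=True) == pytest.approx(100 * 0.2 / 0.1414, rel=1e-3)
        assert cv_isi(ISISeries(np.full(10, 0.5)), literal=True) == np.inf

    def test_insufficient_intervals(self):
        with pytest.raises(InsufficientSpikesError):
            cv_isi(ISISeries([0.5]))

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=10.0), min_size=3, max_size=50),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, intervals, c):
        base = cv_isi(ISISeries(intervals))
        scaled = cv_isi(ISISeries(np.asarray(intervals) * c))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestEligibility:
    def test_good_train_passes_both_gates(self):
        ts = np.linspace(0.1, 199.9, 700)
        m = eligibility(SpikeTrain("n", ts, 200.0))
        assert m.is_putative_da and m.is_classifiable

    def test_too_few_spikes_not_classifiable(self):
        ts = np.linspace(0.1, 199.9, 450)
        m = eligibility(SpikeTrain("n", ts, 200.0))
        assert m.is_putative_da and not m.is_classifiable

    def test_fast_unit_not_putative_da(self):
        ts = np.linspace(0.01, 199.99, 2500)  # 12.5 Hz
        m = eligibility(SpikeTrain("n", ts, 200.0))
        assert not m.is_putative_da and m.is_classifiable

    def test_short_recording_not_classifiable(self):
        ts = np.linspace(0.1, 99.9, 600)
        assert not eligibility(SpikeTrain("n", ts, 100.0)).is_classifiable

    def test_degenerate_train_yields_flags_not_errors(self):
        m = eligibility(SpikeTrain("n", [5.0], 200.0))
        assert not m.is_putative_da and not m.is_classifiable
        assert np.isnan(m.cv_isi)

    def test_adding_spikes_never_revokes_classifiability(self):
        # monotonicity of the spike-count gate
        rng = np.random.default_rng(3)
        base = np.sort(rng.uniform(0, 200, size=520))
        extra = np.sort(np.concatenate([base, rng.uniform(0, 200, size=50) + 1e-4]))
        t1 = SpikeTrain("a", base, 200.0)
        t2 = SpikeTrain("b", np.unique(extra), 200.0)
        assert eligibility(t1).is_classifiable
        assert eligibility(t2).is_classifiable
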