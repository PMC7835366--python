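"""Autocorrelogram construction, feature extraction and classification."""

import numpy as np
import pytest

from spikepattern import (
    AcgConfig,
    AcgFeatures,
    GeneratorSpec,
    InsufficientSpikesError,
    SpikeTrain,
    classify_acg,
    compute_autocorrelogram,
    extract_acg_features,
    generate_train,
)


def brute_force_acg(train, bin_width=0.010, max_lag=2.000):
    """O(n^2) oracle: bin every ordered pair lag in (0, max_lag]."""
    ts = train.timestamps
    lags = np.subtract.outer(ts, ts)
    lags = lags[lags > 0]
    lags = lags[lags <= max_lag]
    n_bins = int(round(max_lag / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.searchsorted(edges, lags, side="left") - 1
    counts = np.zeros(n_bins, dtype=np.int64)
    np.add.at(counts, idx, 1)
    return counts


class TestComputeAutocorrelogram:
    @pytest.mark.parametrize("pattern,seed", [
        ("regular", 0), ("irregular", 1), ("bursty", 2),
    ])
    def test_equals_brute_force_pair_count(self, pattern, seed):
        spec = GeneratorSpec(pattern=pattern, rate=3.0, duration=300.0, seed=seed)
        train = generate_train(spec, min_spikes=600)
        # keep the oracle quadratic cost manageable
        assert train.n_spikes <= 2000
        acg = compute_autocorrelogram(train)
        np.testing.assert_array_equal(acg.counts, brute_force_acg(train))

    def test_total_count_conserves_pairs_within_window(self, periodic_train):
        acg = compute_autocorrelogram(periodic_train)
        ts = periodic_train.timestamps
        lags = np.subtract.outer(ts, ts)
        expected = int(((lags > 0) & (lags <= 2.0)).sum())
        assert int(acg.counts.sum()) == expected

    def test_periodic_train_counts_only_at_period_multiples(self, periodic_train):
        # 2 Hz periodic: lags are exact multiples of 0.5 s -> 4 bins in 2 s
        acg = compute_autocorrelogram(periodic_train)
        nonzero = np.flatnonzero(acg.counts)
        assert nonzero.tolist() == [49, 99, 149, 199]

    def test_poisson_train_is_flat_at_predicted_level(self, poisson_train):
        acg = compute_autocorrelogram(poisson_train)
        rate = poisson_train.n_spikes / poisson_train.duration
        predicted = poisson_train.n_spikes * rate * acg.bin_width
        assert np.mean(acg.counts) == pytest.approx(predicted, rel=0.05)
        # no bin deviates implausibly from the flat level (Poisson noise only)
        z = (acg.counts - predicted) / np.sqrt(predicted)
        assert np.abs(z).max() < 5.0

    def test_refuses_fewer_than_500_spikes(self):
        ts = np.linspace(0.1, 299.9, 400)
        with pytest.raises(InsufficientSpikesError, match="insufficient spikes"):
            compute_autocorrelogram(SpikeTrain("n", ts, 300.0))

    def test_zero_lag_self_pairs_excluded(self):
        ts = np.linspace(0.1, 299.9, 600)
        acg = compute_autocorrelogram(SpikeTrain("n", ts, 300.0))
        # evenly spaced at ~0.5 s: first occupied bin is at the spacing,
        # nothing in bin 0 (which would hold 0-10 ms lags)
        assert acg.counts[0] == 0


class TestFeaturesAndLabels:
    def test_near_periodic_train_shows_three_regular_peaks(self):
        spec = GeneratorSpec(
            pattern="regular", rate=3.0, duration=300.0, shape=1e4, seed=0
        )
        feats = extract_acg_features(compute_autocorrelogram(generate_train(spec)))
        assert feats.n_regular_peaks >= 3
        assert classify_acg(feats) == "regular"

    def test_irregular_train_trough_and_no_peak_run(self, irregular_train):
        feats = extract_acg_features(compute_autocorrelogram(irregular_train))
        assert feats.initial_segment_type == "trough"
        assert feats.n_regular_peaks < 3
        assert classify_acg(feats) == "irregular"

    def test_bursty_train_initial_peak(self, bursty_train):
        feats = extract_acg_features(compute_autocorrelogram(bursty_train))
        assert feats.initial_segment_type == "peak"
        assert classify_acg(feats) == "bursty"

    def test_all_zero_acg_is_a_feature_error(self):
        from spikepattern.acg import Autocorrelogram

        acg = Autocorrelogram(
            bin_width=0.01, max_lag=2.0,
            counts=np.zeros(200, dtype=np.int64), n_reference_spikes=500,
        )
        with pytest.raises(ValueError, match="all-zero"):
            extract_acg_features(acg)

    @pytest.mark.parametrize(
        "n_peaks, segment, fund, expected",
        [
            (3, "trough", 0.3, "regular"),
            (1, "trough", None, "irregular"),
            (0, "peak", None, "bursty"),
            (0, "flat", None, "unclassified"),
        ],
    )
    def test_label_rules_on_synthetic_features(
        self, n_peaks, segment, fund, expected
    ):
        feats = AcgFeatures(
            steady_state=50.0,
            peaks=(),
            initial_segment_type=segment,
            n_regular_peaks=n_peaks,
            fundamental_lag=fund,
        )
        assert classify_acg(feats) == expected

    def test_slow_pacemaker_needs_only_two_visible_peaks(self):
        # a 1.2 Hz pacemaker's third ACG peak would lie beyond max_lag=2 s
        feats = AcgFeatures(
            steady_state=10.0, peaks=(),
            initial_segment_type="trough", n_regular_peaks=2,
            fundamental_lag=0.85,
        )
        assert classify_acg(feats) == "regular"

    def test_label_invariant_under_time_shift(self, regular_train, bursty_train):
        for train in (regular_train, bursty_train):
            before = classify_acg(
                extract_acg_features(compute_autocorrelogram(train))
            )
            after = classify_acg(
                extract_acg_features(compute_autocorrelogram(train.shifted(13.7)))
            )
            assert before == after
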