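"""Synthetic spike-train and cohort generators."""

import numpy as np
import pytest

from spikepattern import (
    BurstParams,
    CohortSpec,
    GeneratorSpec,
    GeneratorSpecError,
    KO_PRESET,
    WT_PRESET,
    allocate_pattern_counts,
    compute_isis,
    cv_isi,
    generate_bursty_train,
    generate_cohort,
    generate_renewal_train,
    generate_train,
)


class TestAllocation:
    @pytest.mark.parametrize(
        "n, mixture, expected",
        [
            (48, (0.42, 0.46, 0.12), [20, 22, 6]),
            (63, (0.66, 0.26, 0.08), [42, 16, 5]),
            (3, (1.0, 0.0, 0.0), [3, 0, 0]),
        ],
    )
    def test_largest_remainder_counts(self, n, mixture, expected):
        assert allocate_pattern_counts(n, mixture) == expected

    @pytest.mark.parametrize("n", [1, 7, 48, 63, 97])
    def test_counts_always_sum_to_n(self, n):
        rng = np.random.default_rng(n)
        p = rng.dirichlet([1, 1, 1])
        assert sum(allocate_pattern_counts(n, p)) == n


class TestRenewalGenerator:
    @pytest.mark.parametrize(
        "shape, duration, expected_cv, tol",
        [
            (1e4, 300.0, 1.0, 1.0),   # near-periodic
            (1.0, 600.0, 100.0, 3.0),  # exponential
            (2.0, 600.0, 70.71, 3.0),
        ],
    )
    def test_cv_matches_analytic_100_over_sqrt_kappa(
        self, shape, duration, expected_cv, tol
    ):
        spec = GeneratorSpec(
            pattern="regular", rate=3.0, duration=duration, shape=shape, seed=11
        )
        cv = cv_isi(compute_isis(generate_renewal_train(spec)))
        assert cv == pytest.approx(expected_cv, abs=tol)

    @pytest.mark.parametrize("shape", [1.0, 2.0, 8.0, 100.0])
    def test_cv_across_shapes(self, shape):
        spec = GeneratorSpec(
            pattern="irregular", rate=3.0, duration=2000.0, shape=shape, seed=5
        )
        cv = cv_isi(compute_isis(generate_renewal_train(spec)))
        expected = 100.0 / np.sqrt(shape)
        # Monte-Carlo tolerance: ~5 relative sigma of the CV estimator
        n = 3.0 * 2000.0
        assert cv == pytest.approx(expected, rel=5 * np.sqrt((1 + 2 / shape) / n) + 0.01)

    def test_same_seed_same_spikes(self):
        spec = GeneratorSpec(pattern="irregular", rate=3.0, duration=300.0, seed=9)
        a = generate_renewal_train(spec)
        b = generate_renewal_train(spec)
        np.testing.assert_array_equal(a.timestamps, b.timestamps)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("pattern", ["regular", "irregular", "bursty"])
    def test_empirical_rate_within_5pct(self, pattern, seed):
        spec = GeneratorSpec(pattern=pattern, rate=4.0, duration=400.0, seed=seed)
        train = generate_train(spec)
        rate = train.n_spikes / train.duration
        assert rate == pytest.approx(4.0, rel=0.05)

    def test_min_spikes_extends_recording(self):
        spec = GeneratorSpec(pattern="irregular", rate=0.5, duration=300.0, seed=2)
        train = generate_train(spec, min_spikes=600)
        assert train.n_spikes >= 600
        assert train.duration > 300.0

    def test_bursty_pattern_rejected_by_renewal_generator(self):
        spec = GeneratorSpec(pattern="bursty", rate=3.0, duration=300.0, seed=0)
        with pytest.raises(GeneratorSpecError):
            generate_renewal_train(spec)


class TestBurstyGenerator:
    def test_cv_exceeds_100(self):
        spec = GeneratorSpec(pattern="bursty", rate=3.5, duration=300.0, seed=3)
        cv = cv_isi(compute_isis(generate_bursty_train(spec)))
        assert cv > 100.0

    def test_single_spike_bursts_rejected(self):
        with pytest.raises(GeneratorSpecError, match="degenerate|>= 2"):
            GeneratorSpec(
                pattern="bursty", rate=3.0, duration=300.0,
                burst=BurstParams(mean_spikes_per_burst=1.0), seed=0,
            )

    def test_infeasible_rate_rejected(self):
        # at 20 Hz the solved pause would not exceed the intra-burst ISI
        with pytest.raises(GeneratorSpecError, match="infeasible"):
            GeneratorSpec(pattern="bursty", rate=20.0, duration=300.0, seed=0)


class TestCohort:
    def test_wt_preset_counts_and_determinism(self):
        import dataclasses

        spec = dataclasses.replace(WT_PRESET, seed=4)
        trains, truth = generate_cohort(spec)
        assert len(trains) == 48
        assert truth["true_pattern"].value_counts().to_dict() == {
            "irregular": 22, "regular": 20, "bursty": 6,
        }
        trains2, truth2 = generate_cohort(spec)
        for a, b in zip(trains, trains2):
            np.testing.assert_array_equal(a.timestamps, b.timestamps)

    def test_ko_preset_counts(self):
        import dataclasses

        trains, truth = generate_cohort(dataclasses.replace(KO_PRESET, seed=4))
        assert len(trains) == 63
        counts = truth["true_pattern"].value_counts().to_dict()
        assert counts == {"regular": 42, "irregular": 16, "bursty": 5}

    def test_all_neurons_meet_spike_floor_and_rate_bounds(self):
        import dataclasses

        trains, truth = generate_cohort(dataclasses.replace(WT_PRESET, seed=8))
        assert all(t.n_spikes >= WT_PRESET.min_spikes for t in trains)
        assert truth["rate_hz"].between(0.5, 10.0).all()

    def test_invalid_mixture_rejected(self):
        with pytest.raises(GeneratorSpecError, match="sum to 1"):
            CohortSpec(group="g", n_neurons=5, mixture=(0.5, 0.4, 0.2))
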