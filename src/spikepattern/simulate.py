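"""Seeded generators for regular, irregular and bursty spike trains and cohorts.

Tonic firing modes (regular and irregular) are modelled as gamma-renewal
processes: ISIs are drawn i.i.d. from a gamma distribution with shape kappa
and mean 1/rate, so the expected CVisi is 100/sqrt(kappa).  Large kappa gives
pacemaker-like regular trains, kappa near 1 gives Poisson-like irregular
trains.

The phasic (bursty) mode alternates bursts -- a geometric number (>= 2) of
spikes separated by short gamma intra-burst ISIs -- with exponential
inter-burst pauses.  The pause mean is solved from the burst parameters so the
long-run rate matches the requested rate.

Cohorts emulate genotype groups: each neuron gets a ground-truth pattern drawn
from a mixture (allocated deterministically by largest-remainder rounding) and
a target rate from a truncated normal.  Per-neuron seeds are spawned from the
cohort seed with :class:`numpy.random.SeedSequence`, so regenerating any single
neuron is independent of cohort order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpikeTrain

__all__ = [
    "BurstParams",
    "GeneratorSpec",
    "CohortSpec",
    "GeneratorSpecError",
    "PATTERNS",
    "REGULAR_SHAPE",
    "IRREGULAR_SHAPE",
    "DEFAULT_BURST",
    "WT_PRESET",
    "KO_PRESET",
    "PRESETS",
    "allocate_pattern_counts",
    "generate_renewal_train",
    "generate_bursty_train",
    "generate_train",
    "generate_cohort",
]

PATTERNS = ("regular", "irregular", "bursty")

#: Default gamma shape for the regular tonic mode (CVisi ~ 100/sqrt(12) ~ 29%).
REGULAR_SHAPE = 12.0
#: Default gamma shape for the irregular tonic mode (CVisi ~ 75%).
IRREGULAR_SHAPE = 1.8


class GeneratorSpecError(ValueError):
    """Raised for invalid or infeasible generator specifications."""


@dataclass(frozen=True)
class BurstParams:
    """Parameters of the burst-pause generative model.

    intra_isi_mean : mean intra-burst ISI (s); short, ~70 ms by default.
    intra_shape : gamma shape of intra-burst ISIs (controls jitter).
    mean_spikes_per_burst : mean of the shifted-geometric burst size (>= 2).
    """

    intra_isi_mean: float = 0.07
    intra_shape: float = 3.0
    mean_spikes_per_burst: float = 4.0

    def validate(self) -> None:
        if self.intra_isi_mean <= 0:
            raise GeneratorSpecError("intra-burst ISI mean must be positive")
        if self.intra_shape <= 0:
            raise GeneratorSpecError("intra-burst gamma shape must be positive")
        if self.mean_spikes_per_burst < 2:
            raise GeneratorSpecError(
                "mean spikes per burst must be >= 2; bursts of a single spike "
                "degenerate to a renewal process"
            )

    def pause_mean(self, rate: float) -> float:
        """Inter-burst pause mean (s) solving the long-run rate constraint.

        With mean burst size B and intra-burst ISI mean d, one cycle holds B
        spikes in expected time (B-1) d + pause, so
        ``pause = B/rate - (B-1) d``.
        """
        b = self.mean_spikes_per_burst
        pause = b / rate - (b - 1.0) * self.intra_isi_mean
        if pause <= self.intra_isi_mean:
            raise GeneratorSpecError(
                f"rate {rate} Hz is infeasible for burst parameters {self}: "
                f"solved pause mean {pause:.4f}s does not exceed the "
                f"intra-burst ISI mean {self.intra_isi_mean}s"
            )
        return pause


DEFAULT_BURST = BurstParams()


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of one synthetic spike train."""

    pattern: str
    rate: float
    duration: float = 300.0
    shape: Optional[float] = None
    burst: Optional[BurstParams] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise GeneratorSpecError(f"unknown pattern {self.pattern!r}")
        if not (0 < self.rate <= 20):
            raise GeneratorSpecError(f"rate must be in (0, 20] Hz, got {self.rate}")
        if self.duration < 180:
            raise GeneratorSpecError(
                f"duration must be >= 180 s, got {self.duration}"
            )
        if self.pattern in ("regular", "irregular"):
            shape = self.shape
            if shape is None:
                shape = REGULAR_SHAPE if self.pattern == "regular" else IRREGULAR_SHAPE
                object.__setattr__(self, "shape", shape)
            if shape <= 0:
                raise GeneratorSpecError(f"gamma shape must be positive, got {shape}")
        else:
            burst = self.burst if self.burst is not None else DEFAULT_BURST
            burst.validate()
            burst.pause_mean(self.rate)  # feasibility check
            object.__setattr__(self, "burst", burst)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one genotype cohort of synthetic neurons.

    ``mixture`` maps pattern -> proportion (summing to 1); integer pattern
    counts are allocated by largest-remainder rounding, so the realized counts
    are deterministic given the spec.  ``min_spikes`` extends individual
    recordings past ``duration`` when a slow neuron would otherwise fall short
    of the spike floor needed for classification.
    """

    group: str
    n_neurons: int
    mixture: Tuple[float, float, float]  # (regular, irregular, bursty)
    rate_mean: float = 3.3
    rate_sd: float = 1.4
    rate_bounds: Tuple[float, float] = (0.5, 10.0)
    duration: float = 300.0
    min_spikes: int = 600
    regular_shape: float = REGULAR_SHAPE
    irregular_shape: float = IRREGULAR_SHAPE
    burst: BurstParams = field(default_factory=BurstParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise GeneratorSpecError("n_neurons must be >= 1")
        mix = tuple(float(p) for p in self.mixture)
        if len(mix) != 3 or any(p < 0 for p in mix):
            raise GeneratorSpecError("mixture must be 3 non-negative proportions")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise GeneratorSpecError(f"mixture must sum to 1, got {sum(mix)}")
        object.__setattr__(self, "mixture", mix)
        lo, hi = self.rate_bounds
        if not (0 < lo < hi):
            raise GeneratorSpecError("rate bounds must satisfy 0 < lo < hi")


# Genotype presets.  Cohort sizes and the regular/irregular percentages follow
# the recorded wild-type (48 neurons) and Sorcs2-null (63 neurons) VTA cohorts;
# the bursty share is the complement of the two printed percentages.  Rate SDs
# give a standard error of ~0.2 Hz at the cohort size.
WT_PRESET = CohortSpec(
    group="Wt",
    n_neurons=48,
    mixture=(0.42, 0.46, 0.12),
    rate_mean=3.3,
    rate_sd=0.2 * math.sqrt(48),
)
KO_PRESET = CohortSpec(
    group="KO",
    n_neurons=63,
    mixture=(0.66, 0.26, 0.08),
    rate_mean=3.6,
    rate_sd=0.2 * math.sqrt(63),
)
PRESETS: Dict[str, CohortSpec] = {"wt": WT_PRESET, "ko": KO_PRESET}


def allocate_pattern_counts(n: int, mixture: Sequence[float]) -> List[int]:
    """Largest-remainder allocation of ``n`` neurons to mixture proportions.

    Floors the exact quotas, then hands remaining units to the largest
    fractional parts (ties broken by position).  Deterministic; counts sum to
    ``n`` exactly.
    """
    quotas = [n * p for p in mixture]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _accumulate_isis(
    draw, duration: float, rate: float, min_spikes: int
) -> Tuple[np.ndarray, float]:
    """Accumulate ISI draws into timestamps covering ``duration``.

    ``draw(k)`` must return ``k`` i.i.d. ISIs.  Returns (timestamps,
    effective_duration): if fewer than ``min_spikes`` fall inside ``duration``,
    the recording is extended to the ``min_spikes``-th spike.
    """
    chunks: List[np.ndarray] = []
    total = 0.0
    count = 0
    while total <= duration or count < min_spikes:
        k = max(64, int(rate * duration * 0.25) + 1)
        block = np.cumsum(draw(k)) + total
        chunks.append(block)
        total = float(block[-1])
        count += block.size
    ts = np.concatenate(chunks)
    inside = int(np.searchsorted(ts, duration, side="right"))
    if inside >= min_spikes:
        return ts[:inside], duration
    ts = ts[:min_spikes]
    return ts, float(ts[-1])


def generate_renewal_train(
    spec: GeneratorSpec, neuron_id: str = "n0", group: Optional[str] = None,
    min_spikes: int = 0,
) -> SpikeTrain:
    """Simulate a gamma-renewal (tonic) spike train from ``spec``.

    ISIs ~ Gamma(shape, scale) with scale = 1/(rate * shape), so mean ISI is
    1/rate and expected CVisi is 100/sqrt(shape).
    """
    if spec.pattern not in ("regular", "irregular"):
        raise GeneratorSpecError(
            f"generate_renewal_train requires a tonic pattern, got {spec.pattern!r}"
        )
    rng = np.random.default_rng(spec.seed)
    scale = 1.0 / (spec.rate * spec.shape)

    def draw(k: int) -> np.ndarray:
        return rng.gamma(spec.shape, scale, size=k)

    ts, dur = _accumulate_isis(draw, spec.duration, spec.rate, min_spikes)
    return SpikeTrain(neuron_id, ts, dur, group)


def generate_bursty_train(
    spec: GeneratorSpec, neuron_id: str = "n0", group: Optional[str] = None,
    min_spikes: int = 0,
) -> SpikeTrain:
    """Simulate a burst-pause (phasic) spike train from ``spec``.

    Bursts hold ``2 + Geometric`` spikes with gamma intra-burst ISIs; pauses
    are exponential with mean solved so the long-run rate matches
    ``spec.rate``.
    """
    if spec.pattern != "bursty":
        raise GeneratorSpecError(
            f"generate_bursty_train requires pattern 'bursty', got {spec.pattern!r}"
        )
    rng = np.random.default_rng(spec.seed)
    burst = spec.burst
    pause_mean = burst.pause_mean(spec.rate)
    # geometric extra spikes beyond the minimum burst size of 2
    p_extra = 1.0 / (burst.mean_spikes_per_burst - 1.0)
    intra_scale = burst.intra_isi_mean / burst.intra_shape

    def draw(k: int) -> np.ndarray:
        # emit ISIs burst by burst until at least k are available
        out: List[np.ndarray] = []
        n = 0
        while n < k:
            size = 1 + rng.geometric(p_extra)
            intra = rng.gamma(burst.intra_shape, intra_scale, size=size - 1)
            pause = rng.exponential(pause_mean)
            isis = np.concatenate([[pause], intra])
            out.append(isis)
            n += isis.size
        return np.concatenate(out)

    ts, dur = _accumulate_isis(draw, spec.duration, spec.rate, min_spikes)
    return SpikeTrain(neuron_id, ts, dur, group)


def generate_train(
    spec: GeneratorSpec, neuron_id: str = "n0", group: Optional[str] = None,
    min_spikes: int = 0,
) -> SpikeTrain:
    """Dispatch to the renewal or bursty generator by ``spec.pattern``."""
    if spec.pattern == "bursty":
        return generate_bursty_train(spec, neuron_id, group, min_spikes)
    return generate_renewal_train(spec, neuron_id, group, min_spikes)


def _truncnorm_rate(rng: np.random.Generator, spec: CohortSpec) -> float:
    lo, hi = spec.rate_bounds
    a = (lo - spec.rate_mean) / spec.rate_sd
    b = (hi - spec.rate_mean) / spec.rate_sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    return float(spec.rate_mean + spec.rate_sd * stats.norm.ppf(u))


def generate_cohort(spec: CohortSpec) -> Tuple[List[SpikeTrain], pd.DataFrame]:
    """Generate a full cohort and its ground-truth table.

    Pattern counts are allocated by largest-remainder rounding of the mixture;
    neuron order interleaves nothing -- neurons 0..k-1 are regular, then
    irregular, then bursty -- but every per-neuron seed is spawned from the
    cohort seed by index, so any single train can be regenerated in isolation.

    Returns
    -------
    trains : list of SpikeTrain
    ground_truth : pandas.DataFrame
        One row per neuron: neuron_id, group, true_pattern, rate, duration,
        shape/burst parameters, seed entropy.
    """
    counts = allocate_pattern_counts(spec.n_neurons, spec.mixture)
    patterns = [p for p, c in zip(PATTERNS, counts) for _ in range(c)]
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_neurons)
    trains: List[SpikeTrain] = []
    records = []
    for i, (pattern, child) in enumerate(zip(patterns, children)):
        rng = np.random.default_rng(child)
        rate = _truncnorm_rate(rng, spec)
        # a fresh stream (spawn) for the train itself keeps the rate draw
        # from perturbing the ISI sequence
        train_seed = child.spawn(1)[0]
        neuron_id = f"{spec.group}-{i:03d}"
        if pattern == "bursty":
            gspec = GeneratorSpec(
                pattern="bursty", rate=rate, duration=spec.duration,
                burst=spec.burst, seed=0,
            )
            gspec = replace(gspec, seed=0)
            train = _generate_with_seedseq(gspec, train_seed, neuron_id, spec)
            shape = float("nan")
        else:
            shape = spec.regular_shape if pattern == "regular" else spec.irregular_shape
            gspec = GeneratorSpec(
                pattern=pattern, rate=rate, duration=spec.duration,
                shape=shape, seed=0,
            )
            train = _generate_with_seedseq(gspec, train_seed, neuron_id, spec)
        trains.append(train)
        records.append(
            {
                "neuron_id": neuron_id,
                "group": spec.group,
                "true_pattern": pattern,
                "rate_hz": rate,
                "duration_s": train.duration,
                "n_spikes": train.n_spikes,
                "gamma_shape": shape,
            }
        )
    return trains, pd.DataFrame.from_records(records)


def _generate_with_seedseq(
    gspec: GeneratorSpec, seedseq: np.random.SeedSequence,
    neuron_id: str, cohort: CohortSpec,
) -> SpikeTrain:
    """Run a generator with an explicit SeedSequence (cohort plumbing)."""
    rng_seed = int(seedseq.generate_state(1, dtype=np.uint32)[0])
    gspec = replace(gspec, seed=rng_seed)
    return generate_train(
        gspec, neuron_id=neuron_id, group=cohort.group, min_spikes=cohort.min_spikes
    )
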