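"""Spike-train domain types and scalar regularity metrics.

The atomic observation is a single neuron's spike timestamp series together
with the recording duration.  From it we derive the interspike-interval (ISI)
series, the mean firing rate, and the coefficient of variation of the ISI
(CVisi, in percent) -- the standard scalar index of spiking regularity for
midbrain dopaminergic neurons (low CVisi = pacemaker-like regular firing).

Eligibility gates mirror standard in vivo single-unit practice for putative
dopaminergic units: a slow firing rate in [0.5, 10] Hz, and, for firing-pattern
classification, at least 500 consecutive spikes from a recording of at least
three minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "ISISeries",
    "NeuronMetrics",
    "InvalidTrainError",
    "InsufficientSpikesError",
    "compute_isis",
    "firing_rate",
    "cv_isi",
    "eligibility",
    "RATE_RANGE_HZ",
    "MIN_SPIKES_FOR_CLASSIFICATION",
    "MIN_DURATION_S",
]

#: Putative-dopaminergic firing-rate gate (Hz), inclusive.
RATE_RANGE_HZ = (0.5, 10.0)
#: Minimum consecutive spikes required for pattern classification.
MIN_SPIKES_FOR_CLASSIFICATION = 500
#: Minimum recording duration (s); three minutes.
MIN_DURATION_S = 180.0


class InvalidTrainError(ValueError):
    """Raised for structurally invalid spike trains (bad duration, unsorted times)."""


class InsufficientSpikesError(ValueError):
    """Raised when an operation needs more spikes than the train provides."""


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered spike timestamp series for one neuron.

    Parameters
    ----------
    neuron_id : str
        Opaque identifier.
    timestamps : array-like of float
        Spike times in seconds, strictly increasing, all within
        ``[0, duration]``.
    duration : float
        Recording duration in seconds, ``> 0``.
    group : str, optional
        Cohort/genotype label (e.g. ``"Wt"``, ``"KO"``).
    """

    neuron_id: str
    timestamps: np.ndarray
    duration: float
    group: Optional[str] = None

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.float64)
        if ts.ndim != 1:
            raise InvalidTrainError("timestamps must be one-dimensional")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise InvalidTrainError(f"duration must be positive, got {self.duration}")
        if ts.size:
            if not np.all(np.isfinite(ts)):
                raise InvalidTrainError("timestamps must be finite")
            if np.any(np.diff(ts) <= 0):
                bad = int(np.flatnonzero(np.diff(ts) <= 0)[0]) + 1
                raise InvalidTrainError(
                    f"timestamps must be strictly increasing (violation at index {bad})"
                )
            if ts[0] < 0 or ts[-1] > self.duration:
                raise InvalidTrainError(
                    "timestamps must lie within [0, duration]; "
                    f"got range [{ts[0]}, {ts[-1]}] with duration {self.duration}"
                )
        object.__setattr__(self, "timestamps", ts)

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    def shifted(self, offset: float) -> "SpikeTrain":
        """Return a copy with all timestamps shifted by ``offset`` seconds.

        The duration is extended as needed so the invariants still hold;
        classification is invariant under this operation.
        """
        ts = self.timestamps + offset
        if ts.size and ts[0] < 0:
            raise InvalidTrainError("shift would produce negative timestamps")
        dur = max(self.duration, float(ts[-1]) if ts.size else self.duration)
        return SpikeTrain(self.neuron_id, ts, dur, self.group)


@dataclass(frozen=True)
class ISISeries:
    """Interspike intervals (seconds) of one spike train."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.float64)
        if iv.size and np.any(iv <= 0):
            raise InvalidTrainError("all interspike intervals must be positive")
        object.__setattr__(self, "intervals", iv)

    @property
    def n(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class NeuronMetrics:
    """Per-neuron scalar metrics and eligibility flags.

    ``cv_isi`` is in percent (100 x SD/mean of the ISI).  ``is_putative_da``
    applies the slow-firing gate; ``is_classifiable`` additionally requires
    enough spikes and recording length for pattern classification.
    """

    neuron_id: str
    firing_rate: float
    mean_isi: float
    sd_isi: float
    cv_isi: float
    n_spikes: int
    duration: float
    is_putative_da: bool
    is_classifiable: bool
    group: Optional[str] = None


def compute_isis(train: SpikeTrain) -> ISISeries:
    """Difference consecutive timestamps into an ISI series.

    Raises
    ------
    InsufficientSpikesError
        If the train has fewer than 2 spikes.
    """
    if train.n_spikes < 2:
        raise InsufficientSpikesError(
            f"insufficient spikes: need >= 2, got {train.n_spikes}"
        )
    return ISISeries(np.diff(train.timestamps))


def firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate in spikes/s, defined as spike count / duration.

    The count-based definition (rather than 1/mean ISI) matches the Hz-gate
    semantics used for putative dopaminergic units.
    """
    return train.n_spikes / train.duration


def cv_isi(isis: ISISeries, literal: bool = False) -> float:
    """Coefficient of variation of the ISI, in percent.

    The conventional definition ``100 x SD(ISI) / mean(ISI)`` is used, with the
    sample (n-1) standard deviation: low values mean regular, pacemaker-like
    firing.  ``literal=True`` returns the inverted ratio ``100 x mean/SD``
    (infinite for a zero-variance train) for auditing against sources that
    state the ratio the other way around.

    Raises
    ------
    InsufficientSpikesError
        If fewer than 2 intervals are available.
    """
    if isis.n < 2:
        raise InsufficientSpikesError(
            f"insufficient intervals: need >= 2, got {isis.n}"
        )
    mean = float(np.mean(isis.intervals))
    sd = float(np.std(isis.intervals, ddof=1))
    if literal:
        return float("inf") if sd == 0.0 else 100.0 * mean / sd
    return 100.0 * sd / mean


def eligibility(
    train: SpikeTrain,
    rate_range: Sequence[float] = RATE_RANGE_HZ,
    min_spikes: int = MIN_SPIKES_FOR_CLASSIFICATION,
    min_duration: float = MIN_DURATION_S,
) -> NeuronMetrics:
    """Compute all scalar metrics and the two inclusion gates for a train.

    Degenerate trains (fewer than 2 spikes) yield NaN ISI statistics and
    ``False`` flags rather than raising.
    """
    rate = firing_rate(train)
    if train.n_spikes >= 3:
        isis = compute_isis(train)
        mean_isi = float(np.mean(isis.intervals))
        sd_isi = float(np.std(isis.intervals, ddof=1))
        cv = cv_isi(isis)
    elif train.n_spikes == 2:
        # a single interval has a mean but no dispersion
        mean_isi = float(train.timestamps[1] - train.timestamps[0])
        sd_isi = cv = float("nan")
    else:
        mean_isi = sd_isi = cv = float("nan")
    lo, hi = rate_range
    return NeuronMetrics(
        neuron_id=train.neuron_id,
        firing_rate=rate,
        mean_isi=mean_isi,
        sd_isi=sd_isi,
        cv_isi=cv,
        n_spikes=train.n_spikes,
        duration=train.duration,
        is_putative_da=bool(lo <= rate <= hi),
        is_classifiable=bool(
            train.n_spikes >= min_spikes and train.duration >= min_duration
        ),
        group=train.group,
    )
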