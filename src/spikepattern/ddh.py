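"""Discharge density histograms and the confirmation classifier built on them.

The recording is tiled with consecutive non-overlapping windows whose length
is set from the mean firing rate so that each window holds ``m`` spikes on
average (window = m / rate; the trailing partial window is discarded).  The
discharge density histogram (DDH) is the occupancy of the per-window spike
counts.  A narrow, symmetric histogram of 3-5 occupied count values indicates
regular firing; a wider but still compact histogram (up to six occupied
values, asymmetric or with appreciable tail mass) indicates irregular firing;
six or more occupied values with the maximum occupancy at the lowest count
(quiescent inter-burst windows dominating) indicate bursty firing.

Two quantitative knobs make the rules operational.  A count value is
"occupied" when its occupancy reaches a noise floor (1% of windows by
default).  The regular rule additionally demands that the sub-floor tail --
the summed occupancy of the 1-2 smallest, below-floor bins -- stays under 1%
of the largest bin, and that the occupied bins are mirror-symmetric about the
midpoint of their range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import InsufficientSpikesError, SpikeTrain, MIN_SPIKES_FOR_CLASSIFICATION

__all__ = [
    "DensityHistogram",
    "DdhFeatures",
    "DdhConfig",
    "compute_density_histogram",
    "extract_ddh_features",
    "classify_ddh",
]


@dataclass(frozen=True)
class DdhConfig:
    """Tunable parameters of the DDH classifier."""

    m: float = 2.0                    # target expected spikes per window
    noise_floor: float = 0.01         # occupancy fraction for an "occupied" bin
    tail_vs_largest: float = 0.01     # sub-floor tail mass over largest bin
    symmetry_tolerance: float = 0.20  # |occ(mode+k)-occ(mode-k)| mass over total
    min_occupied_bursty: int = 6
    max_occupied_regular: int = 5
    max_occupied_irregular: int = 6


@dataclass(frozen=True)
class DensityHistogram:
    """Occupancy of per-window spike counts.

    ``occupancy[c]`` is the number of full windows containing exactly ``c``
    spikes; ``occupied_bins`` lists the count values whose occupancy passes
    the noise floor.
    """

    window_duration: float
    m: float
    window_counts: np.ndarray
    occupancy: np.ndarray
    occupied_bins: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.window_counts.size)


@dataclass(frozen=True)
class DdhFeatures:
    """Scalar features of a density histogram."""

    n_occupied: int
    modal_bin: int
    is_symmetric: bool
    smallest_vs_largest: float
    first_bin_is_mode: bool


def compute_density_histogram(
    train: SpikeTrain,
    m: float = 2.0,
    noise_floor: float = 0.01,
    min_spikes: int = MIN_SPIKES_FOR_CLASSIFICATION,
) -> DensityHistogram:
    """Tile the recording and histogram the per-window spike counts.

    Raises
    ------
    InsufficientSpikesError
        If the train has fewer than ``min_spikes`` spikes.
    """
    if train.n_spikes < min_spikes:
        raise InsufficientSpikesError(
            "insufficient spikes for classification: "
            f"need >= {min_spikes}, got {train.n_spikes}"
        )
    rate = train.n_spikes / train.duration
    window = m / rate
    n_windows = int(np.floor(train.duration / window))
    edges = np.arange(n_windows + 1) * window
    counts, _ = np.histogram(train.timestamps, bins=edges)
    occupancy = np.bincount(counts)
    occupied = np.flatnonzero(occupancy >= noise_floor * n_windows)
    return DensityHistogram(
        window_duration=window,
        m=m,
        window_counts=counts.astype(np.int64),
        occupancy=occupancy.astype(np.int64),
        occupied_bins=occupied,
    )


def extract_ddh_features(
    hist: DensityHistogram, config: Optional[DdhConfig] = None
) -> DdhFeatures:
    """Summarize a density histogram into the classifier's decision features."""
    cfg = config or DdhConfig()
    occ = hist.occupancy
    occupied = hist.occupied_bins
    if occupied.size == 0:
        # every bin under the floor: fall back to the raw nonzero support
        occupied = np.flatnonzero(occ)
    modal = int(occupied[np.argmax(occ[occupied])])
    largest = float(occ[modal])

    # sub-floor tail: nonzero count values pruned by the noise floor
    nonzero = np.flatnonzero(occ)
    sub_floor = np.setdiff1d(nonzero, occupied)
    tail = float(occ[sub_floor].sum())
    smallest_vs_largest = tail / largest if largest > 0 else 0.0

    # mirror symmetry of the histogram about the midpoint of the occupied
    # range (mode-centred mirroring would reject legitimately symmetric
    # histograms whose two central bins tie)
    lo, hi = int(occupied.min()), int(occupied.max())
    segment = occ[lo : hi + 1].astype(float)
    total = float(segment.sum())
    asym = float(np.abs(segment - segment[::-1]).sum()) / 2.0
    is_symmetric = bool(asym <= cfg.symmetry_tolerance * total)

    return DdhFeatures(
        n_occupied=int(occupied.size),
        modal_bin=modal,
        is_symmetric=is_symmetric,
        smallest_vs_largest=smallest_vs_largest,
        first_bin_is_mode=bool(modal == int(occupied.min())),
    )


def classify_ddh(
    hist: DensityHistogram, config: Optional[DdhConfig] = None
) -> str:
    """Map a density histogram to a pattern label.

    Bursty is checked before irregular so that a six-bin histogram whose mode
    sits at the lowest occupied count (quiescent windows) is read as bursty.
    """
    cfg = config or DdhConfig()
    f = extract_ddh_features(hist, cfg)
    if f.n_occupied >= cfg.min_occupied_bursty and f.first_bin_is_mode:
        return "bursty"
    if (
        f.n_occupied <= cfg.max_occupied_regular
        and f.is_symmetric
        and f.smallest_vs_largest < cfg.tail_vs_largest
    ):
        return "regular"
    if f.n_occupied <= cfg.max_occupied_irregular:
        return "irregular"
    return "unclassified"
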