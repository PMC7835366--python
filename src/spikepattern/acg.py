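"""Autocorrelogram construction and shape-based firing-pattern classification.

The autocorrelogram (ACG) bins the lags of all ordered spike pairs (10 ms bins
up to 2000 ms by default).  Its shape encodes the firing mode of a slow
dopaminergic unit:

* three or more regularly occurring peaks (at multiples of the mean ISI)
  -> regular / pacemaker-like firing;
* an initial trough rising smoothly to a steady state -> irregular tonic
  firing;
* an initial peak (short intra-burst lags) decaying to the steady state
  -> bursty firing.

These qualitative rules are made operational here with explicit, configurable
thresholds: a smoothed ACG, a steady-state level estimated from the tail, peak
detection with prominence expressed as a fraction of the steady state, and a
greedy search for a run of evenly spaced peaks anchored at a prominent
fundamental peak.  Because the ripple of a gamma-renewal ACG decays
geometrically with harmonic order, the peaks at two and three mean ISIs are
far shallower than the fundamental; the run search therefore accepts follower
peaks at a much lower prominence than it demands of the fundamental.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .core import InsufficientSpikesError, SpikeTrain, MIN_SPIKES_FOR_CLASSIFICATION

__all__ = [
    "Autocorrelogram",
    "AcgFeatures",
    "AcgConfig",
    "compute_autocorrelogram",
    "extract_acg_features",
    "classify_acg",
]


@dataclass(frozen=True)
class AcgConfig:
    """Tunable parameters of the ACG feature extractor and classifier.

    All prominence/level thresholds are fractions of the steady-state count.
    """

    bin_width: float = 0.010          # s
    max_lag: float = 2.000            # s
    smoothing_span: int = 5           # bins, centred moving average
    steady_state_window: Tuple[float, float] = (1.5, 2.0)  # s
    prominence_fundamental: float = 0.30
    fundamental_height: float = 0.25  # fundamental must exceed (1+this) * steady
    prominence_follower: float = 0.02
    spacing_tolerance: float = 0.30   # fraction of the fundamental lag
    min_fundamental_lag: float = 0.08  # s; slow DA units have mean ISI >= 0.1 s
    trough_depth: float = 0.25        # pre-fundamental level must stay below this
    trough_window: Tuple[float, float] = (0.15, 0.60)  # fractions of fundamental lag
    initial_window_bins: Tuple[int, int] = (1, 6)  # [start, stop) bins, skips bin 0
    initial_level_tolerance: float = 0.15
    min_regular_peaks: int = 3


@dataclass(frozen=True)
class Autocorrelogram:
    """Lag-binned ordered spike-pair counts for positive lags.

    Bin ``b`` covers the half-open lag interval ``(b*w, (b+1)*w]`` with
    ``w = bin_width``; the zero-lag self-pairing of each spike is excluded.
    """

    bin_width: float
    max_lag: float
    counts: np.ndarray
    n_reference_spikes: int
    smoothed: Optional[np.ndarray] = None

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def lags(self) -> np.ndarray:
        """Bin centres in seconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class AcgFeatures:
    """Shape features extracted from a smoothed autocorrelogram."""

    steady_state: float
    peaks: Tuple[Tuple[float, float, float], ...]  # (lag, height, prominence)
    initial_segment_type: str  # 'trough' | 'peak' | 'flat'
    n_regular_peaks: int
    fundamental_lag: Optional[float] = None


def compute_autocorrelogram(
    train: SpikeTrain,
    bin_width: float = 0.010,
    max_lag: float = 2.000,
    min_spikes: int = MIN_SPIKES_FOR_CLASSIFICATION,
) -> Autocorrelogram:
    """Bin the lags of all ordered spike pairs up to ``max_lag``.

    Equivalent to the O(n^2) definition: ``counts[b]`` is the number of pairs
    (i, j), j > i, whose lag falls in bin b.  Computed by differencing the
    sorted timestamp array at increasing offsets, which is O(n * rate*max_lag).

    Raises
    ------
    InsufficientSpikesError
        If the train has fewer than ``min_spikes`` spikes (pattern
        classification requires at least 500 consecutive spikes).
    """
    if train.n_spikes < min_spikes:
        raise InsufficientSpikesError(
            "insufficient spikes for classification: "
            f"need >= {min_spikes}, got {train.n_spikes}"
        )
    n_bins = int(round(max_lag / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    ts = train.timestamps
    k = 1
    while k < ts.size:
        lags = ts[k:] - ts[:-k]
        within = lags[lags <= max_lag]
        if within.size == 0:
            break
        idx = np.searchsorted(edges, within, side="left") - 1
        np.add.at(counts, idx, 1)
        k += 1
    return Autocorrelogram(
        bin_width=bin_width,
        max_lag=max_lag,
        counts=counts,
        n_reference_spikes=train.n_spikes,
    )


def _smooth(counts: np.ndarray, span: int) -> np.ndarray:
    """Centred moving average; edges use the available shorter window."""
    if span <= 1:
        return counts.astype(float)
    kernel = np.ones(span)
    num = np.convolve(counts, kernel, mode="same")
    den = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return num / den


def extract_acg_features(
    acg: Autocorrelogram, config: Optional[AcgConfig] = None
) -> AcgFeatures:
    """Extract steady state, peak list, regular-peak run and initial segment.

    Raises
    ------
    ValueError
        If the ACG is all zero (no pairs within ``max_lag``).
    """
    cfg = config or AcgConfig()
    counts = acg.counts.astype(float)
    if not counts.any():
        raise ValueError("cannot extract features from an all-zero autocorrelogram")
    smoothed = _smooth(counts, cfg.smoothing_span)

    lo = int(round(cfg.steady_state_window[0] / acg.bin_width))
    hi = int(round(cfg.steady_state_window[1] / acg.bin_width))
    steady = float(np.mean(counts[lo:hi]))
    if steady <= 0:
        # degenerate tail (e.g. ultra-slow unit); fall back to the global mean
        steady = float(np.mean(counts))

    peak_idx, props = find_peaks(smoothed, prominence=cfg.prominence_follower * steady)
    lags = acg.lags
    peaks = tuple(
        (float(lags[i]), float(smoothed[i]), float(p))
        for i, p in zip(peak_idx, props["prominences"])
    )

    n_regular, fundamental = _regular_peak_run(
        peaks, steady, smoothed, acg.bin_width, cfg
    )

    a, b = cfg.initial_window_bins
    initial = float(np.mean(counts[a:b]))
    tol = cfg.initial_level_tolerance
    if initial > (1.0 + tol) * steady:
        segment = "peak"
    elif initial < (1.0 - tol) * steady:
        segment = "trough"
    else:
        segment = "flat"

    return AcgFeatures(
        steady_state=steady,
        peaks=peaks,
        initial_segment_type=segment,
        n_regular_peaks=n_regular,
        fundamental_lag=fundamental,
    )


def _trough_before(
    lag: float, smoothed: np.ndarray, bin_width: float, steady: float,
    cfg: AcgConfig,
) -> bool:
    """True if the ACG stays deeply suppressed ahead of a candidate period.

    A genuine pacemaker period leaves the ACG nearly empty below ~0.6 of the
    period; an irregular ACG has already risen toward the steady state there.
    Averaging the window integrates many bins, so the cue stays reliable for
    slow, low-count units where single-peak heights are noise-limited.
    """
    a = int(round(cfg.trough_window[0] * lag / bin_width))
    b = int(round(cfg.trough_window[1] * lag / bin_width))
    a = max(a, 1)
    if b <= a:
        return True
    return float(np.mean(smoothed[a:b])) <= cfg.trough_depth * steady


def _regular_peak_run(
    peaks: Tuple[Tuple[float, float, float], ...],
    steady: float,
    smoothed: np.ndarray,
    bin_width: float,
    cfg: AcgConfig,
) -> Tuple[int, Optional[float]]:
    """Longest run of evenly spaced peaks anchored at a prominent fundamental.

    The fundamental must clear three gates relative to the steady state -- a
    prominence gate, an absolute height gate (rejecting noise bumps on the
    rising edge of an irregular ACG, whose prominence is inflated by the deep
    initial trough), and a pre-fundamental trough-depth gate.  Followers need
    only the detection floor ``prominence_follower``: the ripple of a
    gamma-renewal ACG decays geometrically with harmonic order, so the second
    and third peaks are far shallower than the fundamental.  The period
    estimate is refined from the matched peak positions as the run grows.
    Returns (run length, fundamental lag).
    """
    candidates = [
        (lag, h, p)
        for lag, h, p in peaks
        if lag >= cfg.min_fundamental_lag
        and p >= cfg.prominence_fundamental * steady
        and h >= (1.0 + cfg.fundamental_height) * steady
        and _trough_before(lag, smoothed, bin_width, steady, cfg)
    ]
    if not candidates:
        return 0, None
    best_len, best_fund = 0, None
    for fund_lag, _, _ in candidates:
        run = 1
        period = fund_lag
        last = fund_lag
        tol = cfg.spacing_tolerance * fund_lag
        while True:
            target = last + period
            near = [
                (abs(lag - target), lag)
                for lag, _, _ in peaks
                if abs(lag - target) <= tol and lag > last
            ]
            if not near:
                break
            last = min(near)[1]
            run += 1
            period = last / run  # refine the period from the run so far
        if run > best_len:
            best_len, best_fund = run, fund_lag
    return best_len, best_fund


def classify_acg(
    features: AcgFeatures, config: Optional[AcgConfig] = None
) -> str:
    """Map ACG shape features to a pattern label.

    Precedence: the initial-peak cue (bursty) is evaluated first -- short
    intra-burst lags elevate the leading bins only in burst firing, and the
    harmonics of the intra-burst interval can otherwise masquerade as an
    evenly spaced peak run.  Then the regular-peak run, then the initial
    trough (irregular); anything else is 'unclassified'.

    For slow pacemakers whose mean ISI does not fit the required number of
    peak periods inside ``max_lag``, the required run shortens to however
    many periods fit (never below 2): a 1 Hz regular unit can only show two
    ACG peaks below 2 s.
    """
    cfg = config or AcgConfig()
    if features.initial_segment_type == "peak":
        return "bursty"
    if features.fundamental_lag is not None:
        fits = int(cfg.max_lag / features.fundamental_lag)
        required = max(2, min(cfg.min_regular_peaks, fits))
        if features.n_regular_peaks >= required:
            return "regular"
    if features.initial_segment_type == "trough":
        return "irregular"
    return "unclassified"
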