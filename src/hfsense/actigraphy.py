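"""Actigraphy: tri-axial accelerometer samples -> 30-s activity counts -> motion features.

The conversion follows standard smartphone-actigraphy practice: the z-axis is
band-pass filtered (Butterworth, zero-phase) to reject gravity/drift and
out-of-band noise, the per-second maxima of the absolute filtered signal are
summed over 30-second epochs, and descriptive statistics of the resulting
epoch counts within an analysis window form the motion feature set
(act_mean, act_std, act_mode, act_skew, act_kurt, act_comp).

A window in which fewer than 0.1% of its epochs carry data is treated as a
missing motion modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

SECONDS_PER_DAY = 86_400
EPOCH_S = 30.0
EPOCHS_PER_DAY = int(SECONDS_PER_DAY / EPOCH_S)

#: Minimum fraction of present epochs for the motion modality to count as observed.
MIN_COMPLETENESS = 0.001

#: Band-pass corners (Hz) used to isolate volitional movement.
DEFAULT_LOW_HZ = 0.25
DEFAULT_HIGH_HZ = 11.0

MOTION_FEATURE_NAMES = ("act_mean", "act_std", "act_mode", "act_skew", "act_kurt", "act_comp")


@dataclass
class AccelStream:
    """Time-ordered tri-axial accelerometer samples for one participant.

    Timestamps are seconds relative to the study origin (participant-local
    midnight of day 0); values are in g.
    """

    participant_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("x", "y", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class EpochCountSeries:
    """Activity counts on a contiguous 30-s epoch grid aligned to the study origin.

    ``present`` is False for epochs with no underlying samples (data gaps).
    """

    participant_id: str
    epoch_start: np.ndarray
    count: np.ndarray
    present: np.ndarray
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if np.any(self.count < 0):
            raise ValueError("activity counts must be non-negative")

    def __len__(self) -> int:
        return self.epoch_start.size


@dataclass
class MotionFeatures:
    act_mean: float
    act_std: float
    act_mode: float
    act_skew: float
    act_kurt: float
    act_comp: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MOTION_FEATURE_NAMES}


def bandpass_z(
    z: np.ndarray,
    rate_hz: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass of the z channel.

    When the upper corner is at or above 90% of Nyquist the band-pass is
    infeasible and the filter degenerates to a high-pass at ``low_hz`` (the
    achievable part: rejecting gravity and slow drift); a warning is emitted.
    """
    z = np.asarray(z, dtype=float)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    nyquist = rate_hz / 2.0
    if low_hz >= nyquist:
        raise ValueError(f"low corner {low_hz} Hz is at or above Nyquist {nyquist} Hz")
    if z.size == 0:
        return z.copy()
    if high_hz >= 0.9 * nyquist:
        warnings.warn(
            f"upper corner {high_hz} Hz infeasible at {rate_hz} Hz sampling; "
            f"applying high-pass at {low_hz} Hz only",
            stacklevel=2,
        )
        sos = signal.butter(4, low_hz, btype="highpass", fs=rate_hz, output="sos")
    else:
        sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, z)


def compute_activity_counts(
    filtered: np.ndarray,
    rate_hz: float,
    t0: float = 0.0,
    times: np.ndarray | None = None,
    epoch_s: float = EPOCH_S,
    participant_id: str = "",
) -> EpochCountSeries:
    """Per-second maxima of |filtered|, summed per 30-s epoch.

    Seconds and epochs are aligned to the study origin (t = 0). Epochs in the
    covered span without any sample are emitted with count 0 and
    ``present=False``; bins (seconds) without data simply do not contribute.
    """
    filtered = np.abs(np.asarray(filtered, dtype=float))
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if filtered.size == 0:
        return EpochCountSeries(participant_id, np.empty(0), np.empty(0), np.empty(0, bool), epoch_s)
    if times is None:
        times = t0 + np.arange(filtered.size) / rate_hz
    else:
        times = np.asarray(times, dtype=float)
        if times.size != filtered.size:
            raise ValueError("times and filtered must have equal length")

    sec = np.floor(times).astype(np.int64)
    # per-second maxima (times are sorted)
    starts = np.flatnonzero(np.diff(sec)) + 1
    starts = np.concatenate(([0], starts))
    sec_max = np.maximum.reduceat(filtered, starts)
    sec_idx = sec[starts]

    per_epoch = int(round(epoch_s))
    epoch_idx = sec_idx // per_epoch
    first, last = epoch_idx[0], epoch_idx[-1]
    n_epochs = int(last - first + 1)
    counts = np.zeros(n_epochs)
    np.add.at(counts, (epoch_idx - first).astype(np.intp), sec_max)
    present = np.zeros(n_epochs, dtype=bool)
    present[(epoch_idx - first).astype(np.intp)] = True
    epoch_start = (first + np.arange(n_epochs)) * float(per_epoch)
    return EpochCountSeries(participant_id, epoch_start, counts, present, float(per_epoch))


def stream_to_counts(
    stream: AccelStream,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    epoch_s: float = EPOCH_S,
) -> EpochCountSeries:
    """Full conversion: band-pass the z channel, then form epoch counts."""
    filtered = bandpass_z(stream.z, stream.rate_hz, low_hz, high_hz)
    return compute_activity_counts(
        filtered, stream.rate_hz, times=stream.t, epoch_s=epoch_s, participant_id=stream.participant_id
    )


def _window_mask(series: EpochCountSeries, start_s: float, end_s: float) -> np.ndarray:
    return (series.epoch_start >= start_s) & (series.epoch_start < end_s)


def window_completeness(series: EpochCountSeries, start_s: float, end_s: float) -> float:
    """Fraction of the window's epoch slots that carry data.

    Epoch slots outside the recorded span count as absent. Callers treat the
    motion modality as missing when the fraction falls below ``MIN_COMPLETENESS``.
    """
    if end_s <= start_s:
        raise ValueError("window must have positive length")
    n_slots = (end_s - start_s) / series.epoch_s
    mask = _window_mask(series, start_s, end_s)
    n_present = int(np.count_nonzero(series.present[mask]))
    return n_present / n_slots


def motion_features(series: EpochCountSeries, start_s: float, end_s: float) -> MotionFeatures | None:
    """Descriptive statistics of present epoch counts inside the window.

    Returns None (modality missing) when completeness < ``MIN_COMPLETENESS``.
    Moments use the biased (population) skewness/excess-kurtosis convention;
    a constant series has skewness and kurtosis 0 by convention. The mode is
    the most frequent integer-rounded count, smallest value on ties.
    """
    comp = window_completeness(series, start_s, end_s)
    if comp < MIN_COMPLETENESS:
        return None
    mask = _window_mask(series, start_s, end_s) & series.present
    c = series.count[mask]
    mean = float(np.mean(c))
    std = float(np.std(c, ddof=1)) if c.size > 1 else 0.0
    rounded = np.round(c).astype(np.int64)
    values, freq = np.unique(rounded, return_counts=True)
    mode = float(values[np.argmax(freq)])  # unique() is sorted -> ties to smallest
    if np.ptp(c) == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(c))
        kurt = float(stats.kurtosis(c))
    return MotionFeatures(mean, std, mode, skew, kurt, comp)


def build_double_plot_matrix(series: EpochCountSeries) -> np.ndarray:
    """Double-plot actogram matrix: column k stacks days k and k+1 (2x2880 epochs).

    Missing epochs carry NaN so renderers can paint them white. Requires at
    least two days of (possibly gappy) epoch coverage.
    """
    if len(series) == 0:
        raise ValueError("need at least 2 days of epochs")
    day0 = int(series.epoch_start[0] // SECONDS_PER_DAY)
    day_last = int(series.epoch_start[-1] // SECONDS_PER_DAY)
    n_days = day_last - day0 + 1
    if n_days < 2:
        raise ValueError("need at least 2 days of epochs")
    grid = np.full((n_days, EPOCHS_PER_DAY), np.nan)
    day = (series.epoch_start // SECONDS_PER_DAY).astype(int) - day0
    slot = ((series.epoch_start % SECONDS_PER_DAY) // series.epoch_s).astype(int)
    keep = series.present
    grid[day[keep], slot[keep]] = series.count[keep]
    return np.concatenate([grid[:-1], grid[1:]], axis=1).T
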