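"""Event detection and temporal coarse-graining of multichannel recordings.

Continuous signals are standardized per channel, thresholded in units of
standard deviation, and reduced to point events (one per suprathreshold
excursion, at its extremum). Event rasters can then be coarse-grained to
integer multiples k of the base bin width dt, the temporal-scale axis of the
multiscale criticality analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "EventRaster",
    "decimate_recording",
    "detect_events",
    "rebin_raster",
    "rebase_raster",
]


@dataclass(frozen=True)
class Recording:
    """A multichannel continuous recording.

    Parameters
    ----------
    data
        Real-valued array of shape (n_channels, n_samples). Amplitude units
        are arbitrary: event detection standardizes each channel.
    sampling_rate
        Sampling rate in Hz. Must be positive.
    channel_labels
        Optional channel names; defaults to ``ch00, ch01, ...``.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("need at least 2 channels and 2 samples")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains NaN or infinite values")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        labels = self.channel_labels or tuple(
            f"ch{i:02d}" for i in range(data.shape[0])
        )
        if len(labels) != data.shape[0]:
            raise ValueError("channel_labels length does not match data")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(labels))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class EventRaster:
    """Discretized events on a (channels x bins) grid.

    ``events`` is the binary occupancy matrix; ``counts`` retains, per
    channel and bin, the number of base-resolution events that fell into the
    bin, so avalanche sizes stay consistent under coarse-graining (at the
    base scale ``counts == events``).
    """

    events: np.ndarray
    counts: np.ndarray
    bin_width: float
    base_dt: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        events = np.asarray(self.events, dtype=bool)
        counts = np.asarray(self.counts)
        if events.shape != counts.shape:
            raise ValueError("events and counts shapes differ")
        if np.any((counts > 0) != events):
            raise ValueError("counts support must match binary events")
        k = self.bin_width / self.base_dt
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError("bin_width must be a positive integer multiple of base_dt")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "counts", counts)

    @property
    def scale_k(self) -> int:
        """Bin width as an integer multiple of the base dt."""
        return int(round(self.bin_width / self.base_dt))

    @property
    def n_channels(self) -> int:
        return self.events.shape[0]

    @property
    def n_bins(self) -> int:
        return self.events.shape[1]

    @property
    def total_events(self) -> int:
        """Number of base-resolution events in the raster."""
        return int(self.counts.sum())


def decimate_recording(rec: Recording, target_rate: float) -> Recording:
    """Resample a recording to ``target_rate`` with anti-alias filtering.

    Uses polyphase FIR resampling (zero-phase); the rate ratio need not be an
    integer. ``target_rate`` equal to the current rate returns the recording
    unchanged.
    """
    from fractions import Fraction

    from scipy.signal import resample_poly

    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if target_rate > rec.sampling_rate:
        raise ValueError("target_rate exceeds the recording's sampling rate")
    if target_rate == rec.sampling_rate:
        return rec
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    out = resample_poly(
        rec.data, frac.numerator, frac.denominator, axis=1, padtype="line"
    )
    return Recording(out, target_rate, rec.channel_labels)


def detect_events(rec: Recording, threshold: float) -> EventRaster:
    """Threshold a recording into an event raster at the base bin width.

    Each channel is standardized to zero mean and unit standard deviation
    over the whole recording. An excursion is a maximal run of same-sign
    samples with \\|x\\| > threshold; exactly one event is registered per
    excursion, at the sample of largest \\|x\\|. The raster bin width is the
    sample interval 1/sampling_rate.

    A zero-variance channel cannot be standardized; it is flagged with a
    warning and contributes no events.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    data = rec.data
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        bad = [rec.channel_labels[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"zero-variance channels treated as event-free: {bad}")
        sd[flat] = 1.0
    z = (data - mu) / sd
    events = np.zeros(data.shape, dtype=bool)
    for ch in range(rec.n_channels):
        if flat[ch]:
            continue
        for lo, hi in _excursions(z[ch], threshold):
            peak = lo + int(np.argmax(np.abs(z[ch, lo:hi])))
            events[ch, peak] = True
    dt = 1.0 / rec.sampling_rate
    return EventRaster(
        events=events,
        counts=events.astype(np.uint8),
        bin_width=dt,
        base_dt=dt,
        threshold=threshold,
    )


def _excursions(x: np.ndarray, threshold: float) -> np.ndarray:
    """(start, stop) slices of maximal same-sign runs with |x| > threshold."""
    above = np.abs(x) > threshold
    if not above.any():
        return np.empty((0, 2), dtype=int)
    sign = np.signbit(x)
    prev_above = np.roll(above, 1)
    prev_above[0] = False
    prev_sign = np.roll(sign, 1)
    starts = np.flatnonzero(above & (~prev_above | (sign != prev_sign)))
    next_above = np.roll(above, -1)
    next_above[-1] = False
    next_sign = np.roll(sign, -1)
    stops = np.flatnonzero(above & (~next_above | (sign != next_sign))) + 1
    return np.column_stack([starts, stops])


def rebase_raster(raster: EventRaster, k: int) -> EventRaster:
    """Coarse-grain by k and redeclare the result as base resolution.

    Used to re-analyze the same data at a rescaled base bin width (e.g. the
    slope-doubling check when the base dt is doubled): the returned raster
    has ``scale_k == 1`` with ``base_dt`` multiplied by k, so the whole
    scale ladder can be rebuilt on top of it.
    """
    coarse = rebin_raster(raster, k)
    return EventRaster(
        events=coarse.events,
        counts=coarse.counts,
        bin_width=coarse.bin_width,
        base_dt=coarse.bin_width,
        threshold=coarse.threshold,
    )


def rebin_raster(raster: EventRaster, k: int) -> EventRaster:
    """Coarse-grain a base-resolution raster to bin width k*dt.

    Output bins are consecutive non-overlapping windows of k base bins; a
    coarse bin is occupied if the channel had at least one event anywhere in
    the window, while ``counts`` sums the base events so sizes are preserved.
    A trailing window shorter than k is discarded.
    """
    if int(k) != k or k < 1:
        raise ValueError("k must be a positive integer")
    k = int(k)
    if raster.scale_k != 1:
        raise ValueError("rebinning starts from a base-resolution raster")
    if k == 1:
        return raster
    n_out = raster.n_bins // k
    trimmed = raster.counts[:, : n_out * k].reshape(raster.n_channels, n_out, k)
    counts = trimmed.sum(axis=2, dtype=np.int64)
    return EventRaster(
        events=counts > 0,
        counts=counts,
        bin_width=raster.base_dt * k,
        base_dt=raster.base_dt,
        threshold=raster.threshold,
    )
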