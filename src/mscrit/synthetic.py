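"""Ground-truth-annotated synthetic data for the avalanche pipeline.

Three generators: exact discrete power-law samples (oracle for the MLE), a
mean-field branching-process event raster (oracle for sigma and for the
critical size/duration exponents 3/2 and 2), and a continuous rendering
that turns events into brief pulses in Gaussian sensor noise so threshold
detection can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .events import EventRaster, Recording

__all__ = [
    "BranchingConfig",
    "sample_discrete_powerlaw",
    "simulate_branching_raster",
    "render_continuous",
]

# 3-sample biphasic pulse: a dominant lobe followed by a small rebound, so
# thresholding yields exactly one same-sign excursion extremum per event.
PULSE_KERNEL = np.array([1.0, -0.3, 0.05])


@dataclass(frozen=True)
class BranchingConfig:
    """Generative parameters of the synthetic raster.

    branching_ratio is the mean Poisson offspring number per event (the
    ground-truth sigma); drive_rate the expected number of spontaneous new
    cascades seeded per bin across the whole array. noise_std and
    pulse_amplitude (both in units of the sensor-noise standard deviation)
    control the continuous rendering; amplitude 8 against noise 1 keeps
    planted events essentially always above the default 3-std threshold.
    """

    n_channels: int = 64
    n_bins: int = 100_000
    branching_ratio: float = 1.0
    drive_rate: float = 0.02
    seed: int = 0
    noise_std: float = 1.0
    pulse_amplitude: float = 8.0
    base_dt: float = 0.004
    max_active_factor: int = 100

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.branching_ratio < 0:
            raise ValueError("branching_ratio must be non-negative")
        if not self.drive_rate > 0:
            raise ValueError("drive_rate must be positive")


def sample_discrete_powerlaw(
    n: int,
    exponent: float,
    xmin: int,
    xmax: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n i.i.d. samples from P(x) ∝ x^(-exponent) on {xmin..xmax}.

    Exact inverse-CDF sampling on the normalized mass function; the same
    seed always reproduces the same draw.
    """
    if xmin < 1 or xmax < xmin:
        raise ValueError("need 1 <= xmin <= xmax")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    support = np.arange(xmin, xmax + 1)
    logw = -exponent * np.log(support)
    w = np.exp(logw - logw.max())
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return support[np.searchsorted(cdf, rng.random(int(n)), side="left")]


def simulate_branching_raster(
    cfg: BranchingConfig,
) -> tuple[EventRaster, pd.DataFrame]:
    """Simulate a mean-field branching process on a channel x time grid.

    Each active event spawns Poisson(branching_ratio) descendants in the
    next bin, placed on uniformly random channels (no topology); new
    cascades are seeded by Poisson(drive_rate) per bin. Events colliding on
    one channel-bin merge in the binary raster but are all retained in the
    count matrix. A cascade whose active-event total would exceed
    ``max_active_factor * n_channels`` is truncated and flagged.

    Returns the raster and a per-cascade annotation table with the true
    size, duration, start bin and truncation flag.
    """
    rng = np.random.default_rng(cfg.seed)
    C, T = cfg.n_channels, cfg.n_bins
    counts = np.zeros((C, T), dtype=np.uint16)
    seeds = rng.poisson(cfg.drive_rate, T)
    cap = cfg.max_active_factor * C

    active: dict[int, int] = {}  # cascade id -> events in current bin
    size: dict[int, int] = {}
    start: dict[int, int] = {}
    end: dict[int, int] = {}
    truncated: set[int] = set()
    next_id = 0

    for t in range(T):
        for _ in range(seeds[t]):
            active[next_id] = active.get(next_id, 0) + 1
            size[next_id] = 0
            start[next_id] = t
            next_id += 1
        if not active:
            continue
        total = sum(active.values())
        if total > cap:
            truncated.update(active)
        n_events = np.fromiter(active.values(), dtype=np.int64)
        channels = rng.integers(0, C, int(n_events.sum()))
        np.add.at(counts[:, t], channels, 1)
        for cid, m in zip(list(active), n_events):
            size[cid] += int(m)
            end[cid] = t
        if total > cap or t == T - 1:
            active = {}
            continue
        offspring = rng.poisson(cfg.branching_ratio * n_events)
        active = {
            cid: int(k) for cid, k in zip(active, offspring) if k > 0
        }

    annotations = pd.DataFrame(
        {
            "cascade_id": list(size),
            "true_size": [size[c] for c in size],
            "true_duration": [end[c] - start[c] + 1 for c in size],
            "start_bin": [start[c] for c in size],
            "truncated": [c in truncated for c in size],
        }
    )
    raster = EventRaster(
        events=counts > 0,
        counts=counts,
        bin_width=cfg.base_dt,
        base_dt=cfg.base_dt,
        threshold=None,
    )
    return raster, annotations


def render_continuous(raster: EventRaster, cfg: BranchingConfig) -> Recording:
    """Render an event raster into noisy continuous channel signals.

    Every event becomes a 3-sample biphasic pulse of height
    ``pulse_amplitude`` (scaled by the event count when base events merged
    onto one bin) starting at its bin, on top of additive white Gaussian
    noise of ``noise_std``. With the default amplitude/noise/threshold,
    re-detection recovers at least 99% of planted events in their bins.
    """
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    C, T = raster.counts.shape
    signal = rng.normal(0.0, cfg.noise_std, size=(C, T))
    amp = cfg.pulse_amplitude * raster.counts.astype(float)
    for lag, w in enumerate(PULSE_KERNEL):
        if lag == 0:
            signal += w * amp
        else:
            signal[:, lag:] += w * amp[:, :-lag]
    return Recording(signal, sampling_rate=1.0 / raster.base_dt)
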