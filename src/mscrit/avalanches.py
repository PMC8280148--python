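"""Avalanche extraction and primitive avalanche statistics.

An avalanche is a maximal run of consecutive time bins each containing at
least one event on any channel, bounded by empty bins (or the edges of the
record). From the runs we collect sizes (total base events), durations
(bins), inter-avalanche intervals (quiet-bin gaps) and per-bin event-count
profiles, the raw material for all exponent fits, plus the branching
parameter sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AvalancheSet",
    "extract_avalanches",
    "pool_avalanches",
    "branching_parameter",
]


@dataclass(frozen=True)
class AvalancheSet:
    """Avalanches from one raster (or pooled over a threshold grid).

    sizes[i] is the total number of base-resolution events in avalanche i,
    durations[i] its length in bins, bin_profiles[i] the per-bin event
    counts (so ``sizes[i] == bin_profiles[i].sum()`` and
    ``durations[i] == len(bin_profiles[i])``). ``iai`` holds the quiet-bin
    gaps between consecutive avalanches; pooled sets concatenate the gaps of
    their components.
    """

    sizes: np.ndarray
    durations: np.ndarray
    iai: np.ndarray
    bin_profiles: tuple[np.ndarray, ...]
    starts: np.ndarray
    scale_k: int
    threshold: float | None
    n_channels: int
    n_bins: int = 0

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=np.int64)
        durations = np.asarray(self.durations, dtype=np.int64)
        iai = np.asarray(self.iai, dtype=np.int64)
        if not (len(sizes) == len(durations) == len(self.bin_profiles)):
            raise ValueError("sizes, durations and bin_profiles must align")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "iai", iai)
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.sizes)

    @property
    def n_avalanches(self) -> int:
        return len(self.sizes)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-avalanche table (avalanche_id, size, duration, start_bin)."""
        return pd.DataFrame(
            {
                "avalanche_id": np.arange(len(self)),
                "size": self.sizes,
                "duration": self.durations,
                "start_bin": self.starts,
            }
        )

    def iai_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"interval_id": np.arange(len(self.iai)), "iai": self.iai})


def extract_avalanches(
    raster, base_counts: np.ndarray | None = None
) -> AvalancheSet:
    """Split a raster into avalanches at empty (all-channel quiet) bins.

    Parameters
    ----------
    raster
        An :class:`~mscrit.events.EventRaster` at any temporal scale.
    base_counts
        Optional per-bin total base-event counts aligned to the raster bins;
        defaults to the raster's own ``counts`` summed over channels. Sizes
        are computed from these counts, not from binary occupancy, so they
        are consistent across coarse-graining scales.
    """
    occupied = raster.events.any(axis=0)
    if base_counts is None:
        col_counts = raster.counts.sum(axis=0, dtype=np.int64)
    else:
        col_counts = np.asarray(base_counts, dtype=np.int64)
        if col_counts.shape != (raster.n_bins,):
            raise ValueError("base_counts must align with raster bins")
    if not occupied.any():
        return AvalancheSet(
            sizes=np.empty(0, dtype=np.int64),
            durations=np.empty(0, dtype=np.int64),
            iai=np.empty(0, dtype=np.int64),
            bin_profiles=(),
            starts=np.empty(0, dtype=np.int64),
            scale_k=raster.scale_k,
            threshold=raster.threshold,
            n_channels=raster.n_channels,
            n_bins=raster.n_bins,
        )
    padded = np.concatenate([[False], occupied, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    profiles = tuple(col_counts[a:b] for a, b in zip(starts, stops))
    sizes = np.array([p.sum() for p in profiles], dtype=np.int64)
    durations = stops - starts
    iai = starts[1:] - stops[:-1]
    return AvalancheSet(
        sizes=sizes,
        durations=durations,
        iai=iai,
        bin_profiles=profiles,
        starts=starts,
        scale_k=raster.scale_k,
        threshold=raster.threshold,
        n_channels=raster.n_channels,
        n_bins=raster.n_bins,
    )


def pool_avalanches(sets: Sequence[AvalancheSet]) -> AvalancheSet:
    """Pool avalanche sets, e.g. across a threshold grid.

    Pooling concatenates avalanches (and inter-avalanche intervals), which
    averages the empirical distributions with weights proportional to
    avalanche counts — the signal-to-noise averaging used when the same
    record is thresholded at several levels.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("nothing to pool")
    if len({s.scale_k for s in sets}) != 1:
        raise ValueError("can only pool avalanche sets at one temporal scale")
    return AvalancheSet(
        sizes=np.concatenate([s.sizes for s in sets]),
        durations=np.concatenate([s.durations for s in sets]),
        iai=np.concatenate([s.iai for s in sets]),
        bin_profiles=tuple(p for s in sets for p in s.bin_profiles),
        starts=np.concatenate([s.starts for s in sets]),
        scale_k=sets[0].scale_k,
        threshold=None,
        n_channels=sets[0].n_channels,
        n_bins=sum(s.n_bins for s in sets),
    )


def branching_parameter(
    av: AvalancheSet,
    method: str = "first2",
    min_duration: int = 1,
) -> float:
    """Branching parameter sigma of an avalanche set.

    With the default ``method="first2"`` each avalanche contributes the
    ratio of its second-bin to first-bin event count; a duration-1 avalanche
    has no second bin and contributes 0 (it produced no descendants). This
    makes sigma an unbiased gauge of the mean offspring number: sigma = 1
    marks the critical balance between cascade growth and decay.
    ``min_duration=2`` switches to the stricter convention that drops
    duration-1 avalanches altogether. ``method="all"`` averages all
    consecutive-bin ratios instead of only the first pair.

    Returns NaN (with no exception) when no avalanche qualifies.
    """
    if method not in ("first2", "all"):
        raise ValueError("method must be 'first2' or 'all'")
    ratios: list[float] = []
    for prof in av.bin_profiles:
        if len(prof) < min_duration:
            continue
        if len(prof) == 1:
            ratios.append(0.0)
        elif method == "first2":
            ratios.append(prof[1] / prof[0])
        else:
            ratios.extend(prof[1:] / prof[:-1])
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))
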