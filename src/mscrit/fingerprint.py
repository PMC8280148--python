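"""Multiscale criticality (MsCr) fingerprints.

The five criticality parameters (sigma, alpha, tau, gamma, delta) are
tracked across temporal scales k*dt; each parameter's curve is summarized
by the slope and intercept of a straight-line fit against k, each of the 10
unordered parameter pairs by the slope and intercept of one curve regressed
on the other over shared scales. Together with kappa, generalized kappa and
the size-distribution cutoff at the interval's smallest scale this yields
the 33-element MsCr fingerprint of a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .avalanches import extract_avalanches, pool_avalanches
from .events import EventRaster, Recording, decimate_recording, detect_events, rebin_raster
from .powerlaw_fits import ExponentProfile, FitConfig, profile_at_scale

__all__ = [
    "PARAMETERS",
    "PARAMETER_PAIRS",
    "FEATURE_NAMES",
    "FingerprintConfig",
    "ScaleCurve",
    "MsCrFingerprint",
    "scale_profiles",
    "exponent_curves",
    "fit_scale_line",
    "fit_pair_line",
    "mscr_fingerprint",
    "fingerprint_table",
]

PARAMETERS: tuple[str, ...] = ("sigma", "alpha", "tau", "gamma", "delta")
PARAMETER_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(PARAMETERS, 2))

DEFAULT_THRESHOLDS: dict[str, tuple[float, ...]] = {
    "eeg": (2.5, 3.0, 3.5),
    "meg": (3.0, 3.5, 4.0),
}
DEFAULT_INTERVALS: tuple[tuple[int, int], ...] = ((1, 5), (3, 7), (6, 10))


def _feature_names() -> tuple[str, ...]:
    names = []
    for p in PARAMETERS:
        names += [f"a_{p}", f"b_{p}"]
    for p, q in PARAMETER_PAIRS:
        names += [f"a_{p}_{q}", f"b_{p}_{q}"]
    names += ["kappa", "kappa_gen", "cutoff"]
    return tuple(names)


#: Canonical order of the 33 fingerprint features: slope/intercept of the 5
#: single-parameter scale curves, slope/intercept of the 10 pairwise curves,
#: then the three distribution-deviance measures.
FEATURE_NAMES: tuple[str, ...] = _feature_names()
assert len(FEATURE_NAMES) == 33


@dataclass(frozen=True)
class FingerprintConfig:
    """End-to-end analysis settings.

    thresholds defaults by modality: 2.5-3.5 std for EEG-type, 3-4 std for
    MEG-type signals. base_rate is the common analysis rate (Hz) the input
    is decimated to, so the base bin is dt = 1/base_rate (4 ms at 250 Hz).
    Scale curves use k = 1..10; fingerprints are reported for the three
    k-intervals 1-5, 3-7 and 6-10.
    """

    modality: str = "eeg"
    thresholds: tuple[float, ...] | None = None
    base_rate: float = 250.0
    k_max: int = 10
    intervals: tuple[tuple[int, int], ...] = DEFAULT_INTERVALS
    fit: FitConfig = field(default_factory=FitConfig)

    def threshold_grid(self) -> tuple[float, ...]:
        if self.thresholds is not None:
            return self.thresholds
        try:
            return DEFAULT_THRESHOLDS[self.modality]
        except KeyError:
            raise ValueError(f"unknown modality {self.modality!r}") from None


@dataclass(frozen=True)
class ScaleCurve:
    """One parameter's value as a function of temporal scale k."""

    parameter_name: str
    k_values: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.k_values, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if k.shape != v.shape:
            raise ValueError("k_values and values must align")
        if np.any(np.diff(k) <= 0):
            raise ValueError("k_values must be strictly increasing")
        object.__setattr__(self, "k_values", k)
        object.__setattr__(self, "values", v)

    def restrict(self, k_lo: int, k_hi: int) -> "ScaleCurve":
        mask = (self.k_values >= k_lo) & (self.k_values <= k_hi)
        return ScaleCurve(self.parameter_name, self.k_values[mask], self.values[mask])


@dataclass(frozen=True)
class MsCrFingerprint:
    """The 33 named MsCr features of one recording and one scale interval."""

    features: dict[str, float]
    interval: tuple[int, int]
    recording_id: str = ""

    def __post_init__(self) -> None:
        if tuple(self.features) != FEATURE_NAMES:
            raise ValueError("features must be the 33 canonical names in order")

    def to_series(self) -> pd.Series:
        s = pd.Series(self.features, name=self.recording_id or None)
        s.index.name = "feature"
        return s

    @property
    def interval_label(self) -> str:
        return f"{self.interval[0]}-{self.interval[1]}"


def scale_profiles(
    base_rasters: Sequence[EventRaster],
    k_values: Sequence[int],
    fit: FitConfig | None = None,
    deviance_scales: set[int] | None = None,
) -> dict[int, ExponentProfile]:
    """Threshold-pooled exponent profiles at each temporal scale.

    For each k the base-resolution rasters (one per threshold) are
    coarse-grained, their avalanches extracted and pooled, and the pooled
    set fitted. This is the workhorse behind :func:`exponent_curves`; it
    also accepts simulated rasters directly. ``deviance_scales`` restricts
    the (comparatively slow) kappa/cutoff fits to the listed scales; by
    default they run at every scale.
    """
    profiles = {}
    for k in k_values:
        pooled = pool_avalanches(
            [extract_avalanches(rebin_raster(r, k)) for r in base_rasters]
        )
        dev = deviance_scales is None or k in deviance_scales
        profiles[k] = profile_at_scale(pooled, fit, deviance=dev)
    return profiles


def exponent_curves(
    rec: Recording,
    thresholds: Sequence[float],
    k_range: Sequence[int] = range(1, 11),
    fit: FitConfig | None = None,
) -> dict[str, ScaleCurve]:
    """Scale-dependence curves of the five criticality parameters.

    Detects events at each threshold, then for every scale k pools the
    thresholded avalanche sets and fits one exponent profile; returns one
    curve per parameter (missing fits appear as NaN points).
    """
    rasters = [detect_events(rec, t) for t in thresholds]
    profiles = scale_profiles(rasters, list(k_range), fit, deviance_scales=set())
    ks = np.array(sorted(profiles), dtype=int)
    return {
        p: ScaleCurve(p, ks, np.array([getattr(profiles[k], p) for k in ks]))
        for p in PARAMETERS
    }


def fit_scale_line(curve: ScaleCurve) -> tuple[float, float]:
    """Slope and intercept of a parameter's value against scale k.

    Ordinary least squares over the non-missing points, k counted in
    integer multiples of the base bin width; (NaN, NaN) when fewer than two
    points remain.
    """
    mask = np.isfinite(curve.values)
    if mask.sum() < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(curve.k_values[mask], curve.values[mask], 1)
    return float(slope), float(intercept)


def fit_pair_line(x_curve: ScaleCurve, y_curve: ScaleCurve) -> tuple[float, float]:
    """Slope and intercept of one parameter's curve against another's.

    The two curves are matched on shared scales k where both are
    non-missing, and y(k dt) is regressed on x(k dt); the first-listed
    parameter of the canonical pair order is the abscissa.
    """
    shared, ix, iy = np.intersect1d(
        x_curve.k_values, y_curve.k_values, return_indices=True
    )
    x = x_curve.values[ix]
    y = y_curve.values[iy]
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2 or np.ptp(x[mask]) == 0:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(x[mask], y[mask], 1)
    return float(slope), float(intercept)


def fingerprints_from_rasters(
    base_rasters: Sequence[EventRaster],
    config: FingerprintConfig | None = None,
    recording_id: str = "",
) -> list[MsCrFingerprint]:
    """MsCr fingerprints from already-thresholded base-resolution rasters."""
    cfg = config or FingerprintConfig()
    profiles = scale_profiles(
        base_rasters,
        range(1, cfg.k_max + 1),
        cfg.fit,
        deviance_scales={lo for lo, _ in cfg.intervals},
    )
    ks = np.array(sorted(profiles), dtype=int)
    curves = {
        p: ScaleCurve(p, ks, np.array([getattr(profiles[k], p) for k in ks]))
        for p in PARAMETERS
    }
    out = []
    for k_lo, k_hi in cfg.intervals:
        features: dict[str, float] = {}
        local = {p: curves[p].restrict(k_lo, k_hi) for p in PARAMETERS}
        for p in PARAMETERS:
            a, b = fit_scale_line(local[p])
            features[f"a_{p}"] = a
            features[f"b_{p}"] = b
        for p, q in PARAMETER_PAIRS:
            a, b = fit_pair_line(local[p], local[q])
            features[f"a_{p}_{q}"] = a
            features[f"b_{p}_{q}"] = b
        head = profiles[k_lo]
        features["kappa"] = head.kappa
        features["kappa_gen"] = head.kappa_gen
        features["cutoff"] = head.cutoff
        features = {name: features[name] for name in FEATURE_NAMES}
        out.append(MsCrFingerprint(features, (k_lo, k_hi), recording_id))
    return out


def mscr_fingerprint(
    rec: Recording,
    config: FingerprintConfig | None = None,
    recording_id: str = "",
) -> list[MsCrFingerprint]:
    """Full pipeline: recording in, one 33-feature fingerprint per interval.

    The recording is decimated to the base analysis rate, thresholded over
    the modality's std grid, and analyzed across scales k = 1..k_max;
    each configured interval yields its own fingerprint (the first, 1-5, is
    the conventional report). Component failures propagate as NaN features,
    never as silent zeros.
    """
    cfg = config or FingerprintConfig()
    if rec.sampling_rate > cfg.base_rate:
        rec = decimate_recording(rec, cfg.base_rate)
    rasters = [detect_events(rec, t) for t in cfg.threshold_grid()]
    return fingerprints_from_rasters(rasters, cfg, recording_id)


def fingerprint_table(fingerprints: Sequence[MsCrFingerprint]) -> pd.DataFrame:
    """Tidy table, one row per (recording, interval), 33 feature columns."""
    rows = []
    for fp in fingerprints:
        row = {"recording_id": fp.recording_id, "interval": fp.interval_label}
        row.update(fp.features)
        rows.append(row)
    return pd.DataFrame(rows)
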