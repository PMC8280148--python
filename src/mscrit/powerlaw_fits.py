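"""Criticality exponents and power-law deviance at one temporal scale.

The size (alpha), duration (tau) and inter-avalanche-interval (delta)
exponents come from a truncated discrete power-law maximum-likelihood fit,
P(x) ∝ x^(-e) on an integer support [xmin, xmax]; gamma is the slope of
log mean size against log duration. Deviance from the ideal power law is
scored by kappa (against a fixed reference exponent), generalized kappa
(against the sample's own MLE exponent) and the drop-off scale of an
exponentially truncated power-law fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .avalanches import AvalancheSet, branching_parameter

__all__ = [
    "FitConfig",
    "ExponentProfile",
    "fit_discrete_powerlaw_mle",
    "fit_gamma",
    "kappa",
    "generalized_kappa",
    "distribution_cutoff",
    "profile_at_scale",
]

_EXPONENT_BOUNDS = (-3.0, 20.0)


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the per-scale exponent fits.

    min_samples is the floor of in-range observations below which a fit is
    reported missing; kappa_reference is the reference size exponent for
    kappa (3/2, the mean-field critical value); kappa_m the number of
    log-spaced probe points. size_xmax caps the size-fit support (default:
    n_channels * scale_k, the per-bin event capacity of the array at that
    scale). sigma_method/sigma_min_duration select the branching-parameter
    convention (see :func:`mscrit.avalanches.branching_parameter`).
    """

    min_samples: int = 50
    kappa_reference: float = 1.5
    kappa_m: int = 10
    size_xmax: int | None = None
    gamma_min_per_duration: int = 5
    gamma_min_durations: int = 3
    sigma_method: str = "first2"
    sigma_min_duration: int = 1


@dataclass(frozen=True)
class ExponentProfile:
    """The criticality parameters of one (scale, pooled-threshold) condition.

    Any field may be NaN when the underlying data were insufficient; the
    reasons are collected in ``flags`` rather than silently zeroed.
    """

    sigma: float
    alpha: float
    tau: float
    gamma: float
    delta: float
    kappa: float
    kappa_gen: float
    cutoff: float
    scale_k: int
    n_avalanches: int = 0
    flags: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in (
                "sigma",
                "alpha",
                "tau",
                "gamma",
                "delta",
                "kappa",
                "kappa_gen",
                "cutoff",
            )
        }


def _log_norm(exponent: float, log_support: np.ndarray) -> float:
    """log of the normalizing sum of x^(-e) over the integer support."""
    return float(logsumexp(-exponent * log_support))


def fit_discrete_powerlaw_mle(
    samples: np.ndarray,
    xmin: int = 1,
    xmax: int | None = None,
    min_samples: int = 50,
) -> float:
    """MLE exponent of a truncated discrete power law on [xmin, xmax].

    Samples outside the support are discarded before fitting; the exponent
    maximizing the truncated likelihood is found by bounded 1-D
    optimization of the exact log-likelihood. Returns NaN (with a warning)
    when fewer than ``min_samples`` observations are in range, and +inf
    when the likelihood diverges (all in-range samples equal xmin).
    """
    samples = np.asarray(samples)
    if xmax is None:
        xmax = int(samples.max()) if samples.size else xmin
    if not (xmin >= 1 and xmax > xmin):
        raise ValueError("need xmin >= 1 and xmax > xmin")
    x = samples[(samples >= xmin) & (samples <= xmax)]
    if x.size < min_samples:
        warnings.warn(
            f"power-law fit skipped: {x.size} in-range samples < floor {min_samples}"
        )
        return float("nan")
    if np.all(x == xmin):
        warnings.warn("all in-range samples equal xmin: exponent diverges")
        return float("inf")
    log_support = np.log(np.arange(xmin, xmax + 1))
    sum_log_x = float(np.sum(np.log(x)))
    n = x.size

    def nll(e: float) -> float:
        return n * _log_norm(e, log_support) + e * sum_log_x

    res = minimize_scalar(nll, bounds=_EXPONENT_BOUNDS, method="bounded",
                          options={"xatol": 1e-7})
    return float(res.x)


def fit_gamma(
    av: AvalancheSet,
    min_per_duration: int = 5,
    min_durations: int = 3,
) -> float:
    """Exponent of mean avalanche size versus duration.

    gamma is the least-squares slope of log<size> against log(duration)
    over durations represented by at least ``min_per_duration`` avalanches;
    NaN when fewer than ``min_durations`` durations qualify.
    """
    if len(av) == 0:
        return float("nan")
    durations, counts = np.unique(av.durations, return_counts=True)
    keep = durations[counts >= min_per_duration]
    if keep.size < min_durations:
        return float("nan")
    mean_size = np.array(
        [av.sizes[av.durations == d].mean() for d in keep], dtype=float
    )
    slope, _ = np.polyfit(np.log(keep), np.log(mean_size), 1)
    return float(slope)


def _reference_cdf(exponent: float, xmin: int, xmax: int) -> np.ndarray:
    support = np.arange(xmin, xmax + 1)
    logw = -exponent * np.log(support)
    w = np.exp(logw - logw.max())
    cdf = np.cumsum(w)
    return cdf / cdf[-1]


def kappa(
    sizes: np.ndarray,
    reference_exponent: float = 1.5,
    xmin: int = 1,
    xmax: int | None = None,
    m: int = 10,
) -> float:
    """Deviance of an empirical distribution from a reference power law.

    kappa = 1 + mean over m log-spaced probe points beta_k in [xmin, xmax]
    of F_ref(beta_k) - F_emp(beta_k), with F_ref the truncated discrete
    power-law CDF at ``reference_exponent`` and F_emp the empirical CDF of
    the in-support samples. kappa = 1 marks power-law agreement; values
    above 1 indicate an excess of large events (supercritical), below 1 a
    deficit (subcritical).
    """
    if m < 2:
        raise ValueError("need at least 2 probe points")
    sizes = np.asarray(sizes)
    if xmax is None:
        xmax = int(sizes.max()) if sizes.size else xmin
    if xmax <= xmin:
        raise ValueError("need xmax > xmin")
    x = np.sort(sizes[(sizes >= xmin) & (sizes <= xmax)])
    if x.size == 0:
        return float("nan")
    betas = np.logspace(np.log10(xmin), np.log10(xmax), m)
    ref_cdf = _reference_cdf(reference_exponent, xmin, xmax)
    f_ref = ref_cdf[np.floor(betas).astype(int) - xmin]
    f_emp = np.searchsorted(x, betas, side="right") / x.size
    return float(1.0 + np.mean(f_ref - f_emp))


def generalized_kappa(
    sizes: np.ndarray,
    xmin: int = 1,
    xmax: int | None = None,
    m: int = 10,
    min_samples: int = 50,
) -> float:
    """kappa scored against the sample's own MLE exponent.

    Using the self-fit exponent as the reference isolates deviance of
    distributional *shape* from deviance of exponent value: any exact power
    law scores ~1 regardless of its exponent. NaN when the MLE itself is
    unavailable.
    """
    sizes = np.asarray(sizes)
    if xmax is None:
        xmax = int(sizes.max()) if sizes.size else xmin
    e_hat = fit_discrete_powerlaw_mle(sizes, xmin, xmax, min_samples=min_samples)
    if not np.isfinite(e_hat):
        return float("nan")
    return kappa(sizes, reference_exponent=e_hat, xmin=xmin, xmax=xmax, m=m)


def distribution_cutoff(
    sizes: np.ndarray,
    xmin: int = 1,
    min_samples: int = 50,
) -> float:
    """Drop-off scale of an exponentially truncated power-law fit.

    Jointly fits P(x) ∝ x^(-e) * exp(-x / s_c) for x >= xmin by 2-D maximum
    likelihood and returns the drop-off scale s_c. For a sample without an
    interior drop-off (a clean truncated power law) the fitted s_c runs to
    the optimizer's upper bound, well beyond the sample maximum. NaN when
    the sample is too small or carries no tail information.
    """
    sizes = np.asarray(sizes)
    x = sizes[sizes >= xmin]
    if x.size < min_samples:
        warnings.warn(f"cutoff fit skipped: {x.size} samples < floor {min_samples}")
        return float("nan")
    if np.all(x == x[0]):
        warnings.warn("cutoff fit skipped: degenerate sample")
        return float("nan")
    smax = int(x.max())
    # normalization over the unbounded integer support: exact sum over a
    # head region, Euler-Maclaurin continuous integral beyond it (the
    # integrand is smooth and decaying, so the correction is negligible)
    head_hi = min(smax, 2000)
    support = np.arange(xmin, head_hi + 1, dtype=float)
    log_support = np.log(support)
    n = x.size
    sum_log_x = float(np.sum(np.log(x)))
    sum_x = float(np.sum(x))
    # lam = 1/s_c; its lower bound puts s_c at 10x the sample maximum,
    # flagging "no drop-off"
    log_lam_lo = np.log(1.0 / (10.0 * smax))
    log_lam_hi = np.log(2.0)

    def log_z(e: float, lam: float) -> float:
        head = logsumexp(-e * log_support - lam * support)
        x0 = head_hi + 0.5
        shift = -e * np.log(x0) - lam * x0
        tail, _ = quad(
            lambda u: np.exp(-e * np.log(u) - lam * u - shift),
            x0,
            np.inf,
            limit=200,
        )
        if tail <= 0:
            return head
        return float(np.logaddexp(head, shift + np.log(tail)))

    def nll(params: np.ndarray) -> float:
        e, log_lam = params
        return n * log_z(e, np.exp(log_lam)) + e * sum_log_x + np.exp(log_lam) * sum_x

    best = None
    for lam0 in (1.0 / smax, 5.0 / smax, 0.5 / smax):
        res = minimize(
            nll,
            x0=np.array([1.5, np.log(lam0)]),
            method="L-BFGS-B",
            bounds=[_EXPONENT_BOUNDS, (log_lam_lo, log_lam_hi)],
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        warnings.warn("cutoff fit did not converge")
        return float("nan")
    return float(np.exp(-best.x[1]))


def profile_at_scale(
    av: AvalancheSet, config: FitConfig | None = None, deviance: bool = True
) -> ExponentProfile:
    """Assemble the full criticality parameter set of one avalanche set.

    Fits alpha on sizes (support capped at the array's per-bin event
    capacity n_channels * scale_k by default), tau on durations, delta on
    inter-avalanche intervals, gamma on the size-duration relation, plus
    sigma, kappa, generalized kappa and the size-distribution cutoff.
    Components that cannot be estimated are NaN and named in ``flags``.
    ``deviance=False`` skips the three deviance measures (kappa, generalized
    kappa, cutoff), which are only reported at an interval's head scale.
    """
    cfg = config or FitConfig()
    flags: list[str] = []

    def _guard(name: str, value: float) -> float:
        if not np.isfinite(value):
            flags.append(name)
        return value

    if len(av) == 0:
        return ExponentProfile(
            *(float("nan"),) * 8,
            scale_k=av.scale_k,
            n_avalanches=0,
            flags=("empty",),
        )
    size_xmax = cfg.size_xmax or av.n_channels * av.scale_k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sigma = _guard(
            "sigma",
            branching_parameter(av, cfg.sigma_method, cfg.sigma_min_duration),
        )
        alpha = _guard(
            "alpha",
            fit_discrete_powerlaw_mle(
                av.sizes, 1, max(size_xmax, 2), cfg.min_samples
            ),
        )
        tau = (
            _guard("tau", fit_discrete_powerlaw_mle(
                av.durations, 1, int(av.durations.max()), cfg.min_samples))
            if av.durations.max() > 1
            else _guard("tau", float("nan"))
        )
        delta = (
            _guard("delta", fit_discrete_powerlaw_mle(
                av.iai, 1, int(av.iai.max()), cfg.min_samples))
            if av.iai.size and av.iai.max() > 1
            else _guard("delta", float("nan"))
        )
        gamma = _guard(
            "gamma",
            fit_gamma(av, cfg.gamma_min_per_duration, cfg.gamma_min_durations),
        )
        if deviance:
            kap = _guard(
                "kappa",
                kappa(av.sizes, cfg.kappa_reference, 1, max(size_xmax, 2), cfg.kappa_m),
            )
            kap_gen = _guard(
                "kappa_gen",
                generalized_kappa(
                    av.sizes, 1, max(size_xmax, 2), cfg.kappa_m, cfg.min_samples
                ),
            )
            cut = _guard("cutoff", distribution_cutoff(av.sizes, 1, cfg.min_samples))
        else:
            kap = kap_gen = cut = float("nan")
    return ExponentProfile(
        sigma=sigma,
        alpha=alpha,
        tau=tau,
        gamma=gamma,
        delta=delta,
        kappa=kap,
        kappa_gen=kap_gen,
        cutoff=cut,
        scale_k=av.scale_k,
        n_avalanches=len(av),
        flags=tuple(flags),
    )
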