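"""Closed-form results for passenger mutations in a growing tumor.

Successful mutations (those whose lineages never die out) are labelled
k = 1, 2, ... by order of appearance.  In a supercritical birth–death
process with death–birth ratio ``delta`` and per-division passenger
probability ``u``, the population sizes at which successful mutations
appear form (to leading order in u) a Poisson process of rate u per unit
of population size.  Everything here follows from that observation plus
the beta-mixture law of the eventual fraction of a clone that started
among z competitor cells:

* fixation probability of the k-th successful mutation,
  rho_k = [u / (u - ln delta)]^k;
* the CDF F_k of its eventual cell fraction (with an atom rho_k at 1);
* the conditional law of the fraction given the origin size z, and the
  resulting ML / MAP estimators of z from an observed fraction;
* the expected numbers of subclonal mutations above a frequency threshold,
  u(1-alpha)/((1-delta) alpha), and of clonal passengers, delta*u/(1-delta);
* the expected count of mutations in an allele-fraction window for a
  diploid, heterozygous, purity-one sample (allele fraction = cell
  fraction / 2).

All frequency arguments are *cell* fractions except
:func:`allele_count_in_window`, which takes allele fractions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import integrate, special

from .exceptions import DomainError, InvalidParameterError, NumericalError
from .params import BranchingParams, EstimatorConfig

__all__ = [
    "fixation_probability",
    "fixation_probability_integral",
    "frequency_cdf",
    "frequency_pdf",
    "median_frequency",
    "expected_frequency_given_z",
    "frequency_law_given_z",
    "zhat_ml",
    "zhat_map",
    "expected_subclonal",
    "expected_clonal",
    "expected_total_surviving_mutations",
    "allele_count_in_window",
    "spectrum_coefficient",
    "table1",
]

_CLIP_TOL = 1e-12


def _check_k(k: int) -> int:
    if k != int(k) or k < 1:
        raise DomainError(f"k must be a positive integer, got {k}")
    return int(k)


def _as_probability(x: float) -> float:
    """Clip tiny floating-point overshoot; anything larger is a real bug."""
    if -_CLIP_TOL <= x <= 1 + _CLIP_TOL:
        return min(1.0, max(0.0, x))
    raise NumericalError(f"value {x!r} outside [0, 1] by more than {_CLIP_TOL}")


def fixation_probability(k: int, params: BranchingParams) -> float:
    """Probability rho_k that the k-th successful mutation reaches 100% cell
    frequency, rho_k = [u/(u - ln delta)]^k.

    Fixation of mutation k implies fixation of mutations 1..k-1.  For
    delta = 0 no mutation can fix (the founder lineage is immortal).
    """
    k = _check_k(k)
    delta = params.delta
    if delta == 0.0:
        return 0.0
    return _as_probability((params.u / (params.u - math.log(delta))) ** k)


def fixation_probability_integral(k: int, params: BranchingParams) -> float:
    """rho_k by direct quadrature of its Poisson-mixture representation,
    integral over z of (zu)^(k-1) e^{-zu} u delta^z / (k-1)!.

    Serves as an independent numerical cross-check of
    :func:`fixation_probability`.
    """
    k = _check_k(k)
    u, delta = params.u, params.delta
    if delta == 0.0:
        return 0.0
    log_delta = math.log(delta)
    lgamma_k = special.gammaln(k)

    def integrand(z: float) -> float:
        # (zu)^{k-1} e^{-zu} u delta^z / (k-1)!, computed in log space
        if z == 0.0:
            return u if k == 1 else 0.0
        return u * math.exp((k - 1) * math.log(z * u) - z * u - lgamma_k + z * log_delta)

    value, err = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-12, epsrel=1e-10, limit=200)
    if err > 1e-8 * max(abs(value), 1e-3):
        raise NumericalError(
            f"fixation integral did not converge: value={value!r}, abserr={err!r}"
        )
    return _as_probability(value)


def _log_term(alpha, params: BranchingParams):
    """1 - ln(1 - alpha (1 - delta)) / u — the recurring base of F_k."""
    return 1.0 - np.log1p(-alpha * (1.0 - params.delta)) / params.u


def frequency_cdf(k: int, alpha, params: BranchingParams):
    """CDF F_k(alpha) of the eventual cell fraction of the k-th successful
    mutation, F_k = 1 - [1 - ln(1 - alpha(1-delta))/u]^(-k) for alpha in (0,1).

    F_k(1^-) = 1 - rho_k < 1: the missing mass is the fixation atom.
    """
    k = _check_k(k)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= 1):
        raise DomainError("alpha must lie strictly inside (0, 1)")
    out = 1.0 - _log_term(alpha, params) ** (-k)
    return float(out) if out.ndim == 0 else out


def frequency_pdf(k: int, alpha, params: BranchingParams):
    """Density g_k = dF_k/dalpha of the subclonal part of the k-th
    successful mutation's frequency law (closed-form derivative)."""
    k = _check_k(k)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= 1):
        raise DomainError("alpha must lie strictly inside (0, 1)")
    one_minus = 1.0 - alpha * (1.0 - params.delta)
    out = k * (1.0 - params.delta) / (params.u * one_minus) * _log_term(alpha, params) ** (-(k + 1))
    return float(out) if out.ndim == 0 else out


def median_frequency(k: int, params: BranchingParams) -> float:
    """Median eventual cell fraction of the k-th successful mutation,
    min(1, (1 - e^{u(1 - 2^{1/k})})/(1 - delta)).

    Equals 1 whenever rho_k > 1/2 (the fixation atom carries the median).
    """
    k = _check_k(k)
    return min(1.0, (1.0 - math.exp(params.u * (1.0 - 2.0 ** (1.0 / k)))) / (1.0 - params.delta))


def expected_frequency_given_z(z: int, params: BranchingParams) -> float:
    """Expected eventual cell fraction of a successful mutation that arose
    when z other cells were present: (1 - delta^(z+1)) / ((1-delta)(z+1))."""
    if z < 0 or z != int(z):
        raise DomainError(f"z must be a nonnegative integer, got {z}")
    z = int(z)
    delta = params.delta
    if delta == 0.0:
        return 1.0 / (z + 1)
    return (1.0 - delta ** (z + 1)) / ((1.0 - delta) * (z + 1))


def frequency_law_given_z(z: int, alpha, params: BranchingParams):
    """(CDF, pdf) of the eventual fraction given origin size z:
    CDF = 1 - (1 - alpha + delta*alpha)^z, pdf its derivative.

    The pdf integrates to 1 - delta^z over (0, 1); the remaining mass
    delta^z is the fixation atom (all z competitor lineages die out).
    """
    if z < 1 or z != int(z):
        raise DomainError(f"z must be a positive integer, got {z}")
    z = int(z)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= 1):
        raise DomainError("alpha must lie strictly inside (0, 1)")
    base = 1.0 - alpha * (1.0 - params.delta)
    cdf = 1.0 - base**z
    pdf = (1.0 - params.delta) * z * base ** (z - 1)
    if cdf.ndim == 0:
        return float(cdf), float(pdf)
    return cdf, pdf


def zhat_ml(alpha: float, params: BranchingParams) -> float:
    """Maximum-likelihood estimate of the number of cells present when a
    mutation now at cell fraction alpha arose: -1 / ln(1 - alpha(1-delta)).

    The deterministic (no-death) estimate ~1/alpha is recovered as
    delta -> 0 and alpha -> 0.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie strictly inside (0, 1), got {alpha}")
    return -1.0 / math.log1p(-alpha * (1.0 - params.delta))


def zhat_map(alpha: float, params: BranchingParams, est: EstimatorConfig | None = None) -> float:
    """Maximum a posteriori estimate of the origin size, with a geometric
    prior of rate v on the origin size: -1/(ln(1-v) + ln(1 - alpha(1-delta))).

    For the realistic v ~ 1e-9 this is indistinguishable from the MLE.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie strictly inside (0, 1), got {alpha}")
    est = est or EstimatorConfig()
    return -1.0 / (math.log1p(-est.v) + math.log1p(-alpha * (1.0 - params.delta)))


def expected_subclonal(alpha: float, params: BranchingParams) -> float:
    """Expected number of subclonal mutations at cell frequency above alpha:
    u (1 - alpha) / ((1 - delta) alpha)."""
    if not 0 < alpha <= 1:
        raise DomainError(f"alpha must lie in (0, 1], got {alpha}")
    return params.u * (1.0 - alpha) / ((1.0 - params.delta) * alpha)


def expected_clonal(params: BranchingParams) -> float:
    """Expected number of clonal passenger mutations collected during the
    expansion: delta u / (1 - delta).  Zero for a pure birth process."""
    return params.delta * params.u / (1.0 - params.delta)


def expected_total_surviving_mutations(M: float, u: float) -> float:
    """Expected number of passenger mutations with surviving lineage present
    in a population of M cells: M * u (most at undetectably low frequency)."""
    if M < 1:
        raise DomainError(f"population size M must be >= 1, got {M}")
    if not 0 <= u < 1:
        raise InvalidParameterError(f"u must be in [0, 1), got {u}")
    return M * u


def spectrum_coefficient(params: BranchingParams) -> float:
    """Amplitude a = u / (2 (1 - delta)) of the diploid allele-frequency
    spectrum — the coefficient estimated by the cohort fit."""
    return params.u / (2.0 * (1.0 - params.delta))


def allele_count_in_window(alpha: float, params: BranchingParams, upper: float = 0.25) -> float:
    """Expected number of mutations with *allele* fraction in (alpha, upper],
    [u/(2(1-delta))] (1/alpha - 1/upper), assuming diploid heterozygous
    mutations without LOH so allele fraction = cell fraction / 2."""
    if not 0 < alpha <= upper:
        raise DomainError(f"alpha must lie in (0, {upper}], got {alpha}")
    return spectrum_coefficient(params) * (1.0 / alpha - 1.0 / upper)


def table1(
    u: float = 0.015,
    deltas: tuple[float, ...] = (0.0, 0.72, 0.96, 0.99, 0.999),
    thresholds: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5),
) -> pd.DataFrame:
    """Expected subclonal mutation counts above each cell-frequency
    threshold, plus the clonal count, for a grid of delta values."""
    rows = []
    for delta in deltas:
        p = BranchingParams.from_delta(delta, u=u)
        row: dict[str, float] = {"delta": delta}
        for thr in thresholds:
            row[f">{thr:g}"] = expected_subclonal(thr, p)
        row["clonal"] = expected_clonal(p)
        rows.append(row)
    return pd.DataFrame(rows)
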