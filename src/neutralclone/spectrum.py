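"""Allele-frequency-spectrum fitting: inferring delta from sequencing data.

Under neutral clonal expansion the expected number of mutations with
allele fraction in (alpha, 0.25], for a diploid tumor without LOH, is

    n(alpha) = a (1/alpha - 1/0.25),    a = u / (2 (1 - delta)).

The pipeline mirrors the published analysis: keep near-diploid
(ploidy 1.8–2.2), high-purity (>= 70%) samples; divide each observed
allele fraction by the purity; build the cumulative curve inside the
window [0.12, 0.25] (low edge: detection power; high edge: possible
clonal mutations); least-squares fit the curve to n(alpha) through the
origin; convert the amplitude to delta = 1 - u/(2a) for an assumed u.

The fit is exposed statsmodels-style: :class:`NeutralSpectrumModel` is
built from allele fractions (or a mutation table / DataFrame) and
``fit()`` returns a :class:`NeutralSpectrumResults` carrying the
estimate, its 95% CI, R^2 and a ``summary()`` table.  A synthetic
mutation-table generator with the exact model spectrum, purity dilution
and binomial read noise stands in for protected patient data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import analytic
from .exceptions import (
    DegenerateFitError,
    DomainError,
    EmptyCurveError,
    InsufficientDataError,
    InvalidParameterError,
    NoValidDeltaError,
)
from .params import BranchingParams

__all__ = [
    "MutationTable",
    "FitResult",
    "filter_samples",
    "correct_allele_fraction",
    "cumulative_curve",
    "fit_neutral_model",
    "delta_from_fit",
    "a_from_delta",
    "classify_msi",
    "clonal_origin_estimate",
    "generate_synthetic_table",
    "NeutralSpectrumModel",
    "NeutralSpectrumResults",
]

DEFAULT_WINDOW = (0.12, 0.25)
DEFAULT_MSI_THRESHOLD = 500  # exome mutation count separating MSS from MSI


def _poisson_lower(n: int, alpha: float = 0.05) -> float:
    """Garwood lower bound for a Poisson mean given n observed events."""
    return 0.0 if n == 0 else float(stats.chi2.ppf(alpha / 2, 2 * n) / 2)


def _poisson_upper(n: int, alpha: float = 0.05) -> float:
    return float(stats.chi2.ppf(1 - alpha / 2, 2 * (n + 1)) / 2)


@dataclass
class MutationTable:
    """Per-sample somatic variants with the metadata needed for the fit."""

    sample: str
    allele_fraction: np.ndarray
    purity: float | None = None
    ploidy: float | None = None
    msi: str = "unknown"
    alt_count: np.ndarray | None = None
    ref_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.allele_fraction = np.asarray(self.allele_fraction, dtype=float)
        if np.any((self.allele_fraction < 0) | (self.allele_fraction > 1)):
            raise DomainError(f"sample {self.sample}: allele fractions outside [0, 1]")

    @classmethod
    def from_counts(cls, sample: str, alt, ref, **meta) -> "MutationTable":
        alt = np.asarray(alt, dtype=float)
        ref = np.asarray(ref, dtype=float)
        return cls(sample=sample, allele_fraction=alt / (alt + ref),
                   alt_count=alt, ref_count=ref, **meta)

    @property
    def n_mutations(self) -> int:
        return len(self.allele_fraction)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample": self.sample, "allele_fraction": self.allele_fraction})
        if self.alt_count is not None:
            df["t_alt_count"] = self.alt_count.astype(int)
            df["t_ref_count"] = self.ref_count.astype(int)
        return df


@dataclass(frozen=True)
class FitResult:
    """Outcome of one sample's spectrum fit."""

    a: float
    ci95: tuple[float, float]
    r_squared: float
    n_points: int
    window: tuple[float, float]

    def delta(self, u: float = 0.015) -> float:
        return delta_from_fit(self.a, u)


def filter_samples(
    tables,
    ploidy_range: tuple[float, float] = (1.8, 2.2),
    purity_min: float = 0.70,
):
    """Keep near-diploid, high-purity samples (inclusive boundaries);
    return (kept, audit) where audit lists each exclusion with a reason."""
    kept, audit = [], []
    for t in tables:
        if t.purity is None or t.ploidy is None:
            audit.append({"sample": t.sample, "reason": "missing-metadata"})
        elif not ploidy_range[0] <= t.ploidy <= ploidy_range[1]:
            audit.append({"sample": t.sample, "reason": f"ploidy {t.ploidy} outside {ploidy_range}"})
        elif t.purity < purity_min:
            audit.append({"sample": t.sample, "reason": f"purity {t.purity} < {purity_min}"})
        else:
            kept.append(t)
    return kept, audit


def correct_allele_fraction(af, purity: float):
    """Observed allele fraction divided by tumor purity.  Values > 0.5 can
    indicate clonal or aneuploid variants; they are kept (the fitting
    window removes them) but a warning is emitted."""
    if not 0 < purity <= 1:
        raise DomainError(f"purity must be in (0, 1], got {purity}")
    af = np.asarray(af, dtype=float)
    out = af / purity
    if np.any(out > 0.5):
        warnings.warn(
            f"{int(np.sum(out > 0.5))} corrected allele fraction(s) exceed 0.5 "
            "(potentially clonal or aneuploid); retained but outside the fit window",
            stacklevel=2,
        )
    return float(out) if out.ndim == 0 else out


def cumulative_curve(fractions, window: tuple[float, float] = DEFAULT_WINDOW) -> pd.DataFrame:
    """Cumulative mutation counts at each observed in-window fraction.

    Each mutation with corrected fraction alpha_i in [lo, hi] contributes
    one point (alpha_i, #{j: alpha_j > alpha_i and alpha_j <= hi});
    counts use strict '>' so tied fractions each get the same count.
    """
    lo, hi = window
    fractions = np.asarray(fractions, dtype=float)
    inside = fractions[(fractions >= lo) & (fractions <= hi)]
    if len(inside) == 0:
        raise EmptyCurveError(f"no mutations with fraction inside [{lo}, {hi}]")
    inside = np.sort(inside)
    counts = np.array([np.sum((inside > a)) for a in inside])
    return pd.DataFrame({"alpha": inside, "count": counts})


class NeutralSpectrumModel:
    """Through-origin least-squares model of the cumulative allele-fraction
    curve, count = a (1/alpha - 1/hi).

    Parameters
    ----------
    allele_fractions : array-like
        Observed allele fractions of one sample.
    purity : float
        Tumor purity; fractions are divided by it before windowing.
    window : (float, float)
        Corrected-allele-fraction window, default (0.12, 0.25).
    """

    def __init__(self, allele_fractions, purity: float = 1.0,
                 window: tuple[float, float] = DEFAULT_WINDOW, sample: str = ""):
        self.sample = sample
        self.window = tuple(window)
        self.purity = purity
        corrected = correct_allele_fraction(np.asarray(allele_fractions, float), purity)
        self.curve = cumulative_curve(corrected, self.window)
        self.endog = self.curve["count"].to_numpy(dtype=float)
        self.exog = 1.0 / self.curve["alpha"].to_numpy() - 1.0 / self.window[1]

    @classmethod
    def from_table(cls, table: MutationTable,
                   window: tuple[float, float] = DEFAULT_WINDOW) -> "NeutralSpectrumModel":
        purity = 1.0 if table.purity is None else table.purity
        return cls(table.allele_fraction, purity=purity, window=window, sample=table.sample)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, af_col: str = "allele_fraction",
                       purity: float = 1.0,
                       window: tuple[float, float] = DEFAULT_WINDOW) -> "NeutralSpectrumModel":
        return cls(df[af_col].to_numpy(), purity=purity, window=window)

    def fit(self) -> "NeutralSpectrumResults":
        """Least-squares amplitude with a Poisson-exact confidence interval.

        The point estimate is the through-origin OLS slope of the cumulative
        curve (directly comparable to published spectrum fits).  The CI is
        *not* the OLS t-interval: cumulative counts at neighbouring
        fractions are strongly positively correlated, so the OLS residual
        variance understates the sampling variance many-fold.  Under the
        model the number of in-window mutations is Poisson with mean
        a (1/lo - 1/hi), which pivots into an exact (Garwood) interval for
        the amplitude with calibrated coverage.
        """
        y, x = self.endog, self.exog
        if len(y) < 2:
            raise InsufficientDataError(
                f"need at least 2 in-window points for a fit, got {len(y)}"
            )
        if np.allclose(x, 0.0):
            raise DegenerateFitError("all in-window fractions sit at the window edge")
        ols = sm.OLS(y, x[:, None]).fit()
        a = float(ols.params[0])
        resid = y - a * x
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            r2 = 1.0 if ss_res < 1e-12 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        span = 1.0 / self.window[0] - 1.0 / self.window[1]
        n_window = len(y)
        # widen to include the LS estimate so the interval always brackets it
        ci = (min(_poisson_lower(n_window) / span, a),
              max(_poisson_upper(n_window) / span, a))
        return NeutralSpectrumResults(
            model=self, a=a, bse=float(ols.bse[0]), ci95=ci,
            rsquared=r2, nobs=n_window, df_resid=int(ols.df_resid),
        )


@dataclass
class NeutralSpectrumResults:
    """Fitted spectrum amplitude with uncertainty and diagnostics."""

    model: NeutralSpectrumModel
    a: float
    bse: float
    ci95: tuple[float, float]
    rsquared: float
    nobs: int
    df_resid: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a])

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.a * self.model.exog

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Poisson-exact CI for the amplitude (see NeutralSpectrumModel.fit)."""
        span = 1.0 / self.model.window[0] - 1.0 / self.model.window[1]
        return (_poisson_lower(self.nobs, alpha) / span,
                _poisson_upper(self.nobs, alpha) / span)

    def delta(self, u: float = 0.015) -> float:
        """Death–birth ratio implied by the amplitude at mutation rate u."""
        return delta_from_fit(self.a, u)

    def delta_conf_int(self, u: float = 0.015, alpha: float = 0.05) -> tuple[float, float]:
        """CI for delta, mapping the amplitude CI through delta = 1 - u/(2a)
        and clipping to the admissible range [0, 1)."""
        a_lo, a_hi = self.conf_int(alpha)
        d_hi = 1.0 - u / (2.0 * a_hi) if a_hi > 0 else 0.0
        d_lo = 1.0 - u / (2.0 * a_lo) if a_lo > 0 else 0.0
        return (max(0.0, d_lo), max(0.0, min(d_hi, 1.0)))

    def as_fit_result(self) -> FitResult:
        return FitResult(a=self.a, ci95=self.ci95, r_squared=self.rsquared,
                         n_points=self.nobs, window=self.model.window)

    def summary(self, u: float = 0.015) -> str:
        lines = [
            "Neutral allele-frequency spectrum fit",
            "=" * 46,
            f"sample:          {self.model.sample or '<unnamed>'}",
            f"window:          [{self.model.window[0]:g}, {self.model.window[1]:g}]",
            f"n points:        {self.nobs}",
            f"a (amplitude):   {self.a:.4g}",
            f"std err:         {self.bse:.4g}",
            f"95% CI:          [{self.ci95[0]:.4g}, {self.ci95[1]:.4g}]",
            f"R-squared:       {self.rsquared:.4f}",
        ]
        try:
            d = self.delta(u)
            lines.append(f"delta (u={u:g}):  {d:.4g}")
        except NoValidDeltaError:
            lines.append(f"delta (u={u:g}):  none (a < u/2: evidence against neutral fit)")
        return "\n".join(lines)


def fit_neutral_model(points) -> FitResult:
    """Fit the cumulative curve (DataFrame with alpha/count columns, or a
    pair of arrays) and return the plain :class:`FitResult`."""
    if isinstance(points, pd.DataFrame):
        alpha = points["alpha"].to_numpy(dtype=float)
        count = points["count"].to_numpy(dtype=float)
    else:
        alpha, count = (np.asarray(p, dtype=float) for p in points)
    model = NeutralSpectrumModel.__new__(NeutralSpectrumModel)
    model.sample = ""
    model.window = DEFAULT_WINDOW
    model.purity = 1.0
    model.curve = pd.DataFrame({"alpha": alpha, "count": count})
    model.endog = count
    model.exog = 1.0 / alpha - 1.0 / DEFAULT_WINDOW[1]
    return model.fit().as_fit_result()


def delta_from_fit(a: float, u: float) -> float:
    """Invert a = u/(2(1-delta)): delta = 1 - u/(2a)."""
    if a <= 0 or u <= 0:
        raise DomainError(f"a and u must be positive, got a={a}, u={u}")
    ratio = u / (2.0 * a)
    if ratio > 1:
        raise NoValidDeltaError(
            f"u/(2a) = {ratio:.4g} > 1: no delta in [0, 1) is consistent with this "
            "amplitude at the assumed mutation rate (evidence against the neutral fit)"
        )
    return 1.0 - ratio


def a_from_delta(delta: float, u: float) -> float:
    """Forward map a = u/(2(1-delta))."""
    if not 0 <= delta < 1:
        raise InvalidParameterError(f"delta must be in [0, 1), got {delta}")
    return u / (2.0 * (1.0 - delta))


def classify_msi(table: MutationTable, threshold: int = DEFAULT_MSI_THRESHOLD) -> str:
    """MSI if the sample's total mutation count strictly exceeds the
    threshold, else MSS."""
    return "MSI" if table.n_mutations > threshold else "MSS"


def clonal_origin_estimate(n_clonal: int, n_subclonal_above_half: int) -> int:
    """Estimated clonal mutations already present in the founder cell:
    all clonal minus subclonal-above-50% (floored at zero).  Valid because
    for delta near 1 the latter approximates the passengers that fixed
    during the expansion."""
    if n_clonal < 0 or n_subclonal_above_half < 0:
        raise DomainError("counts must be nonnegative")
    return max(0, n_clonal - n_subclonal_above_half)


def generate_synthetic_table(
    params: BranchingParams,
    depth: float = 100.0,
    purity: float = 0.85,
    seed: int | np.random.Generator | None = None,
    alpha_min: float = 0.05,
    sample: str = "synthetic",
) -> MutationTable:
    """Synthetic diploid tumor sample with the model's exact spectrum.

    Cell fractions are drawn on [alpha_min, 1] by inverse transform from
    the 1/alpha^2 density implied by the subclonal spectrum, with a
    Poisson total count of mean u(1-alpha_min)/((1-delta) alpha_min).
    Allele fractions are cell fraction / 2 (diploid heterozygous), diluted
    by purity, then observed through binomial sampling at Poisson-
    distributed read depth.  Ploidy metadata is 2.0 by construction.
    """
    if not 0 < purity <= 1:
        raise DomainError(f"purity must be in (0, 1], got {purity}")
    if depth < 1:
        raise DomainError(f"depth must be >= 1, got {depth}")
    if not 0 < alpha_min < 1:
        raise DomainError(f"alpha_min must be in (0, 1), got {alpha_min}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if alpha_min * purity / 2.0 < 3.0 / depth:
        warnings.warn(
            "alpha_min implies allele fractions near or below the detection limit "
            f"at depth {depth:g}; the low-frequency tail will be power-limited",
            stacklevel=2,
        )
    n = rng.poisson(analytic.expected_subclonal(alpha_min, params))
    q = rng.random(n)
    cell_fraction = 1.0 / (1.0 / alpha_min - q * (1.0 / alpha_min - 1.0))
    af_true = purity * cell_fraction / 2.0
    reads = np.maximum(rng.poisson(depth, size=n), 1)
    alt = rng.binomial(reads, af_true)
    table = MutationTable.from_counts(
        sample=sample, alt=alt, ref=reads - alt, purity=purity, ploidy=2.0
    )
    return table
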