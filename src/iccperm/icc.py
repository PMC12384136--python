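"""Two-way random-effects ANOVA and the ICC(2,1) agreement estimate.

The two-way random-effects model for ``n`` subjects each rated by the same
``k`` randomly selected raters is

.. math::

    x_{ij} = \\mu + s_i + r_j + e_{ij},

with independent subject effects :math:`s_i \\sim (0, \\sigma_s^2)`, rater
effects :math:`r_j \\sim (0, \\sigma_r^2)` and residuals
:math:`e_{ij} \\sim (0, \\sigma_e^2)`.  The ANOVA mean squares of the two-way
layout with one observation per cell satisfy

.. math::

    E(\\mathrm{MSB}) = \\sigma_e^2 + k\\sigma_s^2, \\quad
    E(\\mathrm{MSW}) = \\sigma_e^2, \\quad
    E(\\mathrm{MSR}) = \\sigma_e^2 + n\\sigma_r^2,

and the single-measure, absolute-agreement intraclass correlation is

.. math::

    \\mathrm{ICC}(2,1) =
    \\frac{\\mathrm{MSB} - \\mathrm{MSW}}
         {\\mathrm{MSB} + (k-1)\\mathrm{MSW} + \\tfrac{k}{n}(\\mathrm{MSR} -
          \\mathrm{MSW})},

which estimates :math:`\\sigma_s^2 / (\\sigma_s^2+\\sigma_r^2+\\sigma_e^2)`.

A note on naming, because "MSW" is overloaded in the reliability
literature: here MSW is the *residual (interaction) mean square* of the
two-way layout, ``SSE / ((n-1)(k-1))``, not the one-way pooled
within-subject mean square.  The two differ by the rater sum of squares;
the two-way residual is the one consistent with a model that carries a
separate rater term and an ICC formula that uses MSR separately.  The
choice is isolated inside :func:`mean_squares` so it can be swapped.

Scope is fixed at ``k = 2`` raters throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InvalidRatingsError

__all__ = [
    "RatingsMatrix",
    "MeanSquares",
    "ICCEstimate",
    "as_ratings",
    "mean_squares",
    "icc21",
    "central_moment",
    "tau_n",
]


@dataclass(frozen=True)
class RatingsMatrix:
    """Continuous ratings of ``n`` subjects by two raters.

    Parameters
    ----------
    values
        Array-like of shape ``(n, 2)``; row ``i`` holds the ratings of
        subject ``i`` by rater 1 and rater 2, in arbitrary but common
        continuous units.  Requires ``n >= 3`` and all entries finite.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidRatingsError(
                f"expected an n x 2 ratings matrix, got shape {v.shape}"
            )
        if v.shape[0] < 3:
            raise InvalidRatingsError(
                f"need at least 3 subjects, got n={v.shape[0]}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidRatingsError("ratings must be finite (no NaN/inf)")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        """Number of subjects."""
        return self.values.shape[0]

    @property
    def k(self) -> int:
        """Number of raters (fixed at 2)."""
        return 2


def as_ratings(data) -> RatingsMatrix:
    """Coerce an array-like or :class:`RatingsMatrix` to a validated matrix."""
    if isinstance(data, RatingsMatrix):
        return data
    return RatingsMatrix(np.asarray(data, dtype=float))


@dataclass(frozen=True)
class MeanSquares:
    """ANOVA mean squares of the two-way layout with one observation per cell.

    Attributes
    ----------
    msb : float
        Mean square between subjects, ``SSB / (n-1)``.
    msw : float
        Residual (interaction) mean square, ``SSE / ((n-1)(k-1))``.
    msr : float
        Mean square for raters, ``SSR / (k-1)``.
    n, k : int
        Subject and rater counts.
    """

    msb: float
    msw: float
    msr: float
    n: int
    k: int


@dataclass(frozen=True)
class ICCEstimate:
    """Point estimate of ICC(2,1) with its variance diagnostics.

    Attributes
    ----------
    rho_hat : float
        The ICC(2,1) estimate.  Negative values are returned as-is (no
        truncation at zero); truncation would bias the permutation null.
    u_hat : float or None
        Auxiliary quantity ``k(MSR-MSW) / (n(MSB-MSW))`` of the classical
        large-sample variance; ``None`` when MSB = MSW (undefined).
    var_classical : float or None
        Classical large-sample variance
        ``2 rho^4 [(1/rho - 1)^2 + n k u^2]``.  Known to be unstable near
        rho = 0, so it is exposed purely as a diagnostic and never used by
        the permutation test; ``None`` whenever ``u_hat`` is undefined.
    tau_n2 : float
        Moment-based variance surrogate ``mu_22 / (mu_20 mu_02)`` used to
        studentize the permutation statistic; NaN if a rater column is
        constant.
    means : tuple of float
        Per-rater sample means ``(xbar_1, xbar_2)``.
    """

    rho_hat: float
    u_hat: float | None
    var_classical: float | None
    tau_n2: float
    means: tuple[float, float]


def mean_squares(ratings) -> MeanSquares:
    """Decompose a ratings matrix into the two-way ANOVA mean squares.

    The total sum of squares about the grand mean splits exactly into
    subject, rater and residual pools, ``SST = SSB + SSR + SSE`` (an
    identity the test suite checks to 1e-10 relative tolerance).

    Parameters
    ----------
    ratings
        A :class:`RatingsMatrix` or array-like coercible to one.

    Returns
    -------
    MeanSquares
    """
    r = as_ratings(ratings)
    v = r.values
    n, k = r.n, r.k
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ssb = k * float(((row_means - grand) ** 2).sum())
    ssr = n * float(((col_means - grand) ** 2).sum())
    sst = float(((v - grand) ** 2).sum())
    sse = max(sst - ssb - ssr, 0.0)  # analytically >= 0; guard rounding
    return MeanSquares(
        msb=ssb / (n - 1),
        msw=sse / ((n - 1) * (k - 1)),
        msr=ssr / (k - 1),
        n=n,
        k=k,
    )


def icc21(ratings) -> ICCEstimate:
    """Estimate ICC(2,1) with its variance diagnostics.

    Raises
    ------
    DegenerateDataError
        If the ICC denominator is zero, which happens only for a fully
        constant matrix (all mean squares zero).
    """
    r = as_ratings(ratings)
    ms = mean_squares(r)
    n, k = r.n, r.k
    denom = ms.msb + (k - 1) * ms.msw + (k / n) * (ms.msr - ms.msw)
    if denom == 0.0:
        raise DegenerateDataError(
            "ICC(2,1) undefined: denominator MSB + (k-1)MSW + (k/n)(MSR-MSW) "
            "is zero (fully constant ratings matrix)"
        )
    rho = (ms.msb - ms.msw) / denom

    if ms.msb != ms.msw:
        u = k * (ms.msr - ms.msw) / (n * (ms.msb - ms.msw))
        var_classical = 2.0 * rho**4 * ((1.0 / rho - 1.0) ** 2 + n * k * u**2)
    else:
        u = None
        var_classical = None

    mu20 = central_moment(r, 2, 0)
    mu02 = central_moment(r, 0, 2)
    if mu20 > 0.0 and mu02 > 0.0:
        tau_n2 = central_moment(r, 2, 2) / (mu20 * mu02)
    else:
        tau_n2 = float("nan")

    x1bar, x2bar = r.values.mean(axis=0)
    return ICCEstimate(
        rho_hat=float(rho),
        u_hat=u,
        var_classical=var_classical,
        tau_n2=float(tau_n2),
        means=(float(x1bar), float(x2bar)),
    )


def central_moment(ratings, p: int, q: int) -> float:
    """Sample central cross-moment ``mu_pq`` with divisor ``n`` (not n-1).

    ``mu_pq = (1/n) sum_i (x_i1 - xbar_1)^p (x_i2 - xbar_2)^q``.
    """
    if not (isinstance(p, (int, np.integer)) and isinstance(q, (int, np.integer))):
        raise InvalidRatingsError(f"moment orders must be integers, got {p!r}, {q!r}")
    if p < 0 or q < 0:
        raise InvalidRatingsError("moment orders p, q must be non-negative")
    r = as_ratings(ratings)
    cx = r.values[:, 0] - r.values[:, 0].mean()
    cy = r.values[:, 1] - r.values[:, 1].mean()
    return float(np.mean(cx**p * cy**q))


def tau_n(ratings) -> float:
    """Moment-based studentizer ``tau_n = sqrt(mu_22 / (mu_20 mu_02))``.

    This is the square root of the large-sample variance surrogate borrowed
    from Pearson's correlation coefficient; dividing the ICC estimate by it
    makes the permutation distribution asymptotically pivotal, which is
    what restores type-I-error control when exchangeability fails.  For
    independent columns ``tau_n -> 1`` as ``n`` grows.

    Raises
    ------
    DegenerateDataError
        If either rater column is constant (``mu_20`` or ``mu_02`` zero).
    """
    r = as_ratings(ratings)
    mu20 = central_moment(r, 2, 0)
    mu02 = central_moment(r, 0, 2)
    if mu20 <= 0.0 or mu02 <= 0.0:
        raise DegenerateDataError(
            "studentizer undefined: a rater column is constant (mu_20 or "
            "mu_02 is zero)"
        )
    return float(np.sqrt(central_moment(r, 2, 2) / (mu20 * mu02)))
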