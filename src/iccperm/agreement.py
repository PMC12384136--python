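"""Hypothesis tests of H0: ICC(2,1) = 0 against H1: ICC(2,1) > 0.

Four tests of the same one-sided point null, for two raters:

``f_test``
    F = MSB/MSW referred to an F(n-1, (n-1)(k-1)) distribution; the
    rho0 = 0 special case of the classical absolute-agreement ICC F test.
    Exact under bivariate normality, unreliable otherwise.
``fisher_z``
    z = atanh(rho_hat) * sqrt(n - 3) referred to the standard normal
    upper tail (Fisher's transformation with the Pearson-style variance
    1/(n - 3)).  Also normality-based.
``permute``
    Naive permutation test: shuffle the second rater's column B times and
    use the raw ICC estimate as the statistic.  Exact only under
    exchangeability, which dependence without correlation, or unequal
    marginals, can break.
``stu_permute``
    Studentized permutation test: same shuffles, statistic
    R = rho_hat / tau_n with the moment-based studentizer of
    :func:`iccperm.icc.tau_n`.  Asymptotically pivotal, so the test keeps
    its level under non-normal data where the other three fail.

Permutation convention (followed literally, no add-one smoothing):
``p = (1/B) * #{k : R_k > R_obs}`` with a *strict* inequality, so p can be
0 and ``p * B`` is always an integer.  Rejection elsewhere in the package
uses ``p <= alpha``.

Seed-stream contract: with ``rng = numpy.random.default_rng(seed)``, the B
permutations are the rows of
``rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)``, applied to the
second column only.  The naive and studentized tests of
:func:`run_all_tests` share this single stream so their contrast is not
confounded by permutation noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .icc import as_ratings, icc21, mean_squares

__all__ = [
    "TestResult",
    "f_test",
    "fisher_z_test",
    "permutation_test",
    "run_all_tests",
    "METHODS",
]

logger = logging.getLogger("iccperm")

#: canonical method labels, in reporting order
METHODS = ("f_test", "fisher_z", "permute", "stu_permute")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one agreement test.

    ``statistic`` is the F value, the Z value, rho_hat, or R = rho_hat/tau_n
    depending on ``method``.  ``n_permutations`` is 0 for the two
    deterministic tests, and ``seed`` is None for them.  ``error`` records a
    degenerate-input failure when the result was produced inside
    :func:`run_all_tests` (statistic and p are NaN in that case).
    """

    method: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    seed: int | None = None
    alpha: float = 0.05
    error: str | None = None

    @property
    def reject(self) -> bool:
        """Decision at the nominal level: reject H0 iff ``p_value <= alpha``."""
        return bool(self.p_value <= self.alpha)


def f_test(ratings, alpha: float = 0.05) -> TestResult:
    """Classical one-sided ANOVA F test of zero ICC(2,1).

    Raises :class:`DegenerateDataError` when MSW = 0 (perfect agreement
    leaves the statistic undefined; no p-value is fabricated).
    """
    r = as_ratings(ratings)
    ms = mean_squares(r)
    if ms.msw == 0.0:
        raise DegenerateDataError(
            "F test undefined: MSW = 0 (raters agree perfectly)"
        )
    f = ms.msb / ms.msw
    df1 = r.n - 1
    df2 = (r.n - 1) * (r.k - 1)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult("f_test", float(f), p, alpha=alpha)


def fisher_z_test(ratings, alpha: float = 0.05) -> TestResult:
    """Fisher's Z test for the intraclass correlation.

    ``z = atanh(rho_hat) * sqrt(n - 3)`` against the standard normal
    upper tail — the Pearson-style variance approximation
    ``Var(z) = 1/(n - 3)``, which is distinctly conservative at small n
    (its calibration under bivariate normal nulls is checked in the
    simulation tests).  Raises :class:`DegenerateDataError` at
    |rho_hat| = 1.

    Unlike a correlation, the ICC(2,1) estimate can fall below -1 (when
    MSW dominates both MSB and MSR); for this one-sided test that is
    maximal evidence against H1, so the statistic is reported as -inf
    with p = 1.
    """
    r = as_ratings(ratings)
    rho = icc21(r).rho_hat
    if rho < -1.0:
        return TestResult("fisher_z", float("-inf"), 1.0, alpha=alpha)
    if abs(rho) == 1.0:
        raise DegenerateDataError(
            "Fisher's Z undefined: |rho_hat| = 1 (atanh diverges)"
        )
    z = math.atanh(rho) * math.sqrt(r.n - 3)
    p = float(stats.norm.sf(z))
    return TestResult("fisher_z", float(z), p, alpha=alpha)


@dataclass(frozen=True)
class _PermCore:
    """Shared-shuffle permutation computations for one dataset."""

    icc_obs: float
    r_obs: float | None
    p_naive: float
    p_stu: float | None
    n_undefined: int


def _icc_from_cross(cross, sxx, syy, msr, n):
    """ICC(2,1) for datasets differing only in the pairing of the columns.

    When only the second column is permuted, the marginals, SST, the
    column means and hence MSR are invariant; every permuted ICC is a
    function of the centred cross-product ``cross = sum cx*cy(pi)``:

      MSB - MSW = 2*cross/(n-1),  MSB + MSW = (Sxx+Syy)/(n-1),
      MSW = (0.5*(Sxx+Syy) - cross)/(n-1).
    """
    nm1 = n - 1
    msw = (0.5 * (sxx + syy) - cross) / nm1
    denom = (sxx + syy) / nm1 + (2.0 / n) * (msr - msw)
    return (2.0 * cross / nm1) / denom


def _perm_core(x: np.ndarray, y: np.ndarray, B: int, rng: np.random.Generator) -> _PermCore:
    """Compute naive and studentized permutation p-values on shared shuffles."""
    n = x.size
    cx = x - x.mean()
    cy = y - y.mean()
    sxx = float(cx @ cx)
    syy = float(cy @ cy)
    if sxx == 0.0 and syy == 0.0 and np.all(x == y):
        raise DegenerateDataError("fully constant ratings matrix")
    # MSR from the (permutation-invariant) column means, k = 2
    msr = 0.5 * n * (x.mean() - y.mean()) ** 2

    idx = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)
    # The observed pairing is evaluated through the identical vectorized
    # route (prepended identity row): a permutation that reproduces the
    # observed pairing then yields a bitwise-equal statistic, so the strict
    # comparison cannot be flipped by last-ulp summation-order effects.
    cyp = cy[np.vstack([np.arange(n), idx])]
    cross_all = cyp @ cx
    cross2_all = (cyp * cyp) @ (cx * cx)
    cross_obs, cross = float(cross_all[0]), cross_all[1:]
    cross2_obs, cross2 = float(cross2_all[0]), cross2_all[1:]

    icc_obs = float(_icc_from_cross(cross_obs, sxx, syy, msr, n))
    icc_perm = _icc_from_cross(cross, sxx, syy, msr, n)
    p_naive = float(np.count_nonzero(icc_perm > icc_obs) / B)

    if sxx > 0.0 and syy > 0.0 and cross2_obs > 0.0:
        # tau_n^2 = mu22/(mu20*mu02) = cross2 * n / (Sxx * Syy)
        r_obs = icc_obs / math.sqrt(cross2_obs * n / (sxx * syy))
        tau2_perm = cross2 * n / (sxx * syy)
        defined = tau2_perm > 0.0
        n_undef = int(B - np.count_nonzero(defined))
        if n_undef:
            # counted as non-exceeding: conservative, and impossible for
            # continuous data
            logger.warning(
                "%d of %d permuted studentizers were undefined (tau=0); "
                "counted as non-exceeding", n_undef, B,
            )
        r_perm = np.full(B, -np.inf)
        r_perm[defined] = icc_perm[defined] / np.sqrt(tau2_perm[defined])
        p_stu = float(np.count_nonzero(r_perm > r_obs) / B)
    else:
        r_obs = None
        p_stu = None
        n_undef = 0

    return _PermCore(icc_obs, r_obs, p_naive, p_stu, n_undef)


def permutation_test(
    ratings,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    studentized: bool = True,
    alpha: float = 0.05,
) -> TestResult:
    """Permutation test of zero ICC(2,1), naive or studentized.

    Only the second rater's column is shuffled (B times); the statistic —
    rho_hat for the naive test, R = rho_hat/tau_n for the studentized one —
    is recomputed on each permuted pairing, MSR included.  See the module
    docstring for the p-value and seed-stream conventions.

    Parameters
    ----------
    ratings
        n x 2 ratings, ``n >= 3``.
    B
        Number of random permutations (>= 1).
    seed
        Seed or ``numpy.random.Generator``; fixed seed gives an identical
        p-value.
    studentized
        If True, use R = rho_hat/tau_n (requires both columns
        non-constant); otherwise the raw ICC estimate.
    """
    if B < 1:
        raise DegenerateDataError(f"B must be a positive integer, got {B}")
    r = as_ratings(ratings)
    x = r.values[:, 0]
    y = r.values[:, 1]
    if studentized:
        sxx = float(((x - x.mean()) ** 2).sum())
        syy = float(((y - y.mean()) ** 2).sum())
        if sxx == 0.0 or syy == 0.0:
            raise DegenerateDataError(
                "studentized statistic undefined: a rater column is constant"
            )
    rng = np.random.default_rng(seed)
    core = _perm_core(x, y, int(B), rng)
    seed_rec = seed if isinstance(seed, (int, np.integer)) or seed is None else None
    if studentized:
        if core.r_obs is None:
            raise DegenerateDataError(
                "studentized statistic undefined: observed tau_n is zero"
            )
        return TestResult(
            "stu_permute", core.r_obs, core.p_stu, int(B), seed_rec, alpha
        )
    return TestResult("permute", core.icc_obs, core.p_naive, int(B), seed_rec, alpha)


def run_all_tests(
    ratings,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Run all four agreement tests on one dataset.

    The two permutation tests share the same B shuffles (one seed stream),
    so the naive/studentized contrast is free of extra permutation noise.
    A method whose statistic is undefined for the data (e.g. the F test
    under perfect agreement) is reported as a :class:`TestResult` with NaN
    statistic/p and the failure message in ``error``; the list always has
    exactly four entries in the order of :data:`METHODS`.
    """
    r = as_ratings(ratings)
    results: list[TestResult] = []
    for name, fn in (("f_test", f_test), ("fisher_z", fisher_z_test)):
        try:
            results.append(fn(r, alpha=alpha))
        except DegenerateDataError as exc:
            results.append(
                TestResult(name, float("nan"), float("nan"), alpha=alpha,
                           error=str(exc))
            )
    rng = np.random.default_rng(seed)
    seed_rec = seed if isinstance(seed, (int, np.integer)) or seed is None else None
    try:
        core = _perm_core(r.values[:, 0], r.values[:, 1], int(B), rng)
    except DegenerateDataError as exc:
        for name in ("permute", "stu_permute"):
            results.append(
                TestResult(name, float("nan"), float("nan"), int(B), seed_rec,
                           alpha, error=str(exc))
            )
        return results
    results.append(
        TestResult("permute", core.icc_obs, core.p_naive, int(B), seed_rec, alpha)
    )
    if core.r_obs is None:
        results.append(
            TestResult("stu_permute", float("nan"), float("nan"), int(B),
                       seed_rec, alpha,
                       error="studentized statistic undefined: tau_n is zero")
        )
    else:
        results.append(
            TestResult("stu_permute", core.r_obs, core.p_stu, int(B), seed_rec,
                       alpha)
        )
    return results
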