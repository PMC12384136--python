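"""Independent brute-force oracles used to pin expected values.

Everything here is written as literal double loops over definitions — no
shared code with the package's fast paths — so these functions can serve
as independent references for the ANOVA decomposition, the ICC(2,1)
formula, the central cross-moments, the studentizer, and the permutation
p-values.
"""

import numpy as np


def brute_mean_squares(values):
    """Two-way ANOVA mean squares via explicit loops over squared deviations.

    The residual pool is computed directly from the interaction residuals
    x_ij - rowmean_i - colmean_j + grand (not by subtraction from SST),
    so this is a genuinely different computational route.
    """
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += v[i, j]
    grand /= n * k
    row_means = [sum(v[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(v[i, j] for i in range(n)) / n for j in range(k)]
    ssb = 0.0
    for i in range(n):
        ssb += k * (row_means[i] - grand) ** 2
    ssr = 0.0
    for j in range(k):
        ssr += n * (col_means[j] - grand) ** 2
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (v[i, j] - row_means[i] - col_means[j] + grand) ** 2
    msb = ssb / (n - 1)
    msr = ssr / (k - 1)
    msw = sse / ((n - 1) * (k - 1))
    return msb, msw, msr


def brute_icc21(values):
    """Direct transcription of the ICC(2,1) formula on brute mean squares."""
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    msb, msw, msr = brute_mean_squares(v)
    return (msb - msw) / (msb + (k - 1) * msw + (k / n) * (msr - msw))


def brute_central_moment(values, p, q):
    """mu_pq as a literal sum with divisor n."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    x1bar = sum(v[i, 0] for i in range(n)) / n
    x2bar = sum(v[i, 1] for i in range(n)) / n
    total = 0.0
    for i in range(n):
        total += (v[i, 0] - x1bar) ** p * (v[i, 1] - x2bar) ** q
    return total / n


def brute_tau(values):
    """sqrt(mu_22 / (mu_20 * mu_02)) from the brute moments."""
    m22 = brute_central_moment(values, 2, 2)
    m20 = brute_central_moment(values, 2, 0)
    m02 = brute_central_moment(values, 0, 2)
    return np.sqrt(m22 / (m20 * m02))


def oracle_permutation_pvalues(values, B, seed):
    """Naive-loop permutation p-values (raw ICC and studentized statistic).

    Uses the package's documented seed-stream contract to draw the same
    permutation indices — rows of ``rng.permuted`` of a tiled arange —
    but recomputes every permuted statistic from scratch with the brute
    oracles above.  Returns ``(p_naive, p_studentized)``.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)

    icc_obs = brute_icc21(v)
    r_obs = icc_obs / brute_tau(v)
    exceed_naive = 0
    exceed_stu = 0
    for b in range(B):
        perm = np.column_stack([v[:, 0], v[idx[b], 1]])
        icc_b = brute_icc21(perm)
        if icc_b > icc_obs:
            exceed_naive += 1
        tau_b = brute_tau(perm)
        if tau_b > 0 and icc_b / tau_b > r_obs:
            exceed_stu += 1
    return exceed_naive / B, exceed_stu / B
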