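"""Unit and property tests for the ANOVA decomposition and ICC(2,1)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iccperm import (
    DegenerateDataError,
    InvalidRatingsError,
    RatingsMatrix,
    central_moment,
    icc21,
    mean_squares,
    tau_n,
)
from oracles import brute_central_moment, brute_icc21, brute_mean_squares

INT_4x2 = np.array([[1, 3], [2, 0], [4, 5], [7, 2]], dtype=float)
INT_5x2 = np.array([[1, 2], [2, 2], [3, 4], [4, 4], [5, 6]], dtype=float)


def matrices(min_n=3, max_n=25):
    """Random finite ratings matrices with moderate magnitudes."""
    return st.integers(min_n, max_n).flatmap(
        lambda n: st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False, width=32),
                st.floats(-100, 100, allow_nan=False, width=32),
            ),
            min_size=n, max_size=n,
        )
    ).map(lambda rows: np.array(rows, dtype=float))


class TestRatingsValidation:
    def test_rejects_too_few_subjects(self):
        with pytest.raises(InvalidRatingsError):
            RatingsMatrix(np.ones((2, 2)))

    def test_rejects_wrong_width_and_nonfinite(self):
        with pytest.raises(InvalidRatingsError):
            RatingsMatrix(np.ones((5, 3)))
        with pytest.raises(InvalidRatingsError):
            RatingsMatrix(np.array([[1, 2], [3, np.nan], [5, 6]]))


class TestMeanSquares:
    def test_identical_nonconstant_columns_have_no_rater_or_residual_variance(self):
        v = np.column_stack([[1, 2, 3, 4], [1, 2, 3, 4]])
        ms = mean_squares(v)
        assert ms.msw == pytest.approx(0.0, abs=1e-12)
        assert ms.msr == pytest.approx(0.0, abs=1e-12)
        assert ms.msb > 0

    def test_constant_matrix_is_fully_degenerate(self):
        ms = mean_squares(np.full((6, 2), 3.7))
        assert ms.msb == pytest.approx(0.0, abs=1e-20)
        assert ms.msw == pytest.approx(0.0, abs=1e-20)
        assert ms.msr == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("values", [INT_4x2, INT_5x2])
    def test_matches_brute_force_anova(self, values):
        ms = mean_squares(values)
        msb, msw, msr = brute_mean_squares(values)
        assert ms.msb == pytest.approx(msb, rel=1e-12)
        assert ms.msw == pytest.approx(msw, rel=1e-12, abs=1e-12)
        assert ms.msr == pytest.approx(msr, rel=1e-12, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(matrices())
    def test_anova_identity(self, v):
        """SSB + SSR + SSE = SST within 1e-10 relative tolerance."""
        ms = mean_squares(v)
        n, k = v.shape[0], 2
        pooled = ms.msb * (n - 1) + ms.msr * (k - 1) + ms.msw * (n - 1) * (k - 1)
        sst = ((v - v.mean()) ** 2).sum()
        assert pooled == pytest.approx(sst, rel=1e-10, abs=1e-8)


class TestICC21:
    def test_perfect_agreement_gives_one(self):
        v = np.column_stack([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert icc21(v).rho_hat == pytest.approx(1.0)

    def test_perfect_disagreement_is_negative(self):
        v = np.column_stack([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]])
        assert icc21(v).rho_hat < 0

    def test_matches_brute_force_oracle(self, gaussian_10x2):
        assert icc21(gaussian_10x2).rho_hat == pytest.approx(
            brute_icc21(gaussian_10x2), rel=1e-12
        )

    def test_constant_matrix_raises(self):
        with pytest.raises(DegenerateDataError):
            icc21(np.full((5, 2), 2.0))

    def test_u_hat_and_var_classical_undefined_when_msb_equals_msw(self):
        # cx = (1,-1,0) orthogonal to cy = (1,1,-2) makes MSB = MSW exactly
        v = np.column_stack([[1.0, -1.0, 0.0], [1.0, 1.0, -2.0]])
        est = icc21(v)
        assert est.rho_hat == pytest.approx(0.0, abs=1e-12)
        assert est.u_hat is None and est.var_classical is None

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(matrices(), st.floats(-50, 50, allow_nan=False),
           st.floats(0.1, 10, allow_nan=False))
    def test_location_scale_equivariance_and_rater_symmetry(self, v, shift, scale):
        try:
            base = icc21(v).rho_hat
        except DegenerateDataError:
            return
        assert icc21(v + shift).rho_hat == pytest.approx(base, rel=1e-6, abs=1e-8)
        assert icc21(v * scale).rho_hat == pytest.approx(base, rel=1e-6, abs=1e-8)
        assert icc21(v[:, ::-1]).rho_hat == pytest.approx(base, rel=1e-6, abs=1e-8)

    def test_consistency_under_generative_model(self):
        """Mean estimate over replicates approaches sigma_s^2 / total."""
        sig_s2, sig_r2, sig_e2 = 2.0, 0.5, 1.0
        true_icc = sig_s2 / (sig_s2 + sig_r2 + sig_e2)
        rng = np.random.default_rng(7)
        n = 2000
        estimates = []
        for _ in range(200):
            s = rng.normal(0, np.sqrt(sig_s2), n)[:, None]
            r = rng.normal(0, np.sqrt(sig_r2), 2)[None, :]
            e = rng.normal(0, np.sqrt(sig_e2), (n, 2))
            estimates.append(icc21(10.0 + s + r + e).rho_hat)
        assert np.mean(estimates) == pytest.approx(true_icc, abs=0.02)


class TestMoments:
    def test_trivial_orders(self, gaussian_10x2):
        assert central_moment(gaussian_10x2, 0, 0) == pytest.approx(1.0)
        assert central_moment(gaussian_10x2, 1, 0) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("p,q", [(2, 2), (2, 0), (0, 2), (3, 1)])
    def test_matches_double_loop(self, p, q):
        assert central_moment(INT_4x2, p, q) == pytest.approx(
            brute_central_moment(INT_4x2, p, q), rel=1e-12
        )

    def test_rejects_bad_orders(self, gaussian_10x2):
        with pytest.raises(InvalidRatingsError):
            central_moment(gaussian_10x2, -1, 0)
        with pytest.raises(InvalidRatingsError):
            central_moment(gaussian_10x2, 1.5, 0)


class TestTau:
    def test_constant_column_raises(self):
        v = np.column_stack([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(DegenerateDataError):
            tau_n(v)

    def test_matches_brute_moment_ratio(self):
        m22 = brute_central_moment(INT_4x2, 2, 2)
        m20 = brute_central_moment(INT_4x2, 2, 0)
        m02 = brute_central_moment(INT_4x2, 0, 2)
        assert tau_n(INT_4x2) == pytest.approx(np.sqrt(m22 / (m20 * m02)), rel=1e-12)

    def test_tends_to_one_for_independent_normals(self):
        """Law of large numbers: tau_n -> 1 under independence."""
        rng = np.random.default_rng(11)
        taus = [tau_n(rng.standard_normal((10_000, 2))) for _ in range(20)]
        assert np.mean(taus) == pytest.approx(1.0, abs=0.05)
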