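import numpy as np
import pytest
from scipy import optimize

from mgx.io import OTUTableError
from mgx.scaling import (
    DARFit,
    compare_scaling_param,
    dar_curve,
    fit_dar,
    fit_power_law,
    mad,
    ple_points,
)
from mgx.synthetic import generate_heterogeneity_cohort, generate_power_law_points

from conftest import make_table, split_halves


class TestPLEPoints:
    def test_type_I_per_sample_arithmetic(self):
        t = make_table(np.array([[2, 1, 1], [4, 5, 2], [6, 9, 4]]))
        pts = ple_points(t, "I")
        assert pts[0] == pytest.approx([4.0, 4.0])  # mean 4, var ddof=1 of (2,4,6)
        assert pts[1] == pytest.approx([5.0, 16.0])

    def test_type_III_per_taxon_arithmetic(self):
        t = make_table(np.array([[1, 3], [2, 6], [10, 4], [4, 4.5]]))
        pts = ple_points(t, "III")
        assert pts[0] == pytest.approx([2.0, 2.0])  # taxon (1,3) across samples

    def test_degenerate_identical_columns(self):
        t = make_table(np.tile([[1.0], [2.0], [3.0]], (1, 4)))
        with pytest.raises(OTUTableError):
            ple_points(t, "III")  # all V=0, everything excluded


class TestFitPowerLaw:
    def test_noiseless_recovery(self):
        pts = generate_power_law_points(2.0, 1.8, n_points=50, noise_sd=0.0)
        fit = fit_power_law(pts)
        assert fit.a == pytest.approx(2.0, rel=1e-9)
        assert fit.b == pytest.approx(1.8, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_exponent(self):
        pts = generate_power_law_points(3.0, 0.0, n_points=10, noise_sd=0.0)
        assert fit_power_law(pts).b == pytest.approx(0.0, abs=1e-9)

    def test_two_points_rejected(self):
        with pytest.raises(OTUTableError):
            fit_power_law([(1, 1), (2, 4)])

    def test_all_m_equal_singular(self):
        with pytest.raises(OTUTableError):
            fit_power_law([(2, 1), (2, 2), (2, 3)])

    def test_rescaling_equivariance(self):
        """Under m -> k*m, the exponent is unchanged and the prefactor
        transforms as a' = a * k^(-b)."""
        pts = generate_power_law_points(2.0, 1.8, n_points=40, noise_sd=0.05, seed=3)
        fit = fit_power_law(pts)
        k = 7.0
        scaled = np.column_stack([pts[:, 0] * k, pts[:, 1]])
        fit2 = fit_power_law(scaled)
        assert fit2.b == pytest.approx(fit.b, rel=1e-9)
        assert fit2.a == pytest.approx(fit.a * k**-fit.b, rel=1e-9)

    def test_noisy_recovery_over_replicates(self):
        errs = [
            abs(fit_power_law(generate_power_law_points(2.0, 1.8, 80, 0.1, seed=r)).b - 1.8)
            for r in range(50)
        ]
        assert np.mean(errs) < 0.05


class TestCompareScalingParam:
    def test_identical_tables_p_one(self):
        t = generate_heterogeneity_cohort(2.0, 1.8, 40, 30, seed=0)
        res = compare_scaling_param(t, t, n_perm=50, seed=0)
        assert res.p_value == pytest.approx(1.0)
        assert res.observed == 0.0

    def test_planted_difference_detected(self):
        # a wide mean-abundance range pins down each cohort's exponent
        a = generate_heterogeneity_cohort(2.0, 1.5, 80, 40, m_range=(20, 2000), seed=1)
        b = generate_heterogeneity_cohort(2.0, 2.0, 80, 40, m_range=(20, 2000), seed=2)
        res = compare_scaling_param(a, b, n_perm=99, seed=0)
        assert res.p_value <= 0.05

    def test_seed_determinism(self):
        t = generate_heterogeneity_cohort(2.0, 1.8, 60, 30, seed=4)
        a, b = split_halves(t)
        r1 = compare_scaling_param(a, b, n_perm=30, seed=9)
        r2 = compare_scaling_param(a, b, n_perm=30, seed=9)
        assert np.array_equal(r1.null_values, r2.null_values)


class TestDAR:
    def test_q0_curve_non_decreasing(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 20, size=(30, 8)))
        curve = dar_curve(t, 0, n_orders=20, seed=1)
        assert np.all(np.diff(curve[:, 1]) >= -1e-9)

    def test_identical_samples_flat_curve(self):
        t = make_table(np.tile([[3.0], [5.0], [1.0]], (1, 6)))
        curve = dar_curve(t, 1, n_orders=5, seed=0)
        np.testing.assert_allclose(curve[:, 1], curve[0, 1], rtol=1e-9)

    def test_curve_deterministic_and_convergent(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.integers(0, 30, size=(40, 12)))
        c1 = dar_curve(t, 1, n_orders=1, seed=3)
        c2 = dar_curve(t, 1, n_orders=1, seed=3)
        np.testing.assert_array_equal(c1, c2)
        c50 = dar_curve(t, 1, n_orders=50, seed=3)
        c100 = dar_curve(t, 1, n_orders=100, seed=4)
        assert np.max(np.abs(c50[:, 1] - c100[:, 1]) / c100[:, 1]) < 0.05

    def test_plec_exact_recovery(self):
        A = np.arange(1.0, 21.0)
        D = 10.0 * A**0.4 * np.exp(-0.01 * A)
        fit = fit_dar(np.column_stack([A, D]), "PLEC")
        assert fit.c == pytest.approx(10.0, rel=1e-9)
        assert fit.z == pytest.approx(0.4, abs=1e-9)
        assert fit.d == pytest.approx(-0.01, abs=1e-9)

    def test_plec_on_pl_data_gives_zero_cutoff(self):
        A = np.arange(1.0, 21.0)
        D = 5.0 * A**0.3
        fit = fit_dar(np.column_stack([A, D]), "PLEC")
        assert fit.d == pytest.approx(0.0, abs=1e-9)
        pl = fit_dar(np.column_stack([A, D]), "PL")
        assert pl.z == pytest.approx(0.3, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(OTUTableError):
            fit_dar([(1, 2), (2, 3), (3, 4)], "PL")


class TestMAD:
    def test_closed_form_plug_in(self):
        fit = DARFit("PLEC", 10.0, 0.4, -0.01, 1.0, np.empty((0, 2)))
        est = mad(fit)
        assert est.A_max == pytest.approx(40.0)
        assert est.D_max == pytest.approx(10.0 * 40**0.4 * np.exp(-0.4))

    def test_agrees_with_numerical_maximization(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            c = rng.uniform(1, 50)
            z = rng.uniform(0.05, 1.5)
            d = -rng.uniform(0.001, 0.1)
            est = mad(DARFit("PLEC", c, z, d, 1.0, np.empty((0, 2))))
            res = optimize.minimize_scalar(
                lambda A: -c * A**z * np.exp(d * A),
                bounds=(1e-6, 10 * est.A_max), method="bounded",
                options={"xatol": 1e-10},
            )
            assert -res.fun == pytest.approx(est.D_max, rel=1e-6)
            assert res.x == pytest.approx(est.A_max, rel=1e-4)

    def test_positive_cutoff_rejected(self):
        with pytest.raises(OTUTableError, match="no finite maximum"):
            mad(DARFit("PLEC", 10.0, 0.4, 0.01, 1.0, np.empty((0, 2))))
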