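import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.special

import closurebench as cb
from closurebench import analysis


def full_grid_records(values=None, rng=None, noise=0.0, slope=0.0):
    """The 768-row disordered covariate grid with a synthetic response."""
    rows = []
    for tg, bg, ctr, el, tl in itertools.product(
            range(0, 120, 15), ("white", "black"),
            ((150.0, 150.0), (134.0, 134.0)), (3, 8, 13, 18, 24, 29),
            (72, 144, 216, 288)):
        rows.append({"variant": "segments", "theta_global": float(tg),
                     "edge_length": float(el), "theta_local": float(tl),
                     "background": bg, "center_x": ctr[0], "center_y": ctr[1]})
    df = pd.DataFrame(rows)
    if values is not None:
        df["value"] = values
    else:
        df["value"] = slope * df["edge_length"]
        if noise:
            df["value"] += rng.normal(0, noise, size=len(df))
    return df


def ols_normal_equations(X, y):
    """Independent textbook OLS: beta = (X'X)^-1 X'y, classical SEs."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


def t_sf_by_quadrature(t, df):
    """P(T > t) by numerical integration of the t density."""
    c = scipy.special.gamma((df + 1) / 2) / (
        np.sqrt(df * np.pi) * scipy.special.gamma(df / 2))
    dens = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    val, _ = scipy.integrate.quad(dens, t, np.inf)
    return val


class TestClosureRegression:
    def test_constant_response_is_degenerate(self):
        df = full_grid_records(values=0.5)
        rep = cb.fit_closure_regression(df)
        assert rep.degenerate
        assert rep.edge_length_slope == 0.0
        assert rep.n == 768

    def test_noiseless_linear_recovery(self):
        df = full_grid_records(slope=0.003)
        rep = cb.fit_closure_regression(df)
        assert rep.edge_length_slope == pytest.approx(0.003, abs=1e-8)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-8)
        assert not rep.degenerate

    def test_matches_normal_equations_oracle(self, rng):
        # small random designs, n <= 50, p <= 6
        for _ in range(5):
            n = int(rng.integers(20, 50))
            df = pd.DataFrame({
                "theta_global": rng.choice([0.0, 15.0, 30.0], n),
                "edge_length": rng.choice([3.0, 13.0, 29.0], n),
                "theta_local": rng.choice([72.0, 144.0], n),
                "background": rng.choice(["white", "black"], n),
                "center_x": 150.0, "center_y": 150.0,
                "value": rng.normal(size=n),
            })
            rep = cb.fit_closure_regression(df)
            X = analysis._design_matrix(df).to_numpy()
            beta, se = ols_normal_equations(X, df["value"].to_numpy())
            cols = list(analysis._design_matrix(df).columns)
            k = cols.index("edge_length")
            assert rep.edge_length_slope == pytest.approx(beta[k], abs=1e-8)
            assert rep.coefficients["edge_length"][1] == pytest.approx(
                se[k], abs=1e-8)

    def test_slope_invariant_to_dummy_reference(self, rng):
        """Relabeling factor levels (hence reference choice) leaves the slope."""
        df = full_grid_records(rng=rng, noise=0.05, slope=0.003)
        rep1 = cb.fit_closure_regression(df)
        relabeled = df.copy()
        relabeled["background"] = relabeled["background"].map(
            {"white": "z_white", "black": "a_black"})
        rep2 = cb.fit_closure_regression(relabeled)
        assert rep1.edge_length_slope == pytest.approx(rep2.edge_length_slope,
                                                       abs=1e-10)
        assert rep1.adjusted_r_squared == pytest.approx(rep2.adjusted_r_squared,
                                                        abs=1e-10)

    def test_confidence_interval_coverage(self):
        """b-hat falls inside the analytic 99% CI ~99% of the time."""
        import scipy.stats
        true_slope, sigma = 0.003, 0.05
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = full_grid_records(rng=rng, noise=sigma, slope=true_slope)
            rep = cb.fit_closure_regression(df)
            se = rep.coefficients["edge_length"][1]
            dof = rep.n - len(rep.coefficients)
            half = scipy.stats.t.ppf(0.995, dof) * se
            hits += abs(rep.edge_length_slope - true_slope) <= half
        assert hits / n_rep == pytest.approx(0.99, abs=0.03)

    def test_planted_sign_recovered(self):
        """The fitted slope sign matches the planted sign in >= 95% of runs."""
        good = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            sign = 1 if seed % 2 == 0 else -1
            df = full_grid_records(rng=rng, noise=0.05, slope=sign * 0.001)
            rep = cb.fit_closure_regression(df)
            good += np.sign(rep.edge_length_slope) == sign
        assert good >= 95

    def test_requires_two_edge_lengths(self):
        df = full_grid_records(slope=0.01)
        with pytest.raises(ValueError):
            cb.fit_closure_regression(df[df.edge_length == 3.0])

    def test_rank_deficiency_names_terms(self):
        df = full_grid_records(slope=0.01)
        # make background a copy of center -> perfectly collinear dummies
        df["background"] = np.where(df["center_x"] == 150.0, "white", "black")
        with pytest.raises(ValueError, match="collinear"):
            cb.fit_closure_regression(df)


class TestTTests:
    def make_records(self, groups):
        rows = []
        for el, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append({"set_id": f"s{el}-{i}", "edge_length": float(el),
                             "value": float(v)})
        return pd.DataFrame(rows)

    def test_symmetric_values_two_sided(self):
        rec = self.make_records({5: [-2, -1, 0, 1, 2]})
        (rep,) = cb.t_tests_by_edge_length(rec, alternative="two-sided")
        assert rep.t == pytest.approx(0.0, abs=1e-12)
        assert rep.p == pytest.approx(1.0, abs=1e-12)

    def test_textbook_example_against_density_quadrature(self):
        rec = self.make_records({10: [1, 2, 3]})
        (rep,) = cb.t_tests_by_edge_length(rec, alternative="two-sided")
        assert rep.t == pytest.approx(2 * np.sqrt(3), abs=1e-10)   # 3.4641
        assert rep.df == 2
        p_oracle = 2 * t_sf_by_quadrature(rep.t, 2)
        assert rep.p == pytest.approx(p_oracle, abs=1e-8)
        assert rep.p == pytest.approx(0.0742, abs=5e-4)

    def test_one_sided_halves_the_p(self):
        rec = self.make_records({10: [1, 2, 3]})
        (rep,) = cb.t_tests_by_edge_length(rec, alternative="greater")
        assert rep.p == pytest.approx(t_sf_by_quadrature(2 * np.sqrt(3), 2),
                                      abs=1e-8)

    def test_full_grid_gives_nine_tests_df31(self, line_sets):
        ext = cb.make_toy_extractor(2, output_dim=32, nonlinear=True)
        records = cb.score_exp2(line_sets, ext)
        tests = cb.t_tests_by_edge_length(records)
        assert len(tests) == 9
        assert all(t.df == 31 and t.n == 32 for t in tests)
        assert [t.edge_length for t in tests] == sorted(
            float(e) for e in (5, 10, 14, 19, 24, 29, 33, 38, 43))

    def test_zero_variance_group_is_an_error(self):
        rec = self.make_records({5: [0.3, 0.3, 0.3], 10: [0, 1, 2]})
        with pytest.raises(ValueError, match="5"):
            cb.t_tests_by_edge_length(rec)


class TestRemovalFraction:
    def test_printed_sequence(self):
        got = [round(cb.removal_fraction(95, e), 1)
               for e in (5, 10, 14, 19, 24, 29, 33, 38, 43)]
        assert got == [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]

    def test_exact_rational_levels(self):
        assert cb.removal_fraction(95, 19) == 57 / 95 == 0.6
        assert cb.removal_fraction(95, 38) == 19 / 95 == 0.2

    def test_limit_vanishes_as_arms_meet(self):
        s = 95.0
        for eps in (1.0, 0.1, 0.001):
            assert cb.removal_fraction(s, s / 2 - eps) == pytest.approx(
                2 * eps / s, abs=1e-12)

    def test_no_gap_is_an_error(self):
        with pytest.raises(ValueError):
            cb.removal_fraction(95, 47.5)
        with pytest.raises(ValueError):
            cb.removal_fraction(95, 60)


class TestVerdicts:
    def reg(self, p, adj):
        return analysis.RegressionReport(
            coefficients={"edge_length": (0.004, 0.001, p)},
            edge_length_slope=0.004, edge_length_p=p, r_squared=adj + 0.02,
            adjusted_r_squared=adj, model_p=1e-6, n=768)

    def test_insignificant_slope_is_no(self):
        v = cb.table1_verdict(reg=self.reg(0.5, 0.45), method="similarity")
        assert v.present == "no" and v.r_threshold is None

    def test_strong_effect(self):
        v = cb.table1_verdict(reg=self.reg(1e-5, 0.45), method="similarity")
        assert v.present == "yes_strong"
        assert v.effect_size_label == "moderate_or_large"

    def test_small_and_intermediate_labels(self):
        v = cb.table1_verdict(reg=self.reg(1e-5, 0.2), method="similarity")
        assert v.present == "yes_small" and v.effect_size_label == "small"
        v = cb.table1_verdict(reg=self.reg(1e-5, 0.35), method="similarity")
        assert v.effect_size_label == "small_to_moderate"

    def ttest(self, el, mean, p):
        return analysis.TTestReport(edge_length=el, n=32, mean=mean,
                                    t=3.0, df=31, p=p, alternative="greater")

    def test_ce_threshold_at_smallest_significant_edge(self):
        tests = [self.ttest(5, -0.1, 0.9), self.ttest(19, 0.02, 0.2),
                 self.ttest(29, 0.2, 1e-4), self.ttest(43, 0.3, 1e-6)]
        v = cb.table1_verdict(tests=tests, method="CE")
        assert v.present == "yes_strong"
        assert v.r_threshold == round(cb.removal_fraction(95, 29), 1) == 0.4

    def test_ce_absent(self):
        tests = [self.ttest(5, -0.1, 0.9), self.ttest(43, -0.2, 0.99)]
        v = cb.table1_verdict(tests=tests, method="CE")
        assert v.present == "no" and v.r_threshold is None
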