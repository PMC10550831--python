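"""Fisher/Welch baseline tests, IRLS logistic regression, VIF."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cyp2c19pgx import (
    ExposureCoding,
    SimulationConfig,
    baseline_comparison,
    fisher_exact_two_sided,
    fit_logistic,
    metabolizer_association,
    vif,
    welch_t_from_summary,
)
from cyp2c19pgx.simulate import (
    OutcomeModel,
    sample_covariates,
    sample_diplotypes,
    sample_outcome,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact-rational enumeration over all tables with
    the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def mass(x):  # P(a = x | margins), hypergeometric
        return Fraction(
            math.comb(c1, x) * math.comb(n - c1, r1 - x), math.comb(n, r1)
        )

    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    p_obs = mass(a)
    return float(sum(mass(x) for x in range(lo, hi + 1) if mass(x) <= p_obs))


def light_rows(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Analysis rows straight from the generator's sampling operations
    (no event-table round trip) for simulation studies."""
    rng = np.random.default_rng(seed)
    dipl = sample_diplotypes(config, rng)
    cov = sample_covariates(config, rng, config.n)
    rows = pd.concat([dipl, cov], axis=1)
    outcome, _, _ = sample_outcome(config, rng, rows)
    rows["recurrent_mi"] = outcome
    rows = rows.rename(columns={"class": "metabolizer"})
    rows["lof_count"] = pd.array(rows["lof_count"], dtype="Int64")
    rows["pci"] = pd.array(rows["pci"], dtype="boolean")
    return rows


class TestFisher:
    def test_zero_margin_degenerate(self):
        res = fisher_exact_two_sided(0, 10, 0, 20)
        assert res.p_value == 1.0 and res.degenerate

    def test_negative_error(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    def test_small_table_matches_enumeration(self):
        assert fisher_exact_two_sided(2, 3, 4, 1).p_value == pytest.approx(
            fisher_oracle(2, 3, 4, 1), abs=1e-12
        )

    def test_swap_invariance(self):
        p1 = fisher_exact_two_sided(3, 36, 8, 650).p_value
        # simultaneous row and column swap
        p2 = fisher_exact_two_sided(650, 8, 36, 3).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_oracle_equivalence_random_tables(self):
        """Two-sided p equals exact enumeration for totals <= 60."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            cells = rng.multinomial(int(rng.integers(4, 61)), [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_two_sided(a, b, c, d).p_value == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            ), (a, b, c, d)


class TestWelch:
    def test_identical_summaries(self):
        assert welch_t_from_summary(5, 1, 50, 5, 1, 50).p_value == pytest.approx(1.0)

    def test_age_difference_significant(self):
        # 60 +/- 12 (n=658) vs 67 +/- 9 (n=39)
        assert welch_t_from_summary(60, 12, 658, 67, 9, 39).p_value < 0.001

    def test_closed_form_oracle(self):
        """Hand-computed Welch statistic and Satterthwaite df."""
        m1, s1, n1, m2, s2, n2 = 0.0, 1.0, 50, 1.0, 1.0, 50
        se2 = s1**2 / n1 + s2**2 / n2
        t = (m1 - m2) / math.sqrt(se2)
        df = se2**2 / (
            (s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1)
        )
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(t), df)
        res = welch_t_from_summary(m1, s1, n1, m2, s2, n2)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(0, 1, 1, 1, 1, 50)
        with pytest.raises(ValueError):
            welch_t_from_summary(0, 0, 50, 1, 1, 50)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 39 + [0] * 658)
        x = np.concatenate([np.zeros(350), np.ones(347)])  # irrelevant covariate
        rng = np.random.default_rng(0)
        rng.shuffle(x)
        fit = fit_logistic(x[:, None], y, term_names=["x"])
        assert fit.coef[0] + fit.coef[1] * x.mean() == pytest.approx(
            math.log(39 / 658), abs=0.05
        )
        pure = fit_logistic(
            np.column_stack([x, 1 - x]), y, term_names=["a", "b"], add_intercept=False
        )
        # with a saturated two-level design each coefficient is the group log-odds
        for j, grp in enumerate((x == 1, x == 0)):
            k, n = y[grp].sum(), grp.sum()
            assert pure.coef[j] == pytest.approx(math.log(k / (n - k)), abs=1e-6)

    def test_matches_direct_likelihood_maximization(self):
        """IRLS equals a derivative-free maximizer of the log-likelihood on a
        small two-covariate design (1e-4)."""
        X = np.array(
            [
                [0.0, 1.0], [0.0, 0.0], [1.0, 0.0], [1.0, 1.0],
                [0.0, 1.0], [1.0, 0.0], [0.0, 0.0], [1.0, 1.0],
            ]
        )
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        fit = fit_logistic(X, y, term_names=["x1", "x2"])
        assert fit.converged

        Xd = np.column_stack([np.ones(8), X])

        def negll(beta):
            eta = Xd @ beta
            return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

        res = optimize.minimize(
            negll, np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000},
        )
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-4)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        X = rng.standard_normal((300, 3))
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + X @ [0.5, -1.0, 0.0])))).astype(int)
        fit = fit_logistic(X, y, term_names=["a", "b", "c"])
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)

    def test_or_ci_consistency(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 2))
        y = (rng.random(100) < 0.3).astype(int)
        fit = fit_logistic(X, y)
        np.testing.assert_allclose(fit.odds_ratio, np.exp(fit.coef))
        np.testing.assert_allclose(fit.ci_lower, np.exp(fit.coef - 1.96 * fit.se))
        np.testing.assert_allclose(fit.ci_upper, np.exp(fit.coef + 1.96 * fit.se))

    def test_separation_flagged(self):
        x = np.array([0.0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 0, 1, 1, 1])
        noise = np.array([0.1, -0.2, 0.3, 0.2, -0.1, 0.4])
        fit = fit_logistic(np.column_stack([x, noise]), y)
        assert fit.separation and not fit.converged

    def test_constant_column_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="constant column"):
            fit_logistic(X, y, term_names=["const_col", "x"])

    def test_missing_values_error(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="missing"):
            fit_logistic(X, np.array([0, 1]))


class TestMetabolizerAssociation:
    def test_lof_dose_excludes_um_exactly(self):
        cfg = SimulationConfig(n=4000, seed=77, pci_missing_count=0)
        rows = light_rows(cfg, 77)
        n_um = int((rows["metabolizer"] == "UM").sum())
        assert n_um > 0
        fit = metabolizer_association(rows, ExposureCoding("lof_dose"))
        assert fit.dropped["um_excluded"] == n_um
        assert fit.n_used == len(rows) - n_um
        assert "UM" not in fit.terms

    def test_pci_missing_rows_dropped(self):
        cfg = SimulationConfig(n=3000, seed=5, pci_missing_count=14)
        rows = light_rows(cfg, 5)
        rows.loc[rows.index[:14], "pci"] = pd.NA
        fit = metabolizer_association(rows, ExposureCoding("categorical"))
        assert fit.dropped["pci_missing"] == 14
        assert fit.n_used == len(rows) - 14

    def test_single_outcome_class_error(self):
        cfg = SimulationConfig(n=200, seed=3, pci_missing_count=0)
        rows = light_rows(cfg, 3)
        rows["recurrent_mi"] = False
        with pytest.raises(ValueError, match="outcome classes"):
            metabolizer_association(rows)

    def test_null_coverage(self):
        """With all exposure effects zero, each exposure CI covers OR = 1 in
        at least 90% of replicates (nominal 95%)."""
        null = OutcomeModel(class_log_or={}, age_log_or_per_year=0.0)
        counts = {"PM": 0, "IM": 0, "UM": 0}
        reps = 100
        done = 0
        for i in range(reps):
            cfg = SimulationConfig(
                n=5000, seed=1000 + i, outcome=null, pci_missing_count=0
            )
            rows = light_rows(cfg, 1000 + i)
            fit = metabolizer_association(rows, ExposureCoding("categorical"))
            if not fit.converged:
                continue
            done += 1
            for term in counts:
                t = fit.term(term)
                if t["ci_lower"] <= 1.0 <= t["ci_upper"]:
                    counts[term] += 1
        assert done >= 95
        for term, k in counts.items():
            assert k / done >= 0.90, (term, k, done)

    def test_parameter_recovery_within_3se(self):
        """Configured exposure log-ORs are inside +/-3 SE in >= 95% of
        replicates at n = 5,000."""
        truth = {"PM": math.log(3.12), "IM": math.log(1.47), "UM": math.log(10.49)}
        reps, ok, done = 200, 0, 0
        for i in range(reps):
            cfg = SimulationConfig(n=5000, seed=30000 + i, pci_missing_count=0)
            rows = light_rows(cfg, 30000 + i)
            fit = metabolizer_association(rows, ExposureCoding("categorical"))
            if not fit.converged:
                continue
            done += 1
            if all(
                abs(fit.term(t)["coef"] - truth[t]) <= 3 * fit.term(t)["se"]
                for t in truth
            ):
                ok += 1
        assert done >= 190
        assert ok / done >= 0.95


class TestVif:
    def test_orthogonal_columns(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        out = vif(X)
        np.testing.assert_allclose(out["vif"], [1.0, 1.0])
        assert not out["flag"].any()

    def test_duplicated_column_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        out = vif(X)
        assert np.isinf(out["vif"]).all() and out["flag"].all()

    def test_correlated_pair_closed_form(self):
        """Two columns with correlation r have VIF = 1/(1-r^2) each."""
        rng = np.random.default_rng(9)
        a = rng.standard_normal(20000)
        b = 0.9 * a + math.sqrt(1 - 0.81) * rng.standard_normal(20000)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        np.testing.assert_allclose(out["vif"], [1 / (1 - r2)] * 2, rtol=1e-10)
        assert out["vif"].iloc[0] == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": [1.0, 2]}))


def table2_margin_rows() -> pd.DataFrame:
    """A 697-row frame reproducing, column by column, the printed per-group
    margins of the acute-MI clopidogrel cohort (39 recurrent, 658 without).
    Fisher tests depend only on these margins, so the joint arrangement is
    immaterial."""

    def col(yes_cases, n_cases, yes_controls, n_controls):
        return np.concatenate(
            [
                np.ones(yes_cases, bool), np.zeros(n_cases - yes_cases, bool),
                np.ones(yes_controls, bool), np.zeros(n_controls - yes_controls, bool),
            ]
        )

    n_cases, n_controls = 39, 658
    df = pd.DataFrame(
        {
            "recurrent_mi": col(n_cases, n_cases, 0, n_controls),
            "male": col(36, n_cases, 520, n_controls),
            "diabetes": col(33, n_cases, 460, n_controls),
            "hypertension": col(38, n_cases, 595, n_controls),
            "dyslipidemia": col(38, n_cases, 587, n_controls),
            "obesity": col(12, n_cases, 206, n_controls),
            "ckd": col(20, n_cases, 247, n_controls),
            "ever_smoker": col(35, n_cases, 589, n_controls),
        }
    )
    # PCI on non-missing denominators: 30/38 cases, 380/644 controls
    pci = pd.array(
        [True] * 30 + [False] * 8 + [pd.NA]
        + [True] * 380 + [False] * 264 + [pd.NA] * 14,
        dtype="boolean",
    )
    df["pci"] = pci
    df["metabolizer"] = (
        ["PM"] * 9 + ["IM"] * 15 + ["UM"] * 3 + ["NM"] * 12
        + ["PM"] * 81 + ["IM"] * 286 + ["UM"] * 8 + ["NM"] * 283
    )
    rng = np.random.default_rng(2023)
    df["age"] = np.where(
        df["recurrent_mi"], rng.normal(67, 9, 697), rng.normal(60, 12, 697)
    )
    return df


class TestBaselineComparison:
    def test_printed_margins_reproduce_p_values(self):
        rows = table2_margin_rows()
        table = baseline_comparison(rows).set_index("characteristic")
        expected = {
            "Ultrarapid metabolizer": (0.020, 0.0005),
            "Percutaneous coronary intervention": (0.016, 0.0005),
            "Poor metabolizer": (0.079, 0.0005),
            "Diabetes": (0.068, 0.0005),
            "Male": (0.062, 0.0005),
            "Hypertension": (0.25, 0.005),
            "Chronic kidney disease": (0.092, 0.0005),
            "Smoker": (1.00, 0.005),
        }
        for name, (p, tol) in expected.items():
            assert table.loc[name, "p_value"] == pytest.approx(p, abs=tol), name

    def test_pci_uses_non_missing_denominators(self):
        table = baseline_comparison(table2_margin_rows()).set_index("characteristic")
        pci = table.loc["Percutaneous coronary intervention"]
        assert pci["recurrence_denom"] == 38
        assert pci["no_recurrence_denom"] == 644

    def test_row_order_invariance(self):
        rows = table2_margin_rows()
        a = baseline_comparison(rows)
        b = baseline_comparison(rows.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a, b)

    def test_single_group_p_is_nan(self):
        rows = table2_margin_rows()
        rows["recurrent_mi"] = False
        table = baseline_comparison(rows)
        assert table["p_value"].isna().all()
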