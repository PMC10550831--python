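"""Association statistics for the clopidogrel cohort.

Baseline characteristics of the recurrent-MI vs no-recurrence groups are
compared with two-sided Fisher exact tests (hypergeometric enumeration
convention: sum of table probabilities not exceeding the observed one) and a
Welch t-test for age. The exposure effect is estimated by multivariable
logistic regression fit with iteratively reweighted least squares (IRLS):
Wald standard errors from the inverse observed information, odds ratios with
95% CIs exp(beta +/- 1.96 SE), and two-sided normal p-values. The exposure is
coded either categorically (PM, IM, UM indicators; NM and RM combined as the
reference) or as a loss-of-function allele dose (0/1/2) with ultrarapid
metabolizers excluded as outliers. Multicollinearity is screened with
variance inflation factors. No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Covariates of the multivariable model, in reporting order.
MODEL_COVARIATES = (
    "male",
    "age",
    "diabetes",
    "hypertension",
    "dyslipidemia",
    "obesity",
    "ckd",
    "ever_smoker",
    "pci",
)


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    odds_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    n_used: int
    converged: bool
    iterations: int
    separation: bool = False
    dropped: dict[str, int] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "or": self.odds_ratio,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_values,
            }
        )

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        return {
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "or": float(self.odds_ratio[i]),
            "ci_lower": float(self.ci_lower[i]),
            "ci_upper": float(self.ci_upper[i]),
            "p": float(self.p_values[i]),
        }


@dataclass(frozen=True)
class ExposureCoding:
    """Exposure parametrization for the outcome model.

    categorical: PM/IM/UM indicators with NM and RM combined as the reference.
    lof_dose: a single 0/1/2 LOF-allele count; UM rows are always excluded.
    """

    mode: str = "categorical"
    um_excluded: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("categorical", "lof_dose"):
            raise ValueError(f"unknown exposure mode {self.mode!r}")
        if self.mode == "lof_dose":
            object.__setattr__(self, "um_excluded", True)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    A table with an empty row or column is degenerate (p = 1).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in {cells}")
    if sum(cells) == 0:
        raise ValueError("empty table")
    if min(a + b, c + d, a + c, b + d) == 0:
        return TestResult(None, 1.0, "fisher_exact", degenerate=True)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(float(odds), min(float(p), 1.0), "fisher_exact")


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Welch two-sample t-test (Satterthwaite df) from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch_t")


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    *,
    term_names: list[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticFit:
    """Logistic regression by IRLS (Newton-Raphson on the log-likelihood).

    Convergence when the largest absolute coefficient change falls below
    ``tol``. Separation is flagged (never silent) when a coefficient diverges
    beyond |15| or the deviance stops decreasing.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = term_names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y shapes incompatible")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in the design matrix or outcome")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant column {name!r} in the design matrix")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names

    n, p = X.shape
    beta = np.zeros(p)
    if add_intercept:
        ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
        beta[0] = np.log(ybar / (1 - ybar))

    def deviance(b: np.ndarray) -> float:
        mu = np.clip(1.0 / (1.0 + np.exp(-(X @ b))), 1e-12, 1 - 1e-12)
        return -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    converged = False
    separation = False
    prev_dev = deviance(beta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        XtWX = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            separation = True
            logger.warning("singular information matrix; possible separation")
            break
        # Newton steps are not deviance-monotone from a cold start: halve the
        # step until the deviance stops increasing. Failure to find any
        # decreasing step signals separation.
        step = 1.0
        for _ in range(25):
            candidate = beta + step * delta
            dev = deviance(candidate)
            if dev <= prev_dev + 1e-8:
                break
            step *= 0.5
        else:
            separation = True
            logger.warning("non-decreasing deviance; possible separation")
            break
        beta = candidate
        if np.max(np.abs(beta)) > 15:
            separation = True
            logger.warning("diverging coefficients; possible separation")
            break
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
        prev_dev = dev

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        ci_lo = np.exp(beta - 1.96 * se)
        ci_hi = np.exp(beta + 1.96 * se)
    return LogisticFit(
        terms=names,
        coef=beta,
        se=se,
        odds_ratio=np.exp(beta),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_values=pvals,
        n_used=n,
        converged=converged and not separation,
        iterations=it,
        separation=separation,
    )


def _design_from_rows(
    rows: pd.DataFrame, coding: ExposureCoding, adjust_pcs: bool
) -> tuple[pd.DataFrame, pd.Series, dict[str, int]]:
    df = rows.copy()
    dropped: dict[str, int] = {}
    n_pci_missing = int(df["pci"].isna().sum())
    if n_pci_missing:
        df = df[df["pci"].notna()]
        dropped["pci_missing"] = n_pci_missing
        logger.info("%d rows with missing PCI dropped from the model", n_pci_missing)
    if coding.um_excluded:
        n_um = int((df["metabolizer"] == "UM").sum())
        if n_um:
            df = df[df["metabolizer"] != "UM"]
            dropped["um_excluded"] = n_um
            logger.info("%d ultrarapid metabolizer rows excluded", n_um)
    if "unrelated_flag" in df.columns:
        cases = df[df["recurrent_mi"].astype(bool)]
        if not cases["unrelated_flag"].astype(bool).all():
            logger.warning("related participants present among recurrent-MI cases")

    design = pd.DataFrame(index=df.index)
    if coding.mode == "categorical":
        design["PM"] = (df["metabolizer"] == "PM").astype(float)
        design["IM"] = (df["metabolizer"] == "IM").astype(float)
        if not coding.um_excluded:
            design["UM"] = (df["metabolizer"] == "UM").astype(float)
    else:
        design["lof_count"] = df["lof_count"].astype(float)
    for cov in MODEL_COVARIATES:
        design[cov] = df[cov].astype(float)
    if adjust_pcs:
        pc_cols = sorted(
            (c for c in df.columns if c.startswith("pc_")),
            key=lambda s: int(s.split("_")[1]),
        )
        if not pc_cols:
            raise ValueError("adjust_pcs requested but no pc_* columns present")
        for c in pc_cols:
            design[c] = df[c].astype(float)
    y = df["recurrent_mi"].astype(int)
    if y.nunique() < 2:
        raise ValueError("fewer than two outcome classes after filtering")
    return design, y, dropped


def metabolizer_association(
    rows: pd.DataFrame,
    coding: ExposureCoding = ExposureCoding(),
    adjust_pcs: bool = False,
) -> LogisticFit:
    """Fit the multivariable recurrent-MI model for a given exposure coding.

    Rows with missing PCI are dropped (the model adjusts for PCI); in
    lof_dose mode UM rows are excluded. Covariates: male, age (years),
    diabetes, hypertension, dyslipidemia, obesity, CKD, ever-smoker, PCI, and
    optionally 20 principal components.
    """
    design, y, dropped = _design_from_rows(rows, coding, adjust_pcs)
    fit = fit_logistic(design, y)
    fit.dropped = dropped
    return fit


def vif(X: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per column: 1 / (1 - R^2) from regressing the
    column on the others (with intercept). Perfect collinearity reports an
    infinite VIF with a flag; values above 5 are flagged."""
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    Xv = X.to_numpy(dtype=float)
    n = Xv.shape[0]
    out = []
    for j, name in enumerate(X.columns):
        others = np.column_stack(
            [np.ones(n), np.delete(Xv, j, axis=1)]
        )
        target = Xv[:, j]
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"constant column {name!r}")
        r2 = 1.0 - ss_res / ss_tot
        value = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"term": name, "vif": value, "flag": not np.isfinite(value) or value > 5})
    return pd.DataFrame(out)


_BINARY_CHARACTERISTICS = (
    ("male", "Male"),
    ("diabetes", "Diabetes"),
    ("hypertension", "Hypertension"),
    ("dyslipidemia", "Dyslipidemia"),
    ("obesity", "Obesity"),
    ("ckd", "Chronic kidney disease"),
    ("ever_smoker", "Smoker"),
    ("pci", "Percutaneous coronary intervention"),
)


def baseline_comparison(rows: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table: % (n) per outcome group with Fisher p
    for binary characteristics (PCI on non-missing denominators), metabolizer
    classes as indicators, and a Welch t-test row for age."""
    if rows.empty:
        raise ValueError("no rows")
    y = rows["recurrent_mi"].astype(bool)
    single_group = y.nunique() < 2
    records = []

    def add_binary(label: str, flags: pd.Series) -> None:
        present = flags.notna()
        f = flags[present].astype(bool)
        g = y[present]
        a = int((f & g).sum())          # characteristic yes, recurrent
        b = int((~f & g).sum())
        c = int((f & ~g).sum())         # characteristic yes, no recurrence
        d = int((~f & ~g).sum())
        n_rec, n_no = a + b, c + d
        p = (
            float("nan")
            if single_group
            else fisher_exact_two_sided(a, b, c, d).p_value
        )
        records.append(
            {
                "characteristic": label,
                "no_recurrence_n": c,
                "no_recurrence_denom": n_no,
                "recurrence_n": a,
                "recurrence_denom": n_rec,
                "p_value": p,
                "method": "fisher_exact",
            }
        )

    for col, label in _BINARY_CHARACTERISTICS:
        add_binary(label, rows[col])
    for cls, label in (
        ("PM", "Poor metabolizer"),
        ("IM", "Intermediate metabolizer"),
        ("UM", "Ultrarapid metabolizer"),
    ):
        add_binary(label, (rows["metabolizer"] == cls))

    age_no = rows.loc[~y, "age"]
    age_rec = rows.loc[y, "age"]
    if single_group or len(age_rec) < 2 or len(age_no) < 2:
        age_p = float("nan")
    else:
        age_p = welch_t_from_summary(
            age_no.mean(), age_no.std(ddof=1), len(age_no),
            age_rec.mean(), age_rec.std(ddof=1), len(age_rec),
        ).p_value
    records.append(
        {
            "characteristic": "Age at enrollment, y",
            "no_recurrence_n": round(float(age_no.mean()), 1) if len(age_no) else float("nan"),
            "no_recurrence_denom": len(age_no),
            "recurrence_n": round(float(age_rec.mean()), 1) if len(age_rec) else float("nan"),
            "recurrence_denom": len(age_rec),
            "p_value": age_p,
            "method": "welch_t",
        }
    )
    return pd.DataFrame(records)
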