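"""Association statistics for cohort measurements.

Implements the study's statistical battery over per-subject measurements
(SFT, BMA, MFI mean/mode indexes) and demographics (age, BMI): pooled-
variance two-sample t-tests, Pearson correlations, ordinary-least-squares
multivariate fits with an overall F-test, the full sex x obesity subgroup
crossing, and a segmentation-noise robustness procedure in which each
measurement is perturbed at its empirical repeatability CV and the p-values
of the whole battery are averaged over repeated executions.

No multiple-testing correction is applied anywhere: every p-value is
reported raw, matching the source analysis; readers should treat marginal
significances across the large subgroup crossing accordingly.  The obesity
cutoff is BMI >= 30.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "OBESITY_BMI_CUTOFF",
    "two_sample_test",
    "correlation_test",
    "multivariate_fit",
    "subgroup_battery",
    "reproducibility_cv",
    "noise_robustness",
]

OBESITY_BMI_CUTOFF = 30.0

OUTCOMES = ("sft", "bma", "mfi_mean", "mfi_mode")
PREDICTORS = ("age", "bmi")
#: additional cross-measurement correlations: MFI indexes vs BMA and SFT
CROSS_PAIRS = (
    ("mfi_mean", "bma"),
    ("mfi_mode", "bma"),
    ("mfi_mean", "sft"),
    ("mfi_mode", "sft"),
)


@dataclass
class TTestResult:
    t: float
    p: float
    means: tuple
    sds: tuple
    n: tuple


def two_sample_test(x1, x2, equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t-test (pooled variance by default)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each sample needs n >= 2")
    if equal_var and np.var(x1, ddof=1) + np.var(x2, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(x1, x2, equal_var=equal_var)
    return TTestResult(
        t=float(t), p=float(p),
        means=(float(x1.mean()), float(x2.mean())),
        sds=(float(x1.std(ddof=1)), float(x2.std(ddof=1))),
        n=(x1.size, x2.size),
    )


def correlation_test(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def multivariate_fit(y, age, bmi):
    """OLS of an outcome on age and BMI.

    Returns ``(params, overall_p, coef_p)``: intercept/age/bmi coefficients,
    the overall F-test p-value of the joint null (both slopes zero), and the
    per-coefficient p-values.
    """
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(
        pd.DataFrame({"age": np.asarray(age, float), "bmi": np.asarray(bmi, float)}),
        has_constant="add",
    )
    if y.size < 4:
        raise ValueError("need n >= 4")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    params = {"const": float(fit.params["const"]),
              "age": float(fit.params["age"]),
              "bmi": float(fit.params["bmi"])}
    coef_p = {k: float(fit.pvalues[k]) for k in ("const", "age", "bmi")}
    return params, float(fit.f_pvalue), coef_p


def _strata(df: pd.DataFrame) -> dict:
    obese = df["bmi"] >= OBESITY_BMI_CUTOFF
    strata = {
        "all": df,
        "male": df[df["sex"] == "M"],
        "female": df[df["sex"] == "F"],
        "obese": df[obese],
        "nonobese": df[~obese],
    }
    for sex, tag in (("M", "male"), ("F", "female")):
        strata[f"{tag}_obese"] = df[(df["sex"] == sex) & obese]
        strata[f"{tag}_nonobese"] = df[(df["sex"] == sex) & ~obese]
    return strata


def subgroup_battery(df: pd.DataFrame) -> pd.DataFrame:
    """Full association crossing over outcomes, predictors and strata.

    ``df`` needs columns sex, age, bmi, sft, bma, mfi_mean, mfi_mode.  Rows:
    one per univariate (outcome x predictor x stratum) correlation, one per
    multivariate (outcome ~ age + bmi) fit per stratum, plus the MFI-vs-BMA
    and MFI-vs-SFT cross-correlations.  Strata too small for a test yield an
    NA row with the reason instead of raising.
    """
    rows = []

    def add_corr(outcome, predictor, name, sub):
        base = {"outcome": outcome, "predictor": predictor, "stratum": name,
                "kind": "correlation", "n": len(sub)}
        try:
            r, p = correlation_test(sub[outcome], sub[predictor])
            rows.append({**base, "stat": r, "p": p, "note": ""})
        except ValueError as err:
            rows.append({**base, "stat": np.nan, "p": np.nan, "note": str(err)})

    for name, sub in _strata(df).items():
        for outcome in OUTCOMES:
            for predictor in PREDICTORS:
                add_corr(outcome, predictor, name, sub)
            base = {"outcome": outcome, "predictor": "age+bmi", "stratum": name,
                    "kind": "multivariate", "n": len(sub)}
            try:
                params, overall_p, _ = multivariate_fit(
                    sub[outcome], sub["age"], sub["bmi"]
                )
                rows.append({**base, "stat": params["age"], "p": overall_p,
                             "note": f"beta_bmi={params['bmi']:.4g}"})
            except ValueError as err:
                rows.append({**base, "stat": np.nan, "p": np.nan,
                             "note": str(err)})
        for outcome, other in CROSS_PAIRS:
            add_corr(outcome, other, name, sub)
    return pd.DataFrame(rows)


def reproducibility_cv(repeats) -> float:
    """Coefficient of variation of repeated measurements, in percent.

    sd / mean x 100, with the sample (ddof=1) standard deviation.
    """
    repeats = np.asarray(repeats, dtype=float)
    if repeats.size < 2:
        raise ValueError("need at least 2 repeats")
    mean = repeats.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(repeats.std(ddof=1) / mean * 100.0)


def noise_robustness(
    df: pd.DataFrame,
    cv_percent: dict,
    n_exec: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Average battery p-values under measurement-repeatability noise.

    Each measurement column named in ``cv_percent`` is perturbed per
    execution by zero-mean Gaussian noise with sd = cv x value; the whole
    subgroup battery is recomputed and p-values are averaged over the
    ``n_exec`` executions.  The result merges the noiseless battery with
    the averaged noisy p (``p_noise_avg``) and flags significance changes
    at alpha = 0.05.
    """
    if any(v < 0 for v in cv_percent.values()):
        raise ValueError("cv must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    base = subgroup_battery(df)
    if all(v == 0 for v in cv_percent.values()):
        out = base.copy()
        out["p_noise_avg"] = out["p"]
        out["significance_changed"] = False
        return out
    acc = np.zeros(len(base))
    for _ in range(n_exec):
        noisy = df.copy()
        for col, cv in cv_percent.items():
            vals = noisy[col].to_numpy(dtype=float)
            noisy[col] = vals + rng.normal(0.0, np.abs(vals) * cv / 100.0)
        acc += subgroup_battery(noisy)["p"].to_numpy()
    out = base.copy()
    out["p_noise_avg"] = acc / n_exec
    out["significance_changed"] = (out["p"] < 0.05) != (out["p_noise_avg"] < 0.05)
    return out
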