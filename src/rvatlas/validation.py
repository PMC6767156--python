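"""Prospective validation of single-point markers against RVEF.

Each candidate marker (SPM-O, TAPSE, TAPSE-F, SFD, SFD-F) is scored on a
held-out cohort by

* Pearson correlation with RVEF, with differences between dependent
  correlations (all sharing RVEF) tested by Steiger's Z̄₁* method;
* covariate-adjusted bootstrapped linear regression with a variance
  decomposition (incremental R² when each term enters last);
* stacked-model comparison treating the model type as an extra covariate;
* leave-one-out prediction of RVEF, with absolute errors summarised as
  median (IQR [range]) and compared across markers by Kruskal–Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .massuni import build_design, _zscore

__all__ = [
    "ValidationReport",
    "pearson",
    "steiger_test",
    "covariate_regression",
    "compare_models",
    "loo_predict",
    "compare_errors_kruskal",
    "validate_markers",
]


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation and two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Difference between two dependent correlations sharing one variable.

    Tests H0: rho_jk = rho_jh given that both correlations involve the same
    variable j (here RVEF), accounting for the correlation r_kh between the
    two markers.  Implements the Z̄₁* variant: Fisher z-transforms of the
    two correlations are compared with a covariance term evaluated at the
    back-transformed mean correlation r̄,

        psi = r_kh (1 - 2 r̄²) - r̄²/2 (1 - 2 r̄² - r_kh²)
        c   = psi / (1 - r̄²)²
        Z   = (z_jk - z_jh) sqrt((n - 3) / (2 - 2c))

    with a two-sided normal p-value.
    """
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    rbar = np.tanh((z_jk + z_jh) / 2.0)
    psi = r_kh * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_kh**2)
    c = psi / (1.0 - rbar**2) ** 2
    z = (z_jk - z_jh) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class RegressionResult:
    terms: list[str]
    coefficients: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    r_squared: float
    variance_fractions: dict[str, float]


def _design_with_marker(
    marker: np.ndarray, covariates: pd.DataFrame
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    Z = build_design(covariates)
    X = np.column_stack([Z[:, :1], _zscore(marker), Z[:, 1:]])
    n_race = Z.shape[1] - 4  # intercept, age, sex, bsa are the other columns
    terms = ["intercept", "marker", "age", "sex"] + [f"race_{i}" for i in range(n_race)] + ["bsa"]
    groups = {
        "marker": [1],
        "age": [2],
        "sex": [3],
        "race": list(range(4, 4 + n_race)),
        "bsa": [4 + n_race],
    }
    return X, terms, groups


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return beta, r2


def covariate_regression(
    marker: np.ndarray,
    covariates: pd.DataFrame,
    rvef: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> RegressionResult:
    """Standardised OLS of RVEF on marker + covariates with bootstrap CIs.

    The variance fraction of each term is its incremental R² when added
    last (squared semi-partial): R²(full) − R²(full without the term).
    """
    y = _zscore(np.asarray(rvef, dtype=float))
    X, terms, groups = _design_with_marker(np.asarray(marker, dtype=float), covariates)
    n = y.shape[0]
    if n <= X.shape[1] + 1:
        raise ValueError("too few subjects for the covariate-adjusted model")
    beta, r2_full = _ols_r2(X, y)

    fractions = {}
    for name, cols in groups.items():
        keep = [j for j in range(X.shape[1]) if j not in cols]
        _, r2_red = _ols_r2(X[:, keep], y)
        fractions[name] = max(r2_full - r2_red, 0.0)

    lo = hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, X.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b], *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return RegressionResult(
        terms=terms, coefficients=beta, ci_low=lo, ci_high=hi,
        r_squared=r2_full, variance_fractions=fractions,
    )


def compare_models(
    marker_a: np.ndarray,
    marker_b: np.ndarray,
    covariates: pd.DataFrame,
    rvef: np.ndarray,
) -> tuple[float, float]:
    """Do two markers carry different adjusted associations with RVEF?

    The two covariate-adjusted models are stacked, a model-type indicator
    added, and the marker × indicator interaction tested; returns the
    interaction coefficient and its OLS p-value.  (Subjects appear in both
    halves of the stack; the test treats the rows as exchangeable, which is
    the standard pragmatic reading of a model-type covariate comparison.)
    """
    y = _zscore(np.asarray(rvef, dtype=float))
    Xa, _, _ = _design_with_marker(np.asarray(marker_a, dtype=float), covariates)
    Xb, _, _ = _design_with_marker(np.asarray(marker_b, dtype=float), covariates)
    n = y.shape[0]
    X = np.vstack([Xa, Xb])
    ind = np.concatenate([np.zeros(n), np.ones(n)])
    inter = X[:, 1] * ind
    Xfull = np.column_stack([X, ind, inter])
    yy = np.concatenate([y, y])
    beta, *_ = np.linalg.lstsq(Xfull, yy, rcond=None)
    resid = yy - Xfull @ beta
    dof = Xfull.shape[0] - np.linalg.matrix_rank(Xfull)
    sigma2 = float(resid @ resid) / max(dof, 1)
    XtX_inv = np.linalg.pinv(Xfull.T @ Xfull)
    se = np.sqrt(sigma2 * XtX_inv[-1, -1])
    coef = float(beta[-1])
    if se <= 1e-14:
        return coef, 1.0
    t = coef / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return coef, float(p)


def loo_predict(
    marker: np.ndarray,
    covariates: pd.DataFrame,
    rvef: np.ndarray,
    edv: np.ndarray,
    marker_only: bool = False,
) -> pd.DataFrame:
    """Leave-one-out RVEF prediction from the covariate-adjusted model.

    Each subject's RVEF is predicted from a model refitted on the remaining
    subjects.  Standardisation of the design uses the full sample, so the
    refits share one fixed design matrix (this keeps the procedure exactly
    equivalent to the closed-form case-deletion formula).  Absolute errors
    are reported in EF points and, scaled by each subject's EDV, in ml.
    """
    y = _zscore(np.asarray(rvef, dtype=float))
    rvef = np.asarray(rvef, dtype=float)
    n = y.shape[0]
    if n < 20:
        raise ValueError("leave-one-out needs at least 20 subjects")
    if marker_only:
        X = np.column_stack([np.ones(n), _zscore(np.asarray(marker, dtype=float))])
    else:
        X, _, _ = _design_with_marker(np.asarray(marker, dtype=float), covariates)
    sd_y = rvef.std(ddof=0)
    mu_y = rvef.mean()
    pred = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise RuntimeError(f"leave-one-out refit failed at fold {i}") from err
        pred[i] = X[i] @ beta
    pred_ef = mu_y + sd_y * pred
    err_ef = np.abs(pred_ef - rvef)
    err_ml = err_ef / 100.0 * np.asarray(edv, dtype=float)
    return pd.DataFrame(
        {"predicted_rvef": pred_ef, "abs_error_ef": err_ef, "abs_error_ml": err_ml}
    )


def error_summary(err: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(err, [25, 50, 75])
    return {
        "median": float(med),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
        "min": float(err.min()),
        "max": float(err.max()),
    }


def compare_errors_kruskal(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis rank-sum comparison of error distributions.

    Tie-corrected H statistic with the chi-square approximation; identical
    values across all groups give H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups.values()):
        raise ValueError("need >= 2 non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class ValidationReport:
    """Marker-comparison outputs of the validation cohort."""

    n_subjects: int
    reference_marker: str
    correlations: dict[str, dict[str, float]]  # marker -> {r, p}
    steiger: dict[str, dict[str, float]]  # marker -> {z, p} vs reference
    regressions: dict[str, RegressionResult] = field(repr=False, default_factory=dict)
    variance_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    model_comparison: dict[str, dict[str, float]] = field(default_factory=dict)
    loo_errors_ml: dict[str, dict[str, float]] = field(default_factory=dict)
    loo_errors_ef: dict[str, dict[str, float]] = field(default_factory=dict)
    kruskal_chi2: float = float("nan")
    kruskal_p: float = float("nan")
    seeds: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "reference_marker": self.reference_marker,
            "correlations": self.correlations,
            "steiger_vs_reference": self.steiger,
            "variance_fractions": self.variance_fractions,
            "model_comparison_vs_reference": self.model_comparison,
            "loo_abs_error_ml": self.loo_errors_ml,
            "loo_abs_error_ef": self.loo_errors_ef,
            "kruskal_wallis": {"chi2": self.kruskal_chi2, "p": self.kruskal_p},
            "seeds": self.seeds,
        }


def validate_markers(
    markers: pd.DataFrame,
    covariates: pd.DataFrame,
    rvef: np.ndarray,
    edv: np.ndarray,
    reference: str = "SPM-O",
    n_boot: int = 10_000,
    seed: int = 0,
) -> ValidationReport:
    """Full marker-validation battery on one cohort."""
    if reference not in markers.columns:
        raise KeyError(f"missing marker column {reference!r}")
    names = list(markers.columns)
    n = len(markers)
    rvef = np.asarray(rvef, dtype=float)

    correlations = {}
    for m in names:
        r, p = pearson(markers[m].to_numpy(), rvef)
        correlations[m] = {"r": r, "p": p}

    steiger = {}
    r_ref = correlations[reference]["r"]
    for m in names:
        if m == reference:
            continue
        r_kh = float(np.corrcoef(markers[reference], markers[m])[0, 1])
        z, p = steiger_test(r_ref, correlations[m]["r"], r_kh, n)
        steiger[m] = {"z": z, "p": p}

    seq = np.random.SeedSequence(seed)
    reg_seeds = {m: int(s.generate_state(1)[0] % (2**31)) for m, s in
                 zip(names, seq.spawn(len(names)))}
    regressions = {}
    fractions = {}
    for m in names:
        res = covariate_regression(
            markers[m].to_numpy(), covariates, rvef, n_boot=n_boot, seed=reg_seeds[m]
        )
        regressions[m] = res
        fractions[m] = res.variance_fractions

    comparison = {}
    for m in names:
        if m == reference:
            continue
        coef, p = compare_models(
            markers[reference].to_numpy(), markers[m].to_numpy(), covariates, rvef
        )
        comparison[m] = {"interaction_coef": coef, "p": p}

    loo_ml = {}
    loo_ef = {}
    err_groups = {}
    for m in names:
        loo = loo_predict(markers[m].to_numpy(), covariates, rvef, edv)
        loo_ml[m] = error_summary(loo["abs_error_ml"].to_numpy())
        loo_ef[m] = error_summary(loo["abs_error_ef"].to_numpy())
        err_groups[m] = loo["abs_error_ml"].to_numpy()
    chi2, kp = compare_errors_kruskal(err_groups)

    return ValidationReport(
        n_subjects=n,
        reference_marker=reference,
        correlations=correlations,
        steiger=steiger,
        regressions=regressions,
        variance_fractions=fractions,
        model_comparison=comparison,
        loo_errors_ml=loo_ml,
        loo_errors_ef=loo_ef,
        kruskal_chi2=chi2,
        kruskal_p=kp,
        seeds={"validation": seed, **{f"boot_{m}": s for m, s in reg_seeds.items()}},
    )
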