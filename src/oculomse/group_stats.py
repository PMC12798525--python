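"""Group-level statistics for entropy profiles and pupil features.

Covers the full inferential battery of the analysis: a mixed
(between-within) repeated-measures ANCOVA of the 30-scale entropy profiles
with age as covariate and Greenhouse-Geisser sphericity correction, a
one-way ANCOVA for scalar features (mean pupil diameter), post hoc
per-scale two-sample t-tests with Benjamini-Hochberg FDR across scales,
Pearson correlations of features with symptom-severity scores, a
demographics comparison table, and the Fisher-z sample-size calculation
for detecting a target correlation.

The repeated-measures ANCOVA follows the classical split-plot
decomposition: between-subject effects are tested on subject means
(group + age against the subject-level residual), within-subject effects
on an orthonormal contrast transform of the scale dimension (scale,
scale x age, scale x group against the pooled contrast residual), with
the Greenhouse-Geisser epsilon estimated from the residual covariance of
the repeated measures and applied to the within-effect degrees of
freedom.  Effect sizes are partial eta-squared within each error stratum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AncovaResult",
    "ScaleTestResult",
    "bh_fdr",
    "rm_ancova_group_by_scale",
    "ancova_oneway",
    "posthoc_scale_ttests",
    "correlate_with_severity",
    "required_sample_size_correlation",
    "demographics_table",
]


@dataclass(frozen=True)
class AncovaResult:
    """One effect from an ANCOVA: F, p, partial eta^2 and (adjusted) dfs."""

    effect: str
    F: float
    p: float
    eta_sq: float
    df_num: float
    df_den: float
    gg_epsilon: float | None = None
    n_used: int = 0


@dataclass(frozen=True)
class ScaleTestResult:
    scale: int
    t: float
    p: float
    q: float
    flag05: bool
    flag01: bool


def bh_fdr(p_values: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(q_values, reject_mask)``; q-values are monotone in the
    sorted-p order and rejections form a prefix of that order.  NaN
    p-values are treated as 1 (never rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    p_filled = np.where(np.isfinite(p), p, 1.0)
    reject, q, _, _ = multipletests(p_filled, alpha=q_level, method="fdr_bh")
    return q, reject


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the least-squares fit of y on X."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A (k, k-1) matrix with orthonormal columns, each orthogonal to 1."""
    # QR of the centering matrix restricted to k-1 independent columns
    helmert = np.zeros((k, k - 1))
    for j in range(1, k):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
        helmert[:, j - 1] /= math.sqrt(j * (j + 1))
    return helmert


def rm_ancova_group_by_scale(
    profiles: np.ndarray,
    groups: np.ndarray,
    age: np.ndarray | None = None,
) -> dict[str, AncovaResult]:
    """Mixed between-within ANCOVA of per-scale entropy profiles.

    ``profiles`` is (n_participants, n_scales) of log FuzzyEn; ``groups``
    a two-level label array; ``age`` an optional covariate (dropped
    automatically if constant).  Participants with any missing profile
    value are removed listwise (count reported via ``n_used``).

    Returns results for the ``group`` between-subject effect, the
    ``scale`` within effect and the ``group_x_scale`` interaction (the
    latter two Greenhouse-Geisser adjusted).
    """
    Y = np.asarray(profiles, dtype=float)
    groups = np.asarray(groups)
    if Y.ndim != 2:
        raise ValueError("profiles must be a 2-D (participants x scales) array")
    n, k = Y.shape
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels.size}")
    # effect coding so dropping the intercept is the Type III scale test
    g = np.where(groups == levels[1], 1.0, -1.0)

    keep = np.all(np.isfinite(Y), axis=1)
    if age is not None:
        age = np.asarray(age, dtype=float)
        keep &= np.isfinite(age)
    Y, g = Y[keep], g[keep]
    n = Y.shape[0]
    if n < 4:
        raise ValueError(f"too few complete participants for the ANCOVA ({n})")

    use_age = age is not None and np.ptp(age[keep]) > 0
    if age is not None and not use_age:
        warnings.warn("age covariate is constant; reducing to a repeated-measures ANOVA")
    covar = [(age[keep] - age[keep].mean())] if use_age else []

    ones = np.ones(n)
    X_full = np.column_stack([ones, *covar, g])
    X_nogrp = np.column_stack([ones, *covar])
    p_between = X_full.shape[1]

    # --- between stratum: subject means ---
    ybar = Y.mean(axis=1)
    sse_full = _sse(ybar, X_full)
    ss_group = _sse(ybar, X_nogrp) - sse_full
    df_den_b = n - p_between
    F_group = (ss_group / 1.0) / (sse_full / df_den_b)
    p_group = float(stats.f.sf(F_group, 1, df_den_b))
    res = {
        "group": AncovaResult(
            "group", float(F_group), p_group,
            float(ss_group / (ss_group + sse_full)), 1.0, float(df_den_b),
            None, n,
        )
    }

    # --- within stratum: orthonormal contrasts over scales ---
    C = _orthonormal_contrasts(k)
    Z = Y @ C  # (n, k-1)
    sse_w_full = 0.0
    ss_scale = 0.0
    ss_gs = 0.0
    X_noint = X_full[:, 1:] if X_full.shape[1] > 1 else np.zeros((n, 0))
    for c in range(k - 1):
        z = Z[:, c]
        full = _sse(z, X_full)
        sse_w_full += full
        ss_scale += _sse(z, X_noint) - full if X_noint.shape[1] else float(z @ z) - full
        ss_gs += _sse(z, X_nogrp) - full

    df_eff = k - 1.0
    df_err = (n - p_between) * (k - 1.0)
    ms_err = sse_w_full / df_err

    # Greenhouse-Geisser epsilon from the residual covariance of Y
    beta, _, _, _ = np.linalg.lstsq(X_full, Y, rcond=None)
    R = Y - X_full @ beta
    S = (R.T @ R) / (n - p_between)
    M = C.T @ S @ C
    tr_m = np.trace(M)
    eps = float(tr_m**2 / ((k - 1) * np.sum(M * M))) if np.sum(M * M) > 0 else 1.0
    eps = min(1.0, max(eps, 1.0 / (k - 1)))

    for name, ss in (("scale", ss_scale), ("group_x_scale", ss_gs)):
        F = (ss / df_eff) / ms_err
        p = float(stats.f.sf(F, df_eff * eps, df_err * eps))
        res[name] = AncovaResult(
            name, float(F), p, float(ss / (ss + sse_w_full)),
            df_eff * eps, df_err * eps, eps, n,
        )
    return res


def ancova_oneway(
    feature: np.ndarray,
    groups: np.ndarray,
    age: np.ndarray | None = None,
) -> AncovaResult:
    """One-way ANCOVA of a scalar feature: group effect adjusted for age.

    Falls back to a plain one-way ANOVA (with a warning) when the age
    covariate is constant or absent.
    """
    y = np.asarray(feature, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(y)
    if age is not None:
        age = np.asarray(age, dtype=float)
        keep &= np.isfinite(age)
    y, groups = y[keep], groups[keep]
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels.size}")
    if min((groups == lv).sum() for lv in levels) < 2:
        raise ValueError("need at least 2 participants per group")
    g = (groups == levels[1]).astype(float)
    n = y.size

    use_age = age is not None and np.ptp(age[keep]) > 0
    if age is not None and not use_age:
        warnings.warn("age covariate is constant; falling back to one-way ANOVA")
    covar = [(age[keep] - age[keep].mean())] if use_age else []
    ones = np.ones(n)
    X_full = np.column_stack([ones, *covar, g])
    X_red = np.column_stack([ones, *covar])
    sse_full = _sse(y, X_full)
    ss_group = _sse(y, X_red) - sse_full
    df_den = n - X_full.shape[1]
    F = (ss_group / 1.0) / (sse_full / df_den)
    return AncovaResult(
        "group", float(F), float(stats.f.sf(F, 1, df_den)),
        float(ss_group / (ss_group + sse_full)), 1.0, float(df_den), None, n,
    )


def posthoc_scale_ttests(
    profiles: np.ndarray,
    groups: np.ndarray,
    scales: np.ndarray | None = None,
    q_levels: tuple[float, float] = (0.05, 0.01),
    welch: bool = False,
) -> list[ScaleTestResult]:
    """Independent two-sample t-test per scale with BH-FDR across scales.

    Student (pooled-variance) t by default; set ``welch=True`` for the
    unequal-variance variant.  Sign convention: positive t means the first
    group level (sorted label order) is higher.
    """
    Y = np.asarray(profiles, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels.size}")
    a_mask, b_mask = groups == levels[0], groups == levels[1]
    n_scales = Y.shape[1]
    if scales is None:
        scales = np.arange(1, n_scales + 1)
    t_vals = np.empty(n_scales)
    p_vals = np.empty(n_scales)
    for s in range(n_scales):
        a = Y[a_mask, s]
        b = Y[b_mask, s]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            t_vals[s], p_vals[s] = np.nan, 1.0
            continue
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_vals[s], p_vals[s] = res.statistic, res.pvalue
    q_vals, _ = bh_fdr(p_vals, q_levels[0])
    return [
        ScaleTestResult(
            int(scales[s]), float(t_vals[s]), float(p_vals[s]), float(q_vals[s]),
            bool(q_vals[s] < q_levels[0]), bool(q_vals[s] < q_levels[1]),
        )
        for s in range(n_scales)
    ]


FEATURE_COLUMNS = ("pupil_size", "hor_fuzzyen", "vert_fuzzyen")
SCORE_COLUMNS = ("asrs_total", "asrs_in", "asrs_hypi")


def correlate_with_severity(
    feature_table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    scores: tuple[str, ...] = SCORE_COLUMNS,
) -> pd.DataFrame:
    """Pearson correlation of each feature with each severity score.

    Computed separately in the ADHD group and its drug-naive subset.
    Pairs with fewer than 3 complete observations or a zero-variance
    feature are marked undefined (NaN r, ``defined=False``).
    """
    out = []
    subsets = {
        "ADHD": feature_table[feature_table["group"] == "ADHD"],
        "drug_naive_ADHD": feature_table[
            (feature_table["group"] == "ADHD") & (feature_table["drug_naive"] == 1)
        ],
    }
    for subset_name, df in subsets.items():
        for feat in features:
            for score in scores:
                x = pd.to_numeric(df[feat], errors="coerce")
                y = pd.to_numeric(df[score], errors="coerce")
                ok = x.notna() & y.notna()
                x, y = x[ok].to_numpy(), y[ok].to_numpy()
                if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
                    out.append((subset_name, feat, score, np.nan, np.nan, x.size, False))
                    continue
                r, p = stats.pearsonr(x, y)
                out.append((subset_name, feat, score, float(r), float(p), x.size, True))
    return pd.DataFrame(
        out, columns=["subset", "feature", "score", "r", "p", "n", "defined"]
    )


def required_sample_size_correlation(
    r: float, alpha: float = 0.05, power: float = 0.80
) -> dict[str, float]:
    """Sample size needed to detect a correlation ``r`` (Fisher-z approximation).

    n = ((z_{1-alpha/2} + z_power) / atanh(|r|))^2 + 3, reported both as the
    exact ceiling and rounded up to the nearest ten.
    """
    if not (0 < abs(r) < 1):
        raise ValueError(f"require 0 < |r| < 1, got {r}")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n_raw = ((z_a + z_b) / math.atanh(abs(r))) ** 2 + 3
    n_ceil = int(math.ceil(n_raw))
    return {
        "n_raw": float(n_raw),
        "n_ceiling": n_ceil,
        "n_nearest_ten": int(math.ceil(n_ceil / 10.0) * 10),
    }


_CONTINUOUS_DEMOGRAPHICS = ("age_years", "asrs_total", "asrs_in", "asrs_hypi")


def demographics_table(
    manifest: pd.DataFrame,
    continuous: tuple[str, ...] = _CONTINUOUS_DEMOGRAPHICS,
) -> pd.DataFrame:
    """Group comparison table of cohort demographics.

    Continuous variables: mean +/- SD per group with a two-tailed
    two-sample t-test; sex ratio: Pearson chi-square.  Contrasts are
    TD vs ADHD and TD vs the drug-naive ADHD subset.
    """
    td = manifest[manifest["group"] == "TD"]
    adhd = manifest[manifest["group"] == "ADHD"]
    naive = adhd[adhd["drug_naive"] == 1]

    def _t_p(a: pd.Series, b: pd.Series) -> float:
        a = pd.to_numeric(a, errors="coerce").dropna()
        b = pd.to_numeric(b, errors="coerce").dropna()
        if len(a) < 2 or len(b) < 2:
            return float("nan")
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)

    rows = []
    for var in continuous:
        rows.append(
            {
                "variable": var,
                "td_mean": td[var].mean(), "td_sd": td[var].std(ddof=1),
                "adhd_mean": adhd[var].mean(), "adhd_sd": adhd[var].std(ddof=1),
                "naive_mean": naive[var].mean(), "naive_sd": naive[var].std(ddof=1),
                "p_td_adhd": _t_p(td[var], adhd[var]),
                "p_td_naive": _t_p(td[var], naive[var]),
            }
        )

    def _chi2_p(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
        table = np.array(
            [
                [(a["sex"] == "M").sum(), (a["sex"] == "F").sum()],
                [(b["sex"] == "M").sum(), (b["sex"] == "F").sum()],
            ]
        )
        if table.sum() == 0 or (table.sum(axis=0) == 0).any():
            return float("nan"), float("nan")
        if np.array_equal(table[0] * table[1].sum(), table[1] * table[0].sum()):
            # identical ratios: chi-square exactly 0
            return 0.0, 1.0
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)

    chi2_a, p_a = _chi2_p(td, adhd)
    chi2_n, p_n = _chi2_p(td, naive)
    rows.append(
        {
            "variable": "sex_male_female",
            "td_mean": (td["sex"] == "M").sum(), "td_sd": (td["sex"] == "F").sum(),
            "adhd_mean": (adhd["sex"] == "M").sum(), "adhd_sd": (adhd["sex"] == "F").sum(),
            "naive_mean": (naive["sex"] == "M").sum(), "naive_sd": (naive["sex"] == "F").sum(),
            "p_td_adhd": p_a,
            "p_td_naive": p_n,
        }
    )
    return pd.DataFrame(rows)
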