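"""Covariate-adjusted cohort statistics for network metrics and edges.

Implements the statistical layer applied to per-subject network measures in
a three-group (HC / MCI / AD) design: demographic comparisons (ANOVA, chi
squared, Kruskal-Wallis), ANCOVA group effects on nodal/global metrics with
Benjamini-Hochberg FDR across metrics, covariate-adjusted pairwise edge
t-tests with FDR within each group-pair family, post hoc pairwise contrasts,
and covariate-adjusted associations reported as Spearman correlations of
residuals.

"Adjusting for age, sex and education" is implemented throughout as linear
residualization: group terms enter a linear model alongside the covariates
(ANCOVA / adjusted t-test), and associations rank-correlate the residuals of
both variables after regressing each on the covariates.  Missingness is
handled listwise and every result row records the n actually used.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "demographics_tests",
    "ancova_group_effect",
    "posthoc_pairwise",
    "edge_group_ttests",
    "residualized_spearman",
    "adjusted_association",
]

DEFAULT_COVARIATES = ("age", "sex", "education")

#: Clinical severity order used for contrast labeling when applicable.
_CANONICAL_GROUPS = ("HC", "MCI", "AD")


def _group_order(groups) -> list[str]:
    """HC < MCI < AD when those labels are used; alphabetical otherwise."""
    known = [g for g in _CANONICAL_GROUPS if g in groups]
    rest = sorted(g for g in groups if g not in _CANONICAL_GROUPS)
    return known + rest


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and the rejection set.

    Returns ``(q_values, reject)`` with monotonicity enforced; q_values[i] >=
    p_values[i] always.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_adj, reject


def _check_groups(cohort: pd.DataFrame, min_per_group: int = 2) -> list[str]:
    counts = cohort["group"].value_counts()
    small = counts[counts < min_per_group]
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if len(small):
        raise ValueError(
            f"every group needs >= {min_per_group} subjects; too small: "
            f"{dict(small)}"
        )
    return list(counts.index)


def demographics_tests(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "education"),
    categorical: tuple[str, ...] = ("sex",),
    score_columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Baseline group comparisons: ANOVA, chi-squared, Kruskal-Wallis.

    Continuous demographics get one-way ANOVA, categorical ones a chi-squared
    test on the contingency table, and score columns (default: every column
    starting with ``score_``) the Kruskal-Wallis H test with tie correction.
    """
    _check_groups(cohort)
    if score_columns is None:
        score_columns = tuple(c for c in cohort.columns if c.startswith("score_"))
    groups = sorted(cohort["group"].unique())
    rows = []

    def by_group(col):
        return [cohort.loc[cohort["group"] == g, col].dropna().values for g in groups]

    for col in continuous:
        samples = by_group(col)
        f, p = sps.f_oneway(*samples)
        rows.append(dict(term=col, test="anova", statistic=f, p=p,
                         n=int(sum(len(s) for s in samples))))
    for col in categorical:
        tab = pd.crosstab(cohort["group"], cohort[col])
        if tab.shape[1] < 2:  # a constant covariate cannot differ by group
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = sps.chi2_contingency(tab.values, correction=False)
        rows.append(dict(term=col, test="chi2", statistic=stat, p=p,
                         n=int(tab.values.sum())))
    for col in score_columns:
        samples = by_group(col)
        if np.ptp(np.concatenate(samples)) == 0:  # identical values: H = 0
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*samples)
        rows.append(dict(term=col, test="kruskal", statistic=stat, p=p,
                         n=int(sum(len(s) for s in samples))))
    return pd.DataFrame(rows)


def _design_rank_check(df: pd.DataFrame, covariates: tuple[str, ...]) -> None:
    X = df[list(covariates)].astype(float).values
    X = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        for i, c in enumerate(covariates):
            Xi = np.delete(X, i + 1, axis=1)
            if np.linalg.matrix_rank(Xi) == rank:
                collinear.append(c)
        raise ValueError(
            f"rank-deficient design: collinear covariate column(s) {collinear}"
        )


def ancova_group_effect(
    cohort: pd.DataFrame,
    metric_columns: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    q: float = 0.05,
) -> pd.DataFrame:
    """ANCOVA group effect per metric, BH-corrected across metrics.

    Fits ``metric ~ C(group) + covariates`` per column and F-tests the group
    term; the BH family is the set of metric columns.
    """
    _check_groups(cohort)
    groups = sorted(cohort["group"].unique())
    rows = []
    for col in metric_columns:
        cols = [col, "group", *covariates]
        data = cohort[cols].dropna()
        _design_rank_check(data, covariates)
        formula = f"Q('{col}') ~ C(group) + " + " + ".join(covariates)
        fit = ols(formula, data=data).fit()
        table = anova_lm(fit, typ=2)
        f = float(table.loc["C(group)", "F"])
        p = float(table.loc["C(group)", "PR(>F)"])
        row = dict(term=col, statistic=f, p=p, n=int(len(data)))
        for g in groups:
            row[f"mean_{g}"] = float(data.loc[data["group"] == g, col].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"], out["significant"] = bh_fdr(out["p"].values, q)
    return out


def posthoc_pairwise(
    cohort: pd.DataFrame,
    metric_columns: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted pairwise group contrasts for selected metrics.

    For each metric and each unordered group pair, fits a two-group linear
    model with covariates.  The contrast labeled ``"ga-gb"`` reports the
    adjusted estimate of gb minus ga (groups taken in clinical order
    HC < MCI < AD), its t, raw p, and BH-q within the metric.
    """
    groups = _group_order(cohort["group"].unique())
    rows = []
    for col in metric_columns:
        metric_rows = []
        for ga, gb in itertools.combinations(groups, 2):
            sub = cohort[cohort["group"].isin([ga, gb])][
                [col, "group", *covariates]
            ].dropna()
            est, t, p, n = _adjusted_two_group_t(
                sub[col].values,
                (sub["group"] == gb).astype(float).values,
                sub[list(covariates)].astype(float).values,
            )
            metric_rows.append(dict(term=col, contrast=f"{ga}-{gb}",
                                    estimate=est, statistic=t, p=p, n=n))
        qvals, rej = bh_fdr(np.array([r["p"] for r in metric_rows]), alpha)
        for r, qa, rj in zip(metric_rows, qvals, rej):
            r["q"], r["significant"] = qa, rj
        rows.extend(metric_rows)
    return pd.DataFrame(rows)


def _adjusted_two_group_t(
    y: np.ndarray, indicator: np.ndarray, covs: np.ndarray
) -> tuple[float, float, float, int]:
    """t-test for a group indicator in a linear model with covariates."""
    n = len(y)
    X = np.column_stack([np.ones(n), covs, indicator])
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"too few subjects ({n}) for {k} model parameters")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("rank-deficient design in adjusted t-test")
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    t = float(beta[-1] / se)
    p = 2.0 * sps.t.sf(abs(t), df=n - k)
    return float(beta[-1]), t, float(p), n


def edge_group_ttests(
    cohort: pd.DataFrame,
    edge_columns: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    q: float = 0.05,
) -> pd.DataFrame:
    """Adjusted two-sample t-tests per edge and group pair, FDR per family.

    For each unordered group pair, every edge column is tested with a linear
    model ``edge ~ indicator + covariates`` (indicator = 1 for the second
    group of the ``"ga-gb"`` label, groups in clinical order HC < MCI < AD);
    BH correction runs within the group-pair family across edges.  Positive
    t means the edge is stronger in the second-listed group ("increase").
    """
    groups = _group_order(cohort["group"].unique())
    all_rows = []
    for ga, gb in itertools.combinations(groups, 2):
        sub = cohort[cohort["group"].isin([ga, gb])]
        need = ["group", *covariates]
        sub = sub.dropna(subset=need)
        indicator = (sub["group"] == gb).astype(float).values
        covs = sub[list(covariates)].astype(float).values
        n = len(sub)
        X = np.column_stack([np.ones(n), covs, indicator])
        k = X.shape[1]
        if n <= k:
            raise ValueError(f"too few subjects in {ga} vs {gb}")
        Y = sub[edge_columns].astype(float).values  # (n, m); NaN-free expected
        pinv = np.linalg.pinv(X)
        B = pinv @ Y
        resid = Y - X @ B
        dof = n - k
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv_last = np.linalg.inv(X.T @ X)[-1, -1]
        se = np.sqrt(sigma2 * xtx_inv_last)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, B[-1] / se, 0.0)
        p = 2.0 * sps.t.sf(np.abs(t), df=dof)
        qvals, rej = bh_fdr(p, q)
        for e, ti, pi, qi, ri in zip(edge_columns, t, p, qvals, rej):
            all_rows.append(dict(
                term=e, contrast=f"{ga}-{gb}", statistic=float(ti),
                p=float(pi), q=float(qi), significant=bool(ri),
                direction="increase" if ti > 0 else "decrease", n=n,
            ))
    return pd.DataFrame(all_rows)


def residualized_spearman(
    cohort: pd.DataFrame,
    var1: str,
    var2: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_n: int = 10,
) -> tuple[float, float, int]:
    """Spearman correlation of the covariate-residualized variables.

    Both variables are regressed on the covariates (with intercept) and the
    residuals rank-correlated.  Listwise-complete cases only; raises when
    fewer than ``min_n`` remain.
    """
    data = cohort[[var1, var2, *covariates]].dropna()
    n = len(data)
    if n < min_n:
        raise ValueError(
            f"insufficient data: {n} complete cases for {var1} vs {var2} "
            f"(need >= {min_n})"
        )
    X = np.column_stack([np.ones(n), data[list(covariates)].astype(float).values])
    resids = []
    for v in (var1, var2):
        y = data[v].astype(float).values
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resids.append(y - X @ beta)
    rho, p = sps.spearmanr(resids[0], resids[1])
    return float(rho), float(p), n


def adjusted_association(
    cohort: pd.DataFrame,
    metric: str,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    by_group: bool = True,
    min_n: int = 10,
) -> pd.DataFrame:
    """Covariate-adjusted metric-outcome association, within each group.

    Returns one row per diagnostic group (plus a pooled ``all`` row) with
    the residualized Spearman rho, two-sided p, and n used.  Groups with
    fewer than ``min_n`` complete cases get NaN results but keep their n;
    raises only if no stratum reaches ``min_n``.  P-values are reported
    uncorrected by default; apply :func:`bh_fdr` to the p column to opt in
    to FDR correction.
    """
    strata = [("all", cohort)]
    if by_group:
        strata += [(g, cohort[cohort["group"] == g])
                   for g in sorted(cohort["group"].unique())]
    rows = []
    any_ok = False
    for name, sub in strata:
        n_complete = len(sub[[metric, outcome, *covariates]].dropna())
        if n_complete < min_n:
            rows.append(dict(group=name, metric=metric, outcome=outcome,
                             rho=np.nan, p=np.nan, n=n_complete))
            continue
        rho, p, n = residualized_spearman(sub, metric, outcome, covariates, min_n)
        rows.append(dict(group=name, metric=metric, outcome=outcome,
                         rho=rho, p=p, n=n))
        any_ok = True
    if not any_ok:
        raise ValueError(
            f"insufficient data: no stratum has >= {min_n} complete cases "
            f"for {metric} vs {outcome}"
        )
    return pd.DataFrame(rows)
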