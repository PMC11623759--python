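"""Covariate-adjusted linear models and per-taxon association scans.

Fits ordinary least squares models of the RCI outcome on an exposure of
interest (food insecurity, Shannon diversity, or a quartile-encoded taxon),
adjusted for age, race/ethnicity, BMI, gender, pet ownership, smoking,
dietary fiber and antibiotic use.  Per-taxon scans are corrected for the
false discovery rate (Benjamini-Hochberg) within stratum and rendered as
volcano tables/plots.  Also produces the descriptive "Table 1" with
rank-sum tests for continuous variables and Fisher's exact test for
categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .prep import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    COVARIATE_COLUMNS,
    FeatureTable,
    quartile_encode,
)

STRATA = ("all", "secure", "insecure")


@dataclass
class AdjustedFit:
    """One exposure coefficient from a covariate-adjusted OLS fit.

    ``ci95`` is the normal-theory interval beta +/- 1.96*se; ``p_raw`` is
    the two-sided t-test p-value and ``p_fdr`` the BH-adjusted value when
    the fit is part of a multi-taxon scan.
    """

    exposure_name: str
    beta: float
    se: float
    ci95: tuple[float, float]
    p_raw: float
    n: int
    stratum: str = "all"
    p_fdr: float | None = None
    label: str | None = None


def stratum_mask(meta: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(meta), dtype=bool)
    if stratum == "secure":
        return meta["food_insecure"].to_numpy() == 0
    if stratum == "insecure":
        return meta["food_insecure"].to_numpy() == 1
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def _design(exposure: np.ndarray, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(exposure, dtype=float), np.asarray(exposure, dtype=float)]
    names = ["intercept", "exposure"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate offending columns from near-zero R diagonal of a pivoted QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(X.shape[1]) if diag[j] <= tol] or names
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_adjusted_lm(
    outcome,
    exposure,
    covariates=None,
    exposure_name: str = "exposure",
    stratum: str = "all",
) -> AdjustedFit:
    """OLS of outcome on exposure plus adjustment covariates.

    Requires complete data (imputation happens upstream) and n > number of
    parameters.  The exposure coefficient matches the normal-equations
    solution; its CI is beta +/- 1.96*se and p_raw the two-sided t-test.
    """
    y = np.asarray(outcome, dtype=float)
    X, names = _design(np.asarray(exposure, dtype=float), covariates)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in outcome/exposure/covariates; impute first")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > number of parameters ({k}), got n={n}")
    _check_rank(X, names)

    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    sigma2 = float(resid @ resid) / (n - k)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta = float(beta_hat[1])
    if se > 0:
        t = beta / se
        p = 2.0 * _st.t.sf(abs(t), df=n - k)
    else:
        p = 0.0 if beta != 0 else 1.0
    return AdjustedFit(
        exposure_name=exposure_name,
        beta=beta,
        se=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        p_raw=float(p),
        n=n,
        stratum=stratum,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def asv_scan(
    table: FeatureTable,
    meta: pd.DataFrame,
    stratum: str = "all",
    covariates: list[str] | None = None,
) -> list[AdjustedFit]:
    """Per-taxon adjusted regressions of RCI on quartile-encoded abundance.

    The table must already be prevalence-filtered; each taxon's relative
    abundance is converted to quartiles within the analysis set so that
    association estimates are comparable across taxa.  BH-FDR is applied
    over all taxa within the stratum.
    """
    covariates = COVARIATE_COLUMNS if covariates is None else covariates
    mask = stratum_mask(meta, stratum)
    sub_meta = meta.loc[mask]
    sub_tab = table.data.loc[mask]
    n = len(sub_meta)
    if n < len(covariates) + 2:
        raise ValueError(
            f"stratum {stratum!r} has n={n} < covariates+2={len(covariates) + 2}"
        )
    y = sub_meta["rci"].to_numpy(dtype=float)
    cov = sub_meta[covariates]
    fits = []
    for taxon in table.taxon_ids:
        quarts = quartile_encode(sub_tab[taxon].to_numpy())
        fit = fit_adjusted_lm(y, quarts, cov, exposure_name=taxon, stratum=stratum)
        fit.label = table.label_for(taxon)
        fits.append(fit)
    adj = bh_fdr([f.p_raw for f in fits])
    for f, q in zip(fits, adj):
        f.p_fdr = float(q)
    return fits


def fits_to_frame(fits: list[AdjustedFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "exposure": [f.exposure_name for f in fits],
            "label": [f.label or f.exposure_name for f in fits],
            "stratum": [f.stratum for f in fits],
            "beta": [f.beta for f in fits],
            "se": [f.se for f in fits],
            "ci_low": [f.ci95[0] for f in fits],
            "ci_high": [f.ci95[1] for f in fits],
            "p_raw": [f.p_raw for f in fits],
            "p_fdr": [f.p_fdr for f in fits],
            "n": [f.n for f in fits],
        }
    )


def volcano_data(fits: list[AdjustedFit]) -> pd.DataFrame:
    """Volcano-plot table: beta vs -log10 raw p per taxon, genus labels when
    available, with reference line heights at p=0.05 and p=0.01."""
    if not fits:
        raise ValueError("no fits to plot")
    df = fits_to_frame(fits)
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_raw"].to_numpy())
    df.attrs["reference_lines"] = {"p=0.05": -np.log10(0.05), "p=0.01": -np.log10(0.01)}
    return df


def volcano_plot(volcano: pd.DataFrame, path: str, title: str = "") -> None:
    """Scatter of beta vs -log10 p with horizontal reference lines at
    p=0.05 (red) and p=0.01 (black)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(volcano["beta"], volcano["neg_log10_p"], s=12, alpha=0.7)
    ax.axhline(-np.log10(0.05), color="red", lw=1)
    ax.axhline(-np.log10(0.01), color="black", lw=1)
    ax.set_xlabel("adjusted beta (per quartile)")
    ax.set_ylabel(r"$-\log_{10}$ raw p")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class DescriptiveRow:
    """One row of the descriptive cohort table: formatted overall and
    per-stratum summaries with the between-stratum test."""

    variable: str
    overall: str
    secure: str
    insecure: str
    test: str  # "rank-sum" | "exact"
    p: float


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p via the normal approximation with tie
    correction (asymptotic Mann-Whitney, no continuity correction)."""
    res = _st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return float(res.pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table [[a, b], [c, d]], summing
    probabilities of tables at most as likely as the observed one."""
    return float(_st.fisher_exact([[a, b], [c, d]])[1])


def descriptive_table(meta: pd.DataFrame) -> list[DescriptiveRow]:
    """Table-1 style summary by food-security status.

    Continuous variables get mean (SD) and a rank-sum p; binary variables
    get n (%) for the coded-1 level and a Fisher exact p.  Rows with
    missing values for a variable are dropped pairwise for that row.
    """
    sec = meta.loc[meta["food_insecure"] == 0]
    ins = meta.loc[meta["food_insecure"] == 1]
    rows: list[DescriptiveRow] = []

    continuous = [c for c in CONTINUOUS_COVARIATES if c in meta.columns]
    if "minicog" in meta.columns:
        continuous.append("minicog")
    if "shannon" in meta.columns:
        continuous.append("shannon")
    for var in continuous:
        xs, xi = sec[var].dropna(), ins[var].dropna()
        fmt = lambda s: f"{s.mean():.2f} ({s.std(ddof=1):.2f})"
        rows.append(
            DescriptiveRow(
                variable=var,
                overall=fmt(meta[var].dropna()),
                secure=fmt(xs),
                insecure=fmt(xi),
                test="rank-sum",
                p=rank_sum_test(xs, xi),
            )
        )

    for var in [c for c in BINARY_COVARIATES if c in meta.columns]:
        xs, xi = sec[var].dropna().astype(int), ins[var].dropna().astype(int)
        a, b = int(xs.sum()), int(xi.sum())
        c, d = int((1 - xs).sum()), int((1 - xi).sum())
        fmt = lambda k, n: f"{k} ({100.0 * k / n:.2f}%)" if n else "0 (0%)"
        rows.append(
            DescriptiveRow(
                variable=var,
                overall=fmt(a + b, len(xs) + len(xi)),
                secure=fmt(a, len(xs)),
                insecure=fmt(b, len(xi)),
                test="exact",
                p=fisher_exact_2x2(a, b, c, d),
            )
        )
    return rows


def descriptive_frame(rows: list[DescriptiveRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "overall": [r.overall for r in rows],
            "food_secure": [r.secure for r in rows],
            "food_insecure": [r.insecure for r in rows],
            "test": [r.test for r in rows],
            "p": [r.p for r in rows],
        }
    )
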