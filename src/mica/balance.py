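"""Sensitivity machinery: PMM imputation and covariate-balance diagnostics.

Sparse covariate missingness (<2% of cells in the motivating cohort) is
filled by predictive mean matching: each missing cell receives the observed
value of a donor whose regression-predicted value is nearest the target's,
so imputations always come from the observed support.  Confounding control
for the clique regressions is checked by propensity-score
subclassification: standardized mean differences (SMDs) per covariate
before and after subclassing, summarized as a love plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def pmm_impute(covariates: pd.DataFrame, k_donors: int = 5, seed: int = 0) -> pd.DataFrame:
    """Predictive-mean-matching imputation of missing covariate cells.

    For each column with missing values, a linear model of that column on
    the remaining covariates (mean-filled for prediction only) is fit on
    the complete cases; every missing cell is filled by the observed value
    of a donor drawn uniformly from the ``k_donors`` complete cases whose
    predictions are nearest the target's prediction.  Deterministic under
    ``seed``; a column that is entirely missing, more than half missing, or
    has fewer than ``k_donors`` complete rows is rejected.
    """
    df = pd.DataFrame(covariates).copy()
    num = df.astype(float)
    if not num.isna().any().any():
        return df
    rng = np.random.default_rng(seed)
    filled = num.fillna(num.mean())

    for col in num.columns:
        miss = num[col].isna()
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"column {col!r} is entirely missing")
        if miss.mean() >= 0.5:
            raise ValueError(f"column {col!r} has >=50% missingness")
        obs_idx = num.index[~miss]
        if len(obs_idx) < k_donors:
            raise ValueError(f"column {col!r} has fewer than {k_donors} complete rows")

        others = [c for c in num.columns if c != col]
        X = np.column_stack([np.ones(len(num))] + [filled[c].to_numpy() for c in others])
        y_obs = num.loc[obs_idx, col].to_numpy()
        X_obs = X[~miss.to_numpy()]
        beta, _, _, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
        pred = X @ beta
        pred_obs = pred[~miss.to_numpy()]

        for i in np.flatnonzero(miss.to_numpy()):
            d = np.abs(pred_obs - pred[i])
            donor_pool = np.argsort(d, kind="stable")[:k_donors]
            donor = donor_pool[rng.integers(0, len(donor_pool))]
            num.iloc[i, num.columns.get_loc(col)] = y_obs[donor]
    for col in num.columns:
        df[col] = num[col]
    return df


@dataclass
class BalanceReport:
    """Per-covariate SMDs before and after propensity subclassification,
    sorted by |SMD before| (the love-plot table)."""

    table: pd.DataFrame  # covariate, smd_before, smd_after
    n_subclasses: int

    def love_table(self) -> pd.DataFrame:
        return self.table


def _smd(x1: np.ndarray, x0: np.ndarray, pooled_sd: float) -> float:
    if pooled_sd <= 0:
        return 0.0
    return float((x1.mean() - x0.mean()) / pooled_sd)


def subclass_balance(
    exposure, covariates: pd.DataFrame, n_subclasses: int = 5
) -> BalanceReport:
    """Covariate balance before/after propensity-score subclassification.

    The exposure (clique present, indicator >= 1) is regressed linearly on
    the covariates to form a propensity-style score; samples are cut into
    ``n_subclasses`` by score quantiles.  SMD = (mean_exposed -
    mean_unexposed) / pooled SD, computed raw and as a
    subclass-size-weighted average (against the overall pooled SD).  A
    subclass containing only one exposure group is merged with its
    neighbor, with a warning.
    """
    z = np.asarray(exposure).astype(int)
    cov = pd.DataFrame(covariates).astype(float)
    if set(np.unique(z)) - {0, 1}:
        raise ValueError("exposure must be binary 0/1")
    if z.sum() == 0 or z.sum() == len(z):
        raise ValueError("both exposure groups must be non-empty")
    if cov.isna().any().any():
        raise ValueError("covariates contain missing values; impute first")

    X = np.column_stack([np.ones(len(z))] + [cov[c].to_numpy() for c in cov.columns])
    beta, _, _, _ = np.linalg.lstsq(X, z.astype(float), rcond=None)
    score = X @ beta

    edges = np.quantile(score, np.linspace(0, 1, n_subclasses + 1))
    edges = np.unique(edges)
    sub = np.clip(np.searchsorted(edges, score, side="right") - 1, 0, len(edges) - 2)

    # merge subclasses lacking one exposure group into their left neighbor
    labels = sorted(np.unique(sub))
    merged = True
    while merged and len(labels) > 1:
        merged = False
        for lab in list(labels):
            sel = sub == lab
            if z[sel].min() == z[sel].max():
                idx = labels.index(lab)
                target = labels[idx - 1] if idx > 0 else labels[idx + 1]
                warnings.warn(
                    f"subclass {lab} has a single exposure group; merging into {target}"
                )
                sub[sel] = target
                labels.remove(lab)
                merged = True
                break
    if len(labels) == 1 and z[sub == labels[0]].min() == z[sub == labels[0]].max():
        raise ValueError("subclassification degenerate: one exposure group only")

    rows = []
    for c in cov.columns:
        x = cov[c].to_numpy()
        x1, x0 = x[z == 1], x[z == 0]
        s1 = x1.std(ddof=1) if len(x1) > 1 else 0.0
        s0 = x0.std(ddof=1) if len(x0) > 1 else 0.0
        pooled = np.sqrt((s1**2 + s0**2) / 2.0)
        before = _smd(x1, x0, pooled)

        after_num, wsum = 0.0, 0.0
        for lab in labels:
            sel = sub == lab
            zs = z[sel]
            if zs.min() == zs.max():
                continue
            xs = x[sel]
            after_num += len(xs) * _smd(xs[zs == 1], xs[zs == 0], pooled)
            wsum += len(xs)
        after = after_num / wsum if wsum else 0.0
        rows.append({"covariate": c, "smd_before": before, "smd_after": after})

    table = pd.DataFrame(rows)
    table = table.reindex(
        table["smd_before"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    return BalanceReport(table=table, n_subclasses=len(labels))


def love_plot(report: BalanceReport, path: str, title: str = "") -> None:
    """Dot plot of |SMD| before (open) vs after (filled) subclassification,
    one row per covariate, with a reference line at 0.1."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = report.table
    ypos = np.arange(len(tab))[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(tab) + 1.5))
    ax.scatter(tab["smd_before"].abs(), ypos, facecolors="none", edgecolors="tab:blue",
               label="before")
    ax.scatter(tab["smd_after"].abs(), ypos, color="tab:orange", label="after")
    ax.axvline(0.1, color="grey", ls="--", lw=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(tab["covariate"])
    ax.set_xlabel("|standardized mean difference|")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
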