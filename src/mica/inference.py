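"""Stage 2 of MiCA: clique-indicator regression with permutation inference.

Each discovered clique is summarized per participant as an integer
indicator counting how many clique members are present (abundance > 0), so
a clique of two taxa yields values 0-2 and a clique of four yields 0-4.
The indicator enters a covariate-adjusted linear model of RCI as a
continuous exposure; its p-value is computed by permuting the outcome
(default 10^5 times) rather than relying on large-sample normality.
Analyses run within food-security strata, and a clique discovered in one
stratum is validated by refitting in the out-of-bag sample of the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _all_perms
from math import factorial

import numpy as np
import pandas as pd

from .prep import COVARIATE_COLUMNS, FeatureTable
from .scan import stratum_mask


@dataclass
class CliqueIndicator:
    """Per-sample count of clique members present (0..k).

    "Harboring the clique" is defined as indicator >= 1 and is the basis of
    the prevalence figures reported alongside each regression.
    """

    taxa: tuple
    values: np.ndarray

    def __post_init__(self):
        k = len(self.taxa)
        v = np.asarray(self.values)
        if v.size and (v.min() < 0 or v.max() > k):
            raise ValueError(f"indicator values must lie in 0..{k}")

    @property
    def harboring(self) -> np.ndarray:
        return self.values >= 1


@dataclass
class PermutationResult:
    """Covariate-adjusted exposure coefficient with a permutation p-value.

    ``p_robust`` uses add-one smoothing: (1 + #{|t_perm| >= |t_obs|}) /
    (1 + n_permutations), so it is never smaller than 1/(n_permutations+1).
    """

    beta: float
    se: float
    ci95: tuple
    p_robust: float
    n_permutations: int
    seed: int | None
    t_obs: float
    n: int
    stratum: str = "all"
    exhaustive: bool = False


def build_indicator(table: FeatureTable, clique) -> CliqueIndicator:
    """Count, per sample, how many clique taxa have abundance > 0."""
    taxa = tuple(sorted(clique.taxa if hasattr(clique, "taxa") else clique))
    if not taxa:
        raise ValueError("empty clique")
    unknown = [t for t in taxa if t not in table.data.columns]
    if unknown:
        raise KeyError(f"taxa not in feature table: {unknown}")
    values = (table.data[list(taxa)] > 0).sum(axis=1).to_numpy(dtype=int)
    return CliqueIndicator(taxa=taxa, values=values)


def _perm_t_stats(Q, R, j, Y):
    """Permutation statistic for coefficient j, one value per column of Y,
    under the design with QR = Q R.

    The statistic is t^2/(t^2 + dof) = beta_j^2/var_j / (beta_j^2/var_j +
    RSS), a bounded, strictly monotone transform of |t| that stays finite
    (= 1) for perfect fits, so exceedance counting is stable when RSS
    underflows to rounding error.  Returns (betas, stat)."""
    QtY = Q.T @ Y
    betas = np.linalg.solve(R, QtY)
    rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", QtY, QtY)
    rss = np.maximum(rss, 0.0)
    Rinv = np.linalg.inv(R)
    var_j = float((Rinv @ Rinv.T)[j, j])
    a = betas[j] ** 2 / var_j
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(a + rss > 0, a / (a + rss), 0.0)
    return betas[j], stat


def permutation_regression(
    outcome,
    indicator,
    covariates=None,
    n_permutations: int = 100_000,
    seed: int = 0,
    stratum: str = "all",
    exhaustive: bool | None = None,
) -> PermutationResult:
    """Covariate-adjusted OLS with a permutation p-value for the exposure.

    The observed fit gives beta and its normal-theory 95% CI; the p-value
    compares |t| of the exposure coefficient against its distribution under
    whole-vector permutations of the outcome (add-one smoothed).  When
    ``exhaustive`` is true (or n <= 7 and all n! orderings fit within
    ``n_permutations``) every permutation is enumerated instead of sampled.
    Deterministic under ``seed``.
    """
    y = np.asarray(outcome, dtype=float)
    x = indicator.values if isinstance(indicator, CliqueIndicator) else np.asarray(indicator, dtype=float)
    x = x.astype(float)
    n = len(y)
    if np.all(x == x[0]):
        raise ValueError("indicator is constant: no exposure variation to test")
    cols = [np.ones(n), x]
    if covariates is not None:
        cov = pd.DataFrame(covariates).to_numpy(dtype=float)
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values; impute before permutation inference")
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"need n > number of parameters ({k})")
    Q, R = np.linalg.qr(X)

    beta_col, stat_col = _perm_t_stats(Q, R, 1, y[:, None])
    beta_obs, stat_obs = float(beta_col[0]), float(stat_col[0])
    Rinv = np.linalg.inv(R)
    var_j = float((Rinv @ Rinv.T)[1, 1])
    rss = float(max(y @ y - (Q.T @ y) @ (Q.T @ y), 0.0))
    dof = n - k
    se = float(np.sqrt(rss / dof * var_j))
    with np.errstate(divide="ignore"):
        t_obs = abs(beta_obs) / se if se > 0 else (0.0 if beta_obs == 0 else np.inf)

    # count permutations at least as extreme, with a hair of tolerance so
    # exact ties survive floating-point noise
    cut = stat_obs - 1e-12

    if exhaustive is None:
        exhaustive = n <= 7 and factorial(n) <= n_permutations
    if exhaustive:
        if factorial(n) > 5_000_000:
            raise ValueError("exhaustive enumeration infeasible for this n")
        perms = np.array(list(_all_perms(range(n))), dtype=np.intp)
        n_perm = perms.shape[0]
        _, stat = _perm_t_stats(Q, R, 1, y[perms].T)
        exceed = int(np.sum(stat >= cut))
    else:
        if n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        rng = np.random.default_rng(seed)
        n_perm = int(n_permutations)
        exceed = 0
        chunk = max(1, min(n_perm, 20_000))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            Y = np.empty((n, b))
            for c in range(b):
                Y[:, c] = y[rng.permutation(n)]
            _, stat = _perm_t_stats(Q, R, 1, Y)
            exceed += int(np.sum(stat >= cut))
            done += b

    p = (1 + exceed) / (1 + n_perm)
    return PermutationResult(
        beta=beta_obs,
        se=se,
        ci95=(beta_obs - 1.96 * se, beta_obs + 1.96 * se),
        p_robust=float(p),
        n_permutations=n_perm,
        seed=None if exhaustive else seed,
        t_obs=t_obs,
        n=n,
        stratum=stratum,
        exhaustive=bool(exhaustive),
    )


@dataclass
class StratifiedCliqueResult:
    """Per-stratum permutation fits for one clique plus harboring
    prevalences, arranged for a forest plot against the null line."""

    taxa: tuple
    results: dict  # stratum -> PermutationResult
    prevalence: dict  # stratum -> (n_harboring, n_stratum)

    def forest_table(self) -> pd.DataFrame:
        rows = []
        for stratum, res in self.results.items():
            nh, ns = self.prevalence[stratum]
            rows.append(
                {
                    "clique": ",".join(self.taxa),
                    "stratum": stratum,
                    "beta": res.beta,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "p_robust": res.p_robust,
                    "n_harboring": nh,
                    "n": ns,
                    "prevalence_pct": 100.0 * nh / ns if ns else float("nan"),
                    "null_line": 0.0,
                }
            )
        return pd.DataFrame(rows)


def stratified_effects(
    table: FeatureTable,
    meta: pd.DataFrame,
    clique,
    covariates: list | None = None,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> StratifiedCliqueResult:
    """Fit the clique-indicator regression separately in the food-secure
    and food-insecure strata.

    Raises if a stratum is smaller than covariates+2 or if the clique is
    absent from every sample of a stratum (no exposure variation there).
    """
    covariates = COVARIATE_COLUMNS if covariates is None else covariates
    indicator = build_indicator(table, clique)
    results: dict = {}
    prevalence: dict = {}
    for i, stratum in enumerate(("secure", "insecure")):
        mask = stratum_mask(meta, stratum)
        ns = int(mask.sum())
        if ns == 0:
            raise ValueError(f"stratum {stratum!r} is empty")
        if ns < len(covariates) + 2:
            raise ValueError(
                f"stratum {stratum!r} has n={ns} < covariates+2={len(covariates) + 2}"
            )
        vals = indicator.values[mask]
        if np.all(vals == 0):
            raise ValueError(
                f"clique {indicator.taxa} absent from every sample of stratum {stratum!r}"
            )
        res = permutation_regression(
            meta.loc[mask, "rci"].to_numpy(),
            vals,
            meta.loc[mask, covariates],
            n_permutations=n_permutations,
            seed=seed + i,
            stratum=stratum,
        )
        results[stratum] = res
        prevalence[stratum] = (int((vals >= 1).sum()), ns)
    return StratifiedCliqueResult(taxa=indicator.taxa, results=results,
                                  prevalence=prevalence)


def cross_stratum_validate(
    table: FeatureTable,
    meta: pd.DataFrame,
    clique,
    discovered_in: str,
    covariates: list | None = None,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> PermutationResult:
    """Validate a clique discovered in one stratum by running the same
    adjusted permutation regression in the out-of-bag sample of the other
    stratum."""
    if discovered_in not in ("secure", "insecure"):
        raise ValueError("discovered_in must be 'secure' or 'insecure'")
    other = "insecure" if discovered_in == "secure" else "secure"
    covariates = COVARIATE_COLUMNS if covariates is None else covariates
    indicator = build_indicator(table, clique)
    mask = stratum_mask(meta, other)
    vals = indicator.values[mask]
    if np.all(vals == 0):
        raise ValueError(
            f"clique {indicator.taxa} absent from every sample of stratum {other!r}"
        )
    return permutation_regression(
        meta.loc[mask, "rci"].to_numpy(),
        vals,
        meta.loc[mask, covariates],
        n_permutations=n_permutations,
        seed=seed,
        stratum=other,
    )
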