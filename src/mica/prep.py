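"""Feature-table and outcome preparation.

Turns a raw sample x taxon abundance matrix and a survey metadata sheet into
the objects the downstream analysis consumes: per-sample relative abundances,
a prevalence-filtered taxon set, Shannon alpha diversity, quartile-encoded
taxa for comparable association scans, the food-insecurity exposure derived
from three survey questions, and the inverted/log-transformed cognitive
outcome (risk of cognitive impairment, RCI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

#: Covariate columns of the adjustment set, in canonical order.
COVARIATE_COLUMNS = [
    "age",
    "bmi",
    "fiber_g",
    "gender",
    "race_white_nh",
    "pet_owner",
    "ever_smoker",
    "antibiotics_year",
]

#: Continuous vs binary split of the adjustment set (used by imputation,
#: descriptive tables and the balance diagnostics).
CONTINUOUS_COVARIATES = ["age", "bmi", "fiber_g"]
BINARY_COVARIATES = [
    "gender",
    "race_white_nh",
    "pet_owner",
    "ever_smoker",
    "antibiotics_year",
]

#: Metadata columns that must be present before analysis.
REQUIRED_METADATA_COLUMNS = ["food_insecure", "minicog"] + COVARIATE_COLUMNS


@dataclass
class FeatureTable:
    """Sample x taxon relative-abundance matrix.

    ``data`` holds samples in rows and taxa in columns; values are relative
    abundances in [0, 1].  After rare-taxon removal row sums may be < 1 —
    abundances are deliberately NOT rescaled when taxa are dropped, so that
    each retained taxon keeps its original per-individual proportion.

    ``taxon_labels`` optionally maps taxon IDs to genus/species strings for
    display (volcano plots, clique reports).
    """

    data: pd.DataFrame
    taxon_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample IDs in feature table")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate taxon IDs in feature table")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1 + 1e-9):
            raise ValueError("relative abundances must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def label_for(self, taxon_id: str) -> str:
        if self.taxon_labels and taxon_id in self.taxon_labels:
            return self.taxon_labels[taxon_id]
        return taxon_id

    def subset_samples(self, mask_or_ids) -> "FeatureTable":
        sub = self.data.loc[mask_or_ids]
        return FeatureTable(sub, self.taxon_labels)


def derive_food_insecurity(q1, q2, q3):
    """Binary food-insecurity status from the three survey questions.

    A participant is food insecure (1) iff they answered yes to ANY of:
    emergency food use, concern about having enough food, or Food Stamp
    authorization, all over the last 12 months.  Accepts scalars or arrays
    of booleans / {0,1} / "yes"/"no" strings.
    """

    def _to01(q):
        a = np.asarray(q, dtype=object)
        out = np.empty(a.shape, dtype=int)
        for i, v in np.ndenumerate(a):
            if isinstance(v, str):
                s = v.strip().lower()
                if s in ("yes", "y", "1", "true"):
                    out[i] = 1
                elif s in ("no", "n", "0", "false"):
                    out[i] = 0
                else:
                    raise ValueError(f"unrecognized survey response: {v!r}")
            else:
                out[i] = 1 if bool(v) else 0
        return out

    res = np.maximum(np.maximum(_to01(q1), _to01(q2)), _to01(q3))
    if res.ndim == 0:
        return int(res)
    return res


def transform_outcome(minicog):
    """RCI outcome from the mini-cog word-recall count.

    The 0-3 recall score is inverted (so higher = more impairment) and
    log-transformed: ``rci = ln(1 + (3 - score))``.  The +1 offset is needed
    because an inverted score of 0 (perfect recall) has no finite log;
    ln(4 - score) is the minimal convention with rci(3) = 0.
    """
    m = np.asarray(minicog)
    if not np.all(np.isin(m, [0, 1, 2, 3])):
        bad = np.unique(m[~np.isin(m, [0, 1, 2, 3])])
        raise ValueError(f"mini-cog scores must be integers in 0..3, got {bad}")
    rci = np.log(4.0 - m.astype(float))
    if rci.ndim == 0:
        return float(rci)
    return rci


def inverse_transform_outcome(rci):
    """Recover the mini-cog score from an exactly transformed RCI value."""
    r = np.asarray(rci, dtype=float)
    m = np.rint(4.0 - np.exp(r)).astype(int)
    if not np.all((m >= 0) & (m <= 3)):
        raise ValueError("rci value does not correspond to a score in 0..3")
    if m.ndim == 0:
        return int(m)
    return m


def to_relative_abundance(counts) -> FeatureTable:
    """Convert a nonnegative count matrix to per-individual relative abundance.

    Each sample (row) is divided by its own total.  Samples with a zero
    total are rejected by name.
    """
    if isinstance(counts, FeatureTable):
        counts = counts.data
    df = pd.DataFrame(counts).astype(float)
    vals = df.to_numpy()
    if vals.size == 0:
        raise ValueError("empty count matrix")
    if (vals < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = vals.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = list(df.index[zero])
        raise ValueError(f"samples with zero total abundance: {bad}")
    rel = vals / totals[:, None]
    return FeatureTable(pd.DataFrame(rel, index=df.index, columns=df.columns))


def prevalence(table: FeatureTable) -> pd.Series:
    """Fraction of samples in which each taxon is present (abundance > 0)."""
    return (table.data > 0).mean(axis=0)


def prevalence_filter(table: FeatureTable, threshold: float = 0.05) -> FeatureTable:
    """Drop rare taxa: keep those present in strictly more than ``threshold``
    of samples.

    Presence means relative abundance > 0.  Remaining abundances are NOT
    rescaled, so each kept taxon retains its original proportion of the
    individual's community; row sums may fall below 1.
    """
    keep = prevalence(table) > threshold
    return FeatureTable(table.data.loc[:, keep[keep].index], table.taxon_labels)


def shannon_diversity(sample_abundances) -> float:
    """Shannon alpha diversity H = -sum p_i ln p_i (natural log).

    The input vector is renormalized to proportions over its nonzero
    entries, so raw counts, relative abundances, or filtered (non-resummed)
    abundances all give the same H.
    """
    p = np.asarray(sample_abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot compute diversity of an all-zero sample")
    # scipy normalizes and uses natural log; zero entries contribute 0
    return float(_st.entropy(p))


def shannon_per_sample(table: FeatureTable) -> pd.Series:
    """Shannon diversity for every sample of a feature table."""
    vals = table.values
    return pd.Series(
        [shannon_diversity(row) for row in vals],
        index=table.data.index,
        name="shannon",
    )


def quartile_encode(values) -> np.ndarray:
    """Encode a vector into quartile codes 1-4 by type-7 sample quantiles.

    Values equal to a cut-point go to the lower quartile.  Zero-inflated
    vectors need a special rule: if more than 25% of the values share one
    identical value (the point mass, typically 0), the entire mass receives
    code 1 and the remaining values are coded by their own quartiles.  A
    constant vector gets all-1 codes with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("quartile_encode expects a 1-D vector")
    if len(v) < 4:
        raise ValueError("need at least 4 values to form quartiles")

    uniq, counts = np.unique(v, return_counts=True)
    if len(uniq) == 1:
        warnings.warn("constant vector: all values assigned quartile 1")
        return np.ones(len(v), dtype=int)

    codes = np.empty(len(v), dtype=int)
    top = counts.argmax()
    if counts[top] > 0.25 * len(v):
        mass = uniq[top]
        is_mass = v == mass
        codes[is_mass] = 1
        rest = v[~is_mass]
        codes[~is_mass] = _plain_quartiles(rest)
        return codes
    return _plain_quartiles(v)


def _plain_quartiles(v: np.ndarray) -> np.ndarray:
    q1, q2, q3 = np.quantile(v, [0.25, 0.50, 0.75])  # type-7 (linear)
    return (1 + (v > q1).astype(int) + (v > q2).astype(int) + (v > q3).astype(int))


def validate_metadata(meta: pd.DataFrame) -> None:
    """Check the metadata sheet has every analysis column; raise naming any
    missing column before compute starts."""
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")


def prepare_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Drop samples lacking food-insecurity status or cognitive score and
    attach the transformed RCI outcome.

    Covariate missingness is left in place (it is imputed downstream); only
    the exposure/outcome completeness rule is applied here.
    """
    validate_metadata(meta)
    out = meta.copy()
    keep = out["food_insecure"].notna() & out["minicog"].notna()
    out = out.loc[keep].copy()
    out["food_insecure"] = out["food_insecure"].astype(int)
    out["minicog"] = out["minicog"].astype(int)
    out["rci"] = transform_outcome(out["minicog"].to_numpy())
    return out
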