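"""Two-cohort metabolomics preprocessing.

Turns raw sample x metabolite intensity matrices (nonnegative, with
missing values and batch labels) into a model-ready design:

* batch normalization — each metabolite divided by its within-batch median;
* subject QC — remove samples whose median metabolite z-score is a gross
  cohort outlier;
* missingness tiers — per-metabolite missing fraction maps to
  IMPUTE (< 20%), INDICATOR (20–80%, dichotomized to present/absent) or
  DROP (> 80%);
* cross-cohort harmonization — keep only metabolites with concordant
  handling in both cohorts;
* kNN imputation (k = 10) of the continuous block on the natural-log
  scale, then a combined design of log columns and 0/1 indicator columns
  with a serializable recipe so the validation cohort is transformed with
  the training plan;
* a Table-1-style cohort comparison (t-tests; chi-squared with continuity
  correction for 2x2 tables, Fisher's exact when expected counts are
  small).

Boundary semantics: missing fractions of exactly 0.20 or 0.80 are
INDICATOR (the dichotomized band is the closed interval [0.20, 0.80]).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "batch_median_normalize",
    "subject_qc_filter",
    "categorize_missingness",
    "harmonize",
    "knn_impute",
    "make_design",
    "HarmonizedDesign",
    "Recipe",
    "cohort_compare",
    "read_abundance_tsv",
]

IMPUTE, INDICATOR, DROP = "IMPUTE", "INDICATOR", "DROP"


@dataclass
class AbundanceMatrix:
    """Raw sample x metabolite intensities with batch labels.

    ``values``: DataFrame (rows = samples, columns = metabolites), NaN for
    missing, all observed entries nonnegative.  ``batch``: Series indexed by
    sample id.  ``metabolite_meta``: optional DataFrame indexed by metabolite
    id with columns like super_pathway / sub_pathway / kegg_id.
    """

    values: pd.DataFrame
    batch: pd.Series
    metabolite_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate metabolite ids")
        vals = self.values.to_numpy(float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("intensities must be nonnegative")
        self.batch = self.batch.reindex(self.values.index)
        if self.batch.isna().any():
            raise ValueError("every sample needs a batch label")

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def metabolite_ids(self):
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[sample_ids].copy(),
                               self.batch.loc[sample_ids].copy(),
                               self.metabolite_meta)

    def to_tsv(self, path):
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_abundance_tsv(values_path, clinical, batch_col="batch",
                       metabolite_meta=None) -> AbundanceMatrix:
    """Read a sample x metabolite TSV ("NA" missing) plus batch labels.

    ``clinical`` is a DataFrame indexed by sample id (or a CSV path with a
    ``sample_id`` column) carrying the batch column.
    """
    values = pd.read_csv(values_path, sep="\t", index_col="sample_id",
                         na_values=["NA"])
    if not isinstance(clinical, pd.DataFrame):
        clinical = pd.read_csv(clinical, index_col="sample_id")
    return AbundanceMatrix(values, clinical[batch_col], metabolite_meta)


# ---------------------------------------------------------------------------


def batch_median_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each metabolite by its within-batch median (missing untouched).

    After normalization every (batch, metabolite) with at least one observed
    value has median 1.  A metabolite entirely missing within a batch is left
    missing with a logged warning (it will be handled by tiering).
    """
    out = matrix.values.copy()
    for b, idx in matrix.batch.groupby(matrix.batch).groups.items():
        block = out.loc[idx]
        med = block.median(axis=0, skipna=True)
        all_missing = med.isna()
        if all_missing.any():
            logger.warning(
                "batch %s: %d metabolite(s) entirely missing; left as missing",
                b, int(all_missing.sum()))
            med = med.fillna(1.0)
        out.loc[idx] = block / med
    return AbundanceMatrix(out, matrix.batch.copy(), matrix.metabolite_meta)


def subject_qc_filter(matrix: AbundanceMatrix, sd_limit=3.0):
    """Remove gross outlier subjects by aggregate metabolite z-score.

    Per metabolite, z-scores are computed across samples (non-missing only,
    population SD); per subject the median z across metabolites; subjects
    whose median lies more than ``sd_limit`` SDs from the cohort mean of
    the medians are removed.  Returns (kept_ids, removed_ids).
    """
    vals = matrix.values
    if len(vals) < 3:
        raise ValueError("subject QC needs at least 3 samples")
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=0, skipna=True).replace(0, np.nan)
    z = (vals - mean) / sd
    med = z.median(axis=1, skipna=True)
    spread = med.std(ddof=0)
    if spread == 0 or np.isnan(spread):
        removed = pd.Index([])
    else:
        removed = med.index[(med - med.mean()).abs() > sd_limit * spread]
    kept = vals.index.difference(removed, sort=False)
    return list(kept), list(removed)


def categorize_missingness(matrix: AbundanceMatrix, low=0.20, high=0.80) -> pd.DataFrame:
    """Per-metabolite missing fraction and handling tier.

    fraction < low -> IMPUTE; low <= fraction <= high -> INDICATOR;
    fraction > high -> DROP.  Returns a DataFrame indexed by metabolite id
    with columns ``missing_fraction`` and ``category``.
    """
    frac = matrix.values.isna().mean(axis=0)
    cat = pd.Series(INDICATOR, index=frac.index)
    cat[frac < low] = IMPUTE
    cat[frac > high] = DROP
    return pd.DataFrame({"missing_fraction": frac, "category": cat})


def harmonize(cat_a: pd.DataFrame, cat_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-cohort feature plan on the shared metabolites.

    Metabolites IMPUTE in both cohorts stay continuous, INDICATOR in both
    stay binary; anything discordant or DROP in either cohort is dropped.
    Returns a DataFrame indexed by metabolite with columns ``category_a``,
    ``category_b`` and ``handling`` in {continuous, indicator, dropped}.
    """
    common = cat_a.index.intersection(cat_b.index)
    if len(common) == 0:
        raise ValueError("cohorts share no metabolite ids")
    a = cat_a.loc[common, "category"]
    b = cat_b.loc[common, "category"]
    handling = pd.Series("dropped", index=common)
    handling[(a == IMPUTE) & (b == IMPUTE)] = "continuous"
    handling[(a == INDICATOR) & (b == INDICATOR)] = "indicator"
    return pd.DataFrame({"category_a": a, "category_b": b, "handling": handling})


def knn_impute(df: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """k-nearest-neighbour imputation of a continuous feature block.

    Distances are Euclidean over the features observed in both samples,
    scaled by the number of shared features; each missing cell becomes the
    unweighted mean of that feature among the k nearest samples with the
    feature observed (all available if fewer than k).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if df.shape[1] and df.isna().all(axis=0).any():
        bad = list(df.columns[df.isna().all(axis=0)])
        raise ValueError(f"feature(s) with no observed values: {bad}")
    if not df.isna().any().any():
        return df.copy()
    k_eff = min(int(k), max(len(df) - 1, 1))
    imputer = KNNImputer(n_neighbors=k_eff, weights="uniform",
                         metric="nan_euclidean")
    out = imputer.fit_transform(df.to_numpy(float))
    return pd.DataFrame(out, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------


@dataclass
class Recipe:
    """Everything needed to rebuild the design for a new cohort.

    Stores the harmonization plan (feature handling), the kNN parameter,
    the log base, and the batch medians observed when the recipe was built
    (for audit; a new cohort is normalized by its own batch medians, as
    each study is normalized within itself).
    """

    handling: dict            # metabolite -> "continuous" | "indicator"
    k: int = 10
    log_base: str = "e"
    sd_limit: float = 3.0
    batch_medians: dict = field(default_factory=dict)

    def to_json(self, path=None):
        s = json.dumps({"handling": self.handling, "k": self.k,
                        "log_base": self.log_base, "sd_limit": self.sd_limit,
                        "batch_medians": self.batch_medians})
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(handling=obj["handling"], k=obj["k"], log_base=obj["log_base"],
                   sd_limit=obj.get("sd_limit", 3.0),
                   batch_medians=obj.get("batch_medians", {}))


@dataclass
class HarmonizedDesign:
    """Model-ready design: log-continuous columns plus 0/1 indicator columns."""

    design: pd.DataFrame
    recipe: Recipe

    @property
    def feature_names(self):
        return list(self.design.columns)

    def to_tsv(self, path):
        self.design.to_csv(path, sep="\t", index_label="sample_id")


def make_design(matrix: AbundanceMatrix, plan: pd.DataFrame | None = None,
                recipe: Recipe | None = None, k: int = 10) -> HarmonizedDesign:
    """Build the harmonized design from a raw abundance matrix.

    Continuous features: batch-median normalized, natural-log transformed
    (nonpositive values treated as missing, logged), then kNN-imputed on the
    log scale.  Indicator features: 1 if observed, 0 if missing.  Column
    order is deterministic (sorted feature name).  Supply either a ``plan``
    from :func:`harmonize` (training cohort) or a ``recipe`` from a previous
    call (validation cohort).
    """
    if recipe is not None:
        handling = recipe.handling
        k = recipe.k
    elif plan is not None:
        handling = plan.loc[plan["handling"] != "dropped", "handling"].to_dict()
    else:
        raise ValueError("make_design needs a plan or a recipe")

    cont = sorted(m for m, h in handling.items() if h == "continuous")
    ind = sorted(m for m, h in handling.items() if h == "indicator")
    missing_feats = [m for m in cont + ind if m not in matrix.values.columns]
    if missing_feats:
        raise ValueError(f"matrix lacks planned metabolites: {missing_feats[:5]}...")

    normed = batch_median_normalize(matrix)
    medians = {
        str(b): matrix.values.loc[idx].median(axis=0, skipna=True).to_dict()
        for b, idx in matrix.batch.groupby(matrix.batch).groups.items()
    }

    blocks = []
    if cont:
        cvals = normed.values[cont]
        nonpos = (cvals <= 0)
        if nonpos.any().any():
            logger.warning("%d nonpositive value(s) treated as missing before log",
                           int(nonpos.sum().sum()))
            cvals = cvals.mask(nonpos)
        logged = np.log(cvals)
        imputed = knn_impute(logged, k=k)
        blocks.append(imputed)
    if ind:
        indicators = (~matrix.values[ind].isna()).astype(float)
        indicators.columns = [f"{m}__present" for m in ind]
        blocks.append(indicators)
    if not blocks:
        raise ValueError("plan retains no features")
    design = pd.concat(blocks, axis=1)
    design = design[sorted(design.columns)]
    out_recipe = Recipe(handling=dict(handling), k=int(k), log_base="e",
                        batch_medians=medians)
    return HarmonizedDesign(design=design, recipe=out_recipe)


# ---------------------------------------------------------------------------


@dataclass
class CohortCompareRow:
    variable: str
    summary_a: str
    summary_b: str
    test: str
    p: float


def _continuous_row(name, a, b, pooled=True):
    a = a.dropna().to_numpy(float)
    b = b.dropna().to_numpy(float)
    stat, p = stats.ttest_ind(a, b, equal_var=pooled)
    fmt = lambda x: f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f})"
    test = "t-test" if pooled else "Welch t-test"
    return CohortCompareRow(name, fmt(a), fmt(b), test, float(p))


def _categorical_row(name, a, b):
    a = a.dropna().astype(str)
    b = b.dropna().astype(str)
    levels = sorted(set(a) | set(b))
    ca = a.value_counts().reindex(levels, fill_value=0)
    cb = b.value_counts().reindex(levels, fill_value=0)
    table = np.vstack([ca.to_numpy(), cb.to_numpy()]).T  # levels x cohorts
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        return CohortCompareRow(name, _count_summary(ca), _count_summary(cb),
                                "none (single level)", 1.0)
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any() and table.shape == (2, 2):
        _, p = stats.fisher_exact(table)
        test = "Fisher's exact"
    elif table.shape == (2, 2):
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
        test = "chi-squared (corrected)"
    else:
        if (expected < 5).any():
            warnings.warn(f"{name}: expected counts < 5 in an RxC table; "
                          "chi-squared p may be unreliable")
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        test = "chi-squared"
    return CohortCompareRow(name, _count_summary(ca), _count_summary(cb),
                            test, float(p))


def _count_summary(counts):
    total = counts.sum()
    parts = [f"{lvl}: {c} ({100*c/total:.1f}%)" for lvl, c in counts.items()]
    return "; ".join(parts)


def cohort_compare(clin_a: pd.DataFrame, clin_b: pd.DataFrame, variables=None,
                   pooled=True) -> pd.DataFrame:
    """Table-1-style comparison of two clinical tables.

    Continuous variables get a two-sample t-test (pooled by default, Welch
    via ``pooled=False``); categorical variables a chi-squared test
    (continuity-corrected for 2x2) or Fisher's exact when expected counts
    fall below 5 in a 2x2 table.  Variables absent from either cohort are
    skipped with a warning.
    """
    if variables is None:
        variables = [c for c in clin_a.columns if c in clin_b.columns]
    rows = []
    for v in variables:
        if v not in clin_a.columns or v not in clin_b.columns:
            warnings.warn(f"variable {v!r} missing in one cohort; skipped")
            continue
        a, b = clin_a[v], clin_b[v]
        if pd.api.types.is_numeric_dtype(a) and pd.api.types.is_numeric_dtype(b) \
                and not _looks_binary_categorical(a, b):
            rows.append(_continuous_row(v, a, b, pooled=pooled))
        else:
            rows.append(_categorical_row(v, a, b))
    return pd.DataFrame([r.__dict__ for r in rows])


def _looks_binary_categorical(a, b):
    vals = pd.concat([a, b]).dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}
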