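"""Cohort-level statistics on diversity estimates.

Covers the downstream analyses run once per-sample biodiversity numbers
are available: read-depth outlier removal, within-dataset
standardization, covariate adjustment, the natural-cubic-spline age-trend
model with per-dataset deviations, pairwise Mann-Whitney group tests, the
four-criterion elderly health classifier, the PCA health score, and
leave-one-out cross-validated health prediction with AUC.

The age-trend model regresses a standardized diversity index on a
natural cubic spline basis of age (df = 3 by default, knots at age
quantiles), with the dataset factor in sum-to-zero (deviation) coding
interacting with the spline terms, plus sex and standardized read depth.
Under deviation coding the uncontrasted spline coefficients read as the
grand-mean ("global") trend across datasets, invariant to dataset sample
sizes when the per-dataset effects are equal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "HealthLabel",
    "SplineFitResult",
    "PredictionResult",
    "remove_read_outliers",
    "standardize_within_dataset",
    "adjust_for_covariates",
    "natural_spline_basis",
    "fit_age_trend",
    "select_spline_df",
    "pairwise_group_test",
    "classify_health",
    "health_pc_score",
    "rank_auc",
    "loo_predict_health",
]

RESIDENCE_HEALTHY = ("Community", "Day-Hospital")
RESIDENCE_SETTINGS = ("Community", "Day-Hospital", "Rehabilitation", "Long-stay")


def remove_read_outliers(
    cohort: pd.DataFrame, z_threshold: float = 4.0, reads_col: str = "total_reads"
) -> pd.DataFrame:
    """Drop subjects whose total read count is a z-score outlier.

    The z-scores are computed once on the input table; removal is not
    iterated.  With zero read-count variance nothing is removed and a
    warning is issued.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    reads = cohort[reads_col].to_numpy(dtype=np.float64)
    sd = reads.std(ddof=0)
    if sd == 0:
        warnings.warn("read counts have zero variance; no outliers removed")
        return cohort.copy()
    z = np.abs(reads - reads.mean()) / sd
    return cohort.loc[z <= z_threshold].copy()


def standardize_within_dataset(
    values: Sequence[float], dataset_labels: Sequence
) -> np.ndarray:
    """Z-score values separately within each dataset label."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(dataset_labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    out = np.empty_like(values)
    for lab in np.unique(labels):
        mask = labels == lab
        if mask.sum() < 2:
            raise ValueError(f"dataset {lab!r} has fewer than 2 subjects")
        sub = values[mask]
        sd = sub.std(ddof=0)
        if sd == 0:
            raise ValueError(f"dataset {lab!r} has constant values")
        out[mask] = (sub - sub.mean()) / sd
    return out


def adjust_for_covariates(
    y: Sequence[float], covariate_matrix: np.ndarray
) -> np.ndarray:
    """OLS residuals of y on the covariates plus an intercept."""
    y = np.asarray(y, dtype=np.float64)
    X = np.column_stack([np.ones(len(y)), np.asarray(covariate_matrix, dtype=np.float64)])
    if X.shape[0] != y.shape[0]:
        raise ValueError("row mismatch between y and covariates")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"covariate matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def natural_spline_basis(
    age: Sequence[float], df: int = 3, knots: Sequence[float] | None = None
) -> np.ndarray:
    """Natural cubic spline basis of age: df columns, C2 everywhere,
    linear beyond the boundary knots.

    Knots default to equally spaced age quantiles with the boundary knots
    at the age extremes (patsy's ``cr`` convention).
    """
    age = np.asarray(age, dtype=np.float64)
    if np.unique(age).size < df + 2:
        raise ValueError(f"need at least df + 2 = {df + 2} distinct ages")
    if knots is not None:
        design = patsy.dmatrix(
            "cr(age, knots=knots) - 1", {"age": age, "knots": list(knots)},
            return_type="matrix",
        )
    else:
        design = patsy.dmatrix(
            f"cr(age, df={df}) - 1", {"age": age}, return_type="matrix"
        )
    return np.asarray(design)


@dataclass
class SplineFitResult:
    """Coefficients and t-test p-values of the age-trend model."""

    index_name: str
    df: int
    global_coefficients: pd.Series     # intercept + spline1..df (grand mean)
    global_pvalues: pd.Series
    dataset_deviations: pd.DataFrame   # term x dataset deviation coefficients
    dataset_pvalues: pd.DataFrame
    covariate_coefficients: pd.Series  # sex, standardized reads
    covariate_pvalues: pd.Series
    aic: float
    bic: float
    model_result: object               # the underlying statsmodels fit

    @property
    def spline_coefficients(self) -> np.ndarray:
        return self.global_coefficients.iloc[1:].to_numpy()


def _age_trend_formula(df: int) -> str:
    return f"y ~ cr(age, df={df}) * C(dataset, Sum) + sex + reads_std"


def _prepare_trend_frame(cohort: pd.DataFrame, index_name: str) -> pd.DataFrame:
    required = {index_name, "age", "sex", "total_reads", "dataset"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    data = cohort.copy()
    data["y"] = standardize_within_dataset(
        data[index_name].to_numpy(), data["dataset"].to_numpy()
    )
    reads = data["total_reads"].to_numpy(dtype=np.float64)
    data["reads_std"] = (reads - reads.mean()) / reads.std(ddof=0)
    return data


def fit_age_trend(
    cohort: pd.DataFrame, index_name: str, df: int = 3
) -> SplineFitResult:
    """Fit the spline age-trend model for one diversity index.

    ``cohort`` needs columns ``age``, ``sex`` (0/1), ``total_reads``,
    ``dataset`` and the index itself.  The index is standardized within
    each dataset before fitting.  Datasets spanning fewer than two
    inter-knot intervals produce ill-determined deviation terms; a
    warning is issued and statsmodels' pseudoinverse handles the
    deficiency.
    """
    if cohort["dataset"].nunique() < 2:
        raise ValueError("need at least 2 datasets for deviation coding")
    data = _prepare_trend_frame(cohort, index_name)
    # warn when a dataset's age range cannot identify its spline deviations
    quantiles = np.quantile(data["age"], np.linspace(0, 1, df + 1))
    for lab, sub in data.groupby("dataset"):
        spanned = np.searchsorted(quantiles[1:-1], [sub["age"].min(), sub["age"].max()])
        if spanned[1] - spanned[0] < 1 and df > 1:
            warnings.warn(
                f"dataset {lab!r} spans fewer than 2 knot intervals; its "
                "spline deviation terms are weakly identified"
            )
    res = sm.OLS.from_formula(_age_trend_formula(df), data=data).fit()
    params, pvals = res.params, res.pvalues
    spline_terms = [f"cr(age, df={df})[{j}]" for j in range(df)]
    global_names = ["Intercept", *spline_terms]
    glob = params[global_names]
    glob.index = ["intercept"] + [f"spline{j + 1}" for j in range(df)]
    glob_p = pvals[global_names]
    glob_p.index = glob.index
    dev_rows = {}
    dev_pv = {}
    for name in params.index:
        if "C(dataset, Sum)" not in name:
            continue
        level = name.split("S.", 1)[1].rstrip("]")
        term = "intercept" if not name.startswith("cr(") else (
            "spline" + str(int(name.split(")[", 1)[1].split("]")[0]) + 1)
        )
        dev_rows.setdefault(level, {})[term] = params[name]
        dev_pv.setdefault(level, {})[term] = pvals[name]
    covs = params[["sex", "reads_std"]]
    covs_p = pvals[["sex", "reads_std"]]
    return SplineFitResult(
        index_name=index_name,
        df=df,
        global_coefficients=glob,
        global_pvalues=glob_p,
        dataset_deviations=pd.DataFrame(dev_rows).T,
        dataset_pvalues=pd.DataFrame(dev_pv).T,
        covariate_coefficients=covs,
        covariate_pvalues=covs_p,
        aic=float(res.aic),
        bic=float(res.bic),
        model_result=res,
    )


def select_spline_df(
    cohort: pd.DataFrame, index_name: str, df_grid: Sequence[int] = (3, 4, 5, 6)
) -> tuple[int, pd.DataFrame]:
    """AIC/BIC over a grid of spline degrees of freedom (each >= 3; the
    quantile-knot natural cubic basis needs at least three columns).

    Returns the chosen df (smallest AIC, BIC breaking ties) and the
    criterion table.
    """
    if len(df_grid) == 0:
        raise ValueError("df_grid must be non-empty")
    rows = []
    for df in df_grid:
        fit = fit_age_trend(cohort, index_name, df=df)
        rows.append({"df": df, "aic": fit.aic, "bic": fit.bic})
    table = pd.DataFrame(rows).set_index("df")
    best = table.sort_values(["aic", "bic"]).index[0]
    return int(best), table


def pairwise_group_test(
    values: Sequence[float], group_labels: Sequence
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests for every unordered pair of groups.

    Uses the exact null when the smaller group has <= 8 subjects and the
    data are tie-free, the tie-corrected normal approximation otherwise.
    Values should already be covariate-adjusted.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(group_labels)
    groups = {lab: values[labels == lab] for lab in pd.unique(labels)}
    for lab, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 subjects")
    rows = []
    for a, b in combinations(groups, 2):
        xa, xb = groups[a], groups[b]
        tie_free = np.unique(np.concatenate([xa, xb])).size == xa.size + xb.size
        method = "exact" if (min(xa.size, xb.size) <= 8 and tie_free) else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append(
            {"group_a": a, "group_b": b, "U": float(res.statistic),
             "p_value": float(res.pvalue), "method": method}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HealthLabel:
    """Outcome of the four-criterion elderly health rule."""

    points: tuple[int, int, int, int]  # Barthel, MMSE, FIM, residence
    total: int
    healthy: bool


def classify_health(
    barthel: float, mmse: float, fim: float, residence: str
) -> HealthLabel:
    """One point each for Barthel >= 15, MMSE >= 24, FIM >= 100 and
    residence in the community or a day hospital; healthy iff >= 3 points."""
    for name, val in (("barthel", barthel), ("mmse", mmse), ("fim", fim)):
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise ValueError(f"missing {name} score (imputation is out of scope)")
    if residence not in RESIDENCE_SETTINGS:
        raise ValueError(f"unknown residence setting {residence!r}")
    points = (
        int(barthel >= 15),
        int(mmse >= 24),
        int(fim >= 100),
        int(residence in RESIDENCE_HEALTHY),
    )
    total = sum(points)
    return HealthLabel(points=points, total=total, healthy=total >= 3)


def health_pc_score(
    score_matrix: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """First-principal-component health score per subject.

    Columns (Barthel, MMSE, FIM, residence coded 1 for Community or
    Day-Hospital) are standardized; the first principal axis is
    sign-fixed so that a higher score means healthier (positive loading
    on the first column, Barthel).  Returns (scores, variance-explained
    fractions).
    """
    X = np.asarray(score_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 subjects")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"column {bad} is constant; PCA is undefined")
    Z = (X - X.mean(axis=0)) / sd
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    explained = svals**2 / np.sum(svals**2)
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    return Z @ axis, explained


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with midrank ties."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class PredictionResult:
    """Leave-one-out health-score predictions and their discrimination."""

    predicted_scores: np.ndarray
    true_scores: np.ndarray
    true_labels: np.ndarray       # healthy = True
    predicted_labels: np.ndarray  # thresholded predictions
    threshold: float
    auc: float


def loo_predict_health(
    cohort: pd.DataFrame,
    predictor_names: Sequence[str],
    score_col: str = "health_score",
    label_col: str = "healthy",
) -> PredictionResult:
    """LOO-cross-validated linear prediction of the PC health score.

    For every subject an OLS model trained on the remaining n-1 subjects
    predicts the held-out score.  AUC (rank formulation) measures how
    well the predicted scores separate the true healthy/unhealthy labels;
    predicted labels use the threshold midway between the true-label
    class means of the observed PC score.
    """
    n = len(cohort)
    if n < 3:
        raise ValueError("need at least 3 subjects for LOO")
    X = np.column_stack(
        [np.ones(n)] + [cohort[p].to_numpy(dtype=np.float64) for p in predictor_names]
    )
    y = cohort[score_col].to_numpy(dtype=np.float64)
    labels = cohort[label_col].to_numpy(dtype=bool)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi = X[mask]
        if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
            raise ValueError(f"rank-deficient design when holding out row {i}")
        beta, *_ = np.linalg.lstsq(Xi, y[mask], rcond=None)
        preds[i] = X[i] @ beta
    if labels.all() or not labels.any():
        raise ValueError("both health classes must be present")
    threshold = 0.5 * (y[labels].mean() + y[~labels].mean())
    return PredictionResult(
        predicted_scores=preds,
        true_scores=y,
        true_labels=labels,
        predicted_labels=preds >= threshold,
        threshold=float(threshold),
        auc=rank_auc(labels, preds),
    )
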