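"""Statistical layer: predictor comparison, expression association,
expression-threshold search, threshold validation, and tissue-average
outlier analysis.

The linear model throughout is ordinary least squares,
y = X beta + eps with eps ~ N(0, sigma^2 I), and goodness of fit is
R^2 = 1 - SS_res / SS_tot with SS_tot taken about the mean of y.

The threshold finder scans every midpoint between consecutive distinct
sorted expression values whose induced split leaves at least
``min_group_size`` lines on each side, scores each split with a
two-sample t-test on the phenotype scores, and returns the most
significant split.  Because the minimum p over many candidate splits is
itself a selected statistic, its null distribution is NOT uniform; an
optional permutation-adjusted p-value calibrates for that selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .conditions import normalize_gene

logger = logging.getLogger(__name__)

#: Expression drivers associated with each single-agent phenotype and the
#: sign of the association (+1: higher expression => higher dependence).
DEFAULT_ASSOCIATION_DIRECTIONS: dict[str, tuple[str, int]] = {
    "A199": ("BCL2", +1),
    "W539": ("PMAIP1", +1),
    "A121": ("BCL2L1", -1),
}


# ---------------------------------------------------------------------------
# Linear models
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """An OLS fit of sensitivity scores on a labelled design matrix."""

    phenotype: str
    labels: list[str]
    beta: np.ndarray
    pvalues: dict[str, float]
    sigma2: float
    r2: float
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    y: np.ndarray


def fit_linear(
    y: Sequence[float],
    X: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
    phenotype: str = "",
) -> LinearFit:
    """Ordinary least squares of ``y`` on ``X`` (which must carry an intercept).

    Per-column two-sided p-values come from the t distribution with
    n - p degrees of freedom.  A rank-deficient design is rejected with
    the offending columns named rather than silently pseudo-inverted.
    """
    if isinstance(X, pd.DataFrame):
        labels = list(X.columns) if labels is None else list(labels)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        labels = [f"x{i}" for i in range(X.shape[1])] if labels is None else list(labels)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per observation in y")
    if y.shape[0] <= X.shape[1]:
        raise ValueError("need n > number of design columns")
    is_const = np.all(X == X[0, :], axis=0)
    if not np.any(is_const & (X[0, :] != 0)):
        raise ValueError("design matrix must include an intercept column")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, labels)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    model = sm.OLS(y, X).fit()
    intercept_idx = int(np.argmax(is_const & (X[0, :] != 0)))
    pvals = {
        lab: float(model.pvalues[i])
        for i, lab in enumerate(labels)
        if i != intercept_idx
    }
    return LinearFit(
        phenotype=phenotype,
        labels=list(labels),
        beta=np.asarray(model.params, dtype=float),
        pvalues=pvals,
        sigma2=float(model.mse_resid) if model.df_resid > 0 else float("nan"),
        r2=float(model.rsquared) if np.var(y) > 0 else 0.0,
        n=int(y.shape[0]),
        residuals=np.asarray(model.resid, dtype=float),
        fitted=np.asarray(model.fittedvalues, dtype=float),
        y=y,
    )


def _collinear_columns(X: np.ndarray, labels: Sequence[str]) -> list[str]:
    kept: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(labels[j])
    return bad


def r_squared(fit: LinearFit) -> float:
    """R^2 = 1 - SS_res/SS_tot, SS_tot about the mean of the observed y.

    For a constant y (SS_tot = 0) the statistic is defined as 0 with a
    warning: there is no variance to explain.
    """
    ss_tot = float(np.sum((fit.y - fit.y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant response: R^2 defined as 0", stacklevel=2)
        return 0.0
    ss_res = float(np.sum(fit.residuals**2))
    return 1.0 - ss_res / ss_tot


def _design_with_intercept(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Prefix an intercept and drop constant or duplicated columns."""
    dropped = [c for c in frame.columns if frame[c].nunique() <= 1]
    frame = frame.drop(columns=dropped)
    out = pd.DataFrame({"intercept": np.ones(len(frame))}, index=frame.index)
    out = pd.concat([out, frame.astype(float)], axis=1)
    return out, dropped


def compare_predictors(
    scores: pd.DataFrame,
    tissue_labels: pd.Series,
    mutations: pd.DataFrame,
    phenotypes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tissue-of-origin vs mutation-status goodness-of-fit comparison.

    ``scores``: wide matrix of dependency scores (cell lines x
    conditions).  ``mutations``: binary gene x cell-line table (mutant
    includes amplifications/deletions, a single state).  For each
    phenotype a tissue-only and a mutation-only OLS model is fitted on
    the shared cell lines and their R^2 values compared.
    """
    phenotypes = list(phenotypes) if phenotypes is not None else list(scores.columns)
    shared = scores.index.intersection(tissue_labels.index).intersection(
        mutations.columns
    )
    n_pred = max(tissue_labels.loc[shared].nunique(), mutations.shape[0])
    if len(shared) < 3 + n_pred:
        raise ValueError(
            f"only {len(shared)} shared cell lines; need at least {3 + n_pred}"
        )
    tissue_design = pd.get_dummies(
        tissue_labels.loc[shared], drop_first=True, dtype=float
    )
    tissue_design, _ = _design_with_intercept(tissue_design)
    mut_design, dropped = _design_with_intercept(mutations.T.loc[shared])
    if dropped:
        logger.info("dropped constant mutation columns: %s", dropped)
    rows = []
    for phen in phenotypes:
        y = scores.loc[shared, phen]
        ok = y.notna()
        if not ok.any():
            logger.info("phenotype %s skipped: all scores missing", phen)
            continue
        yv = y[ok].to_numpy()
        fit_t = fit_linear(yv, tissue_design.loc[ok.index[ok]], phenotype=phen)
        fit_m = fit_linear(yv, mut_design.loc[ok.index[ok]], phenotype=phen)
        r2_t, r2_m = r_squared(fit_t), r_squared(fit_m)
        rows.append(
            {
                "phenotype": phen,
                "r2_tissue": r2_t,
                "r2_mutation": r2_m,
                "winner": "tissue" if r2_t > r2_m else "mutation",
                "n": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def expression_association(
    scores: pd.DataFrame,
    expression: pd.DataFrame,
    genes: Sequence[str] | None = None,
    phenotypes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene simple regression of each phenotype on log2 expression.

    Returns a tidy table (phenotype, gene, slope, p_value, inv_p) where
    ``inv_p`` = 1/p is the plotting-friendly association strength.
    Zero-variance genes are skipped with a log entry.
    """
    genes = [normalize_gene(g) for g in (genes if genes is not None else expression.index)]
    phenotypes = list(phenotypes) if phenotypes is not None else list(scores.columns)
    shared = scores.index.intersection(expression.columns)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared cell lines; need >= 4")
    rows = []
    for gene in genes:
        if gene not in expression.index:
            logger.info("gene %s absent from expression matrix; skipped", gene)
            continue
        x = expression.loc[gene, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.info("gene %s has zero expression variance; skipped", gene)
            continue
        for phen in phenotypes:
            y = scores.loc[shared, phen].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 4 or np.ptp(y[ok]) == 0:
                continue
            res = stats.linregress(x[ok], y[ok])
            rows.append(
                {
                    "phenotype": phen,
                    "gene": gene,
                    "slope": float(res.slope),
                    "p_value": float(res.pvalue),
                    "inv_p": float(1.0 / res.pvalue) if res.pvalue > 0 else float("inf"),
                    "n": int(ok.sum()),
                }
            )
    return pd.DataFrame(rows)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional layer over raw association p-values)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Sliding-scale threshold search
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Best expression cutpoint separating responders from non-responders."""

    gene: str
    phenotype: str
    threshold: float
    direction: str  # "above-sensitive" | "below-sensitive"
    p_value: float
    n_above: int
    n_below: int
    mean_above: float
    mean_below: float
    min_group_size: int
    significant: bool
    p_permutation: float | None = None


def _split_stats(
    x_sorted: np.ndarray,
    ys: np.ndarray,
    min_group_size: int,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-sample t-tests over every admissible split.

    ``x_sorted`` is ascending expression; ``ys`` is a (m, n) block of
    score vectors already arranged in the same order (m >= 1 rows allows
    scoring permutations in one pass).  Returns (thresholds, k, p,
    mean_below, mean_above) with p of shape (m, n_splits).
    """
    n = x_sorted.size
    ks = np.arange(1, n)
    distinct = x_sorted[:-1] < x_sorted[1:]
    ok = (ks >= min_group_size) & ((n - ks) >= min_group_size) & distinct
    ks = ks[ok]
    if ks.size == 0:
        raise ValueError("no admissible split satisfies min_group_size")
    thresholds = (x_sorted[ks - 1] + x_sorted[ks]) / 2.0
    cs = np.cumsum(ys, axis=1)
    cq = np.cumsum(ys**2, axis=1)
    tot, totq = cs[:, -1:], cq[:, -1:]
    s1, q1 = cs[:, ks - 1], cq[:, ks - 1]
    n1 = ks.astype(float)
    n2 = (n - ks).astype(float)
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    ss1 = np.maximum(q1 - n1 * m1**2, 0.0)
    ss2 = np.maximum((totq - q1) - n2 * m2**2, 0.0)
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = (ss1 + ss2) / (n - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df = np.full_like(se, n - 2.0)
        else:
            v1 = ss1 / np.maximum(n1 - 1, 1) / n1
            v2 = ss2 / np.maximum(n2 - 1, 1) / n2
            se = np.sqrt(v1 + v2)
            denom = v1**2 / np.maximum(n1 - 1, 1) + v2**2 / np.maximum(n2 - 1, 1)
            df = np.where(denom > 0, (v1 + v2) ** 2 / np.where(denom > 0, denom, 1), n - 2.0)
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf) * np.sign(diff + (diff == 0)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return thresholds, ks, p, m1, m2


def find_threshold(
    expression: Sequence[float] | pd.Series,
    scores: Sequence[float] | pd.Series,
    min_group_size: int = 3,
    equal_var: bool = True,
    n_permutations: int = 0,
    alpha: float = 0.05,
    gene: str = "",
    phenotype: str = "",
    rng: np.random.Generator | None = None,
) -> ThresholdResult:
    """Sliding-scale search for the expression cutpoint that best
    segregates high- from low-scoring cell lines.

    Every midpoint between consecutive distinct sorted expression values
    is a candidate; splits leaving fewer than ``min_group_size`` lines
    on a side are inadmissible.  Each split is scored by a two-sample
    t-test (pooled-variance Student by default; Welch with
    ``equal_var=False``).  Ties on the minimal p are broken by larger
    between-group mean difference, then by lower threshold, so output
    is deterministic.

    With ``n_permutations`` > 0 a selection-adjusted p-value is added:
    the fraction of score permutations whose own minimal split p is at
    least as small as the observed one.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression and scores must be 1-D and aligned")
    if x.size < 2 * min_group_size:
        raise ValueError("need at least 2 * min_group_size observations")
    if np.unique(x).size < 2:
        raise ValueError("expression must have at least 2 distinct values")
    order = np.argsort(x, kind="stable")
    xs, ysrt = x[order], y[order]
    thresholds, ks, p, m_below, m_above = _split_stats(
        xs, ysrt[None, :], min_group_size, equal_var
    )
    p0, mb, ma = p[0], m_below[0], m_above[0]
    best_p = p0.min()
    tied = np.flatnonzero(p0 == best_p)
    diffs = np.abs(ma[tied] - mb[tied])
    tied = tied[diffs == diffs.max()]
    idx = tied[np.argmin(thresholds[tied])]
    direction = "above-sensitive" if ma[idx] >= mb[idx] else "below-sensitive"
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng() if rng is None else rng
        perms = np.stack([rng.permutation(ysrt) for _ in range(n_permutations)])
        _, _, pp, _, _ = _split_stats(xs, perms, min_group_size, equal_var)
        p_perm = float((1 + np.sum(pp.min(axis=1) <= best_p)) / (n_permutations + 1))
    return ThresholdResult(
        gene=gene,
        phenotype=phenotype,
        threshold=float(thresholds[idx]),
        direction=direction,
        p_value=float(best_p),
        n_above=int(xs.size - ks[idx]),
        n_below=int(ks[idx]),
        mean_above=float(ma[idx]),
        mean_below=float(mb[idx]),
        min_group_size=min_group_size,
        significant=bool(best_p < alpha),
        p_permutation=p_perm,
    )


@dataclass
class ValidationResult:
    threshold: float
    n_below: int
    n_above: int
    mean_below: float
    mean_above: float
    t_statistic: float
    p_value: float


def validate_threshold(
    threshold: ThresholdResult | float,
    external_expression: Sequence[float] | pd.Series,
    external_sensitivity: Sequence[float] | pd.Series,
    equal_var: bool = True,
) -> ValidationResult:
    """Apply a fixed (not re-fit) threshold to an independent cohort.

    The external cohort (e.g. expression plus log2 IC50 from a public
    chemogenomic screen) is split at the given cutpoint and the two
    groups compared with a two-sample t-test.  A one-sided split —
    threshold outside the cohort's expression range or a side with
    fewer than 2 lines — is an error, not a silent NaN.
    """
    cut = threshold.threshold if isinstance(threshold, ThresholdResult) else float(threshold)
    x = np.asarray(external_expression, dtype=float)
    y = np.asarray(external_sensitivity, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression and sensitivity must be aligned")
    below, above = y[x < cut], y[x >= cut]
    if below.size < 2 or above.size < 2:
        raise ValueError(
            f"threshold {cut} yields a degenerate split "
            f"({below.size} below / {above.size} above); need >= 2 per side"
        )
    t, p = stats.ttest_ind(above, below, equal_var=equal_var)
    return ValidationResult(
        threshold=cut,
        n_below=int(below.size),
        n_above=int(above.size),
        mean_below=float(below.mean()),
        mean_above=float(above.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Tissue-average outlier analysis
# ---------------------------------------------------------------------------

def _pct_delta(value: float, mean: float) -> float:
    if mean == 0.0:
        return 0.0 if value == 0.0 else float("nan")
    return 100.0 * (value - mean) / mean


def outlier_analysis(
    scores: pd.DataFrame,
    expression: pd.DataFrame,
    tissue_labels: pd.Series,
    phenotypes: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    association_directions: Mapping[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Percentage difference of each line's dependency scores and driver-gene
    expression against its tissue-of-origin averages.

    Dependency deltas are computed on the score scale; expression deltas
    on the linear (un-logged) scale so "percentage difference" keeps its
    meaning.  When a phenotype has an associated driver gene, the
    ``concordant_<phenotype>`` flag marks lines whose dependency and
    expression deltas deviate in the direction the association table
    predicts.  Lines in singleton tissues are skipped (no average to
    compare against).
    """
    phenotypes = list(phenotypes) if phenotypes is not None else list(scores.columns)
    assoc = dict(
        association_directions
        if association_directions is not None
        else DEFAULT_ASSOCIATION_DIRECTIONS
    )
    if genes is None:
        genes = sorted({g for g, _ in assoc.values() if g in expression.index})
    genes = [normalize_gene(g) for g in genes]
    shared = scores.index.intersection(expression.columns).intersection(
        tissue_labels.index
    )
    lin_expr = 2.0 ** expression.loc[[g for g in genes if g in expression.index], shared]
    tissues = tissue_labels.loc[shared]
    rows = []
    for tissue, members in tissues.groupby(tissues):
        lines = members.index
        if len(lines) < 2:
            logger.info("tissue %s has a single line; skipped", tissue)
            continue
        dep_means = scores.loc[lines, phenotypes].mean()
        expr_means = lin_expr[lines].mean(axis=1)
        for line in lines:
            row: dict[str, object] = {"cell_line": line, "tissue": tissue}
            for phen in phenotypes:
                row[f"dep_delta_{phen}"] = _pct_delta(
                    float(scores.loc[line, phen]), float(dep_means[phen])
                )
            for gene in expr_means.index:
                row[f"expr_delta_{gene}"] = _pct_delta(
                    float(lin_expr.loc[gene, line]), float(expr_means[gene])
                )
            for phen, (gene, sign) in assoc.items():
                if phen in phenotypes and gene in expr_means.index:
                    d = row[f"dep_delta_{phen}"]
                    e = row[f"expr_delta_{gene}"]
                    row[f"concordant_{phen}"] = bool(
                        d == d and e == e and d != 0 and e != 0
                        and np.sign(d) == sign * np.sign(e)
                    )
            rows.append(row)
    return pd.DataFrame(rows)
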