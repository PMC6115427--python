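import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bh3map import (
    build_profiles,
    compare_predictors,
    expression_association,
    find_threshold,
    fit_linear,
    outlier_analysis,
    r_squared,
    score_matrix,
    simulate_screen,
    validate_threshold,
)
from bh3map.simulate import DependencyRule, MutationRule, SimConfig
from conftest import threshold_recovery_config


# ---------------------------------------------------------------------------
# OLS and R^2
# ---------------------------------------------------------------------------

def test_fit_linear_perfect_fit():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    X = np.column_stack([np.ones(4), x])
    fit = fit_linear(2 * x, X, labels=["intercept", "x"])
    assert fit.beta == pytest.approx([0.0, 2.0], abs=1e-10)
    assert fit.residuals == pytest.approx(np.zeros(4), abs=1e-10)


def test_fit_linear_textbook_closed_form():
    """Slope/intercept/p against the closed-form simple-regression oracle."""
    x = np.array([1.0, 2.0, 3.0, 5.0])
    y = np.array([1.0, 2.0, 3.0, 4.0])
    X = np.column_stack([np.ones(4), x])
    fit = fit_linear(y, X, labels=["intercept", "x"])
    # hand-derived OLS: b1 = Sxy/Sxx, b0 = ybar - b1 xbar
    sxx = np.sum((x - x.mean()) ** 2)
    b1 = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    b0 = y.mean() - b1 * x.mean()
    assert fit.beta == pytest.approx([b0, b1])
    resid = y - (b0 + b1 * x)
    s2 = np.sum(resid**2) / 2  # n - p = 2 df
    t = b1 / np.sqrt(s2 / sxx)
    p = 2 * stats.t.sf(abs(t), 2)
    assert fit.pvalues["x"] == pytest.approx(p)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert r_squared(fit) == pytest.approx(1 - np.sum(resid**2) / ss_tot)


def test_fit_linear_intercept_only_degenerate_design():
    rng = np.random.default_rng(0)
    y = rng.normal(size=10)
    fit = fit_linear(y, np.ones((10, 1)), labels=["intercept"])
    assert fit.pvalues == {}
    assert r_squared(fit) == pytest.approx(0.0)


def test_fit_linear_rejects_rank_deficiency():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    X = np.column_stack([np.ones(4), x, 2 * x])
    with pytest.raises(ValueError, match="x2"):
        fit_linear(x, X, labels=["intercept", "x1", "x2"])


def test_fit_linear_requires_intercept():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError, match="intercept"):
        fit_linear(x, x[:, None], labels=["x"])


def test_r_squared_constant_y_defined_zero():
    X = np.column_stack([np.ones(5), np.arange(5.0)])
    fit = fit_linear(np.full(5, 3.0), X)
    with pytest.warns(UserWarning, match="constant"):
        assert r_squared(fit) == 0.0


def test_r_squared_monotone_in_nested_models():
    rng = np.random.default_rng(4)
    n = 40
    cols = [np.ones(n)] + [rng.normal(size=n) for _ in range(4)]
    y = rng.normal(size=n)
    r2 = [
        r_squared(fit_linear(y, np.column_stack(cols[: k + 1])))
        for k in range(1, 5)
    ]
    assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))


# ---------------------------------------------------------------------------
# Predictor comparison
# ---------------------------------------------------------------------------

def _tissue_driven_config(seed):
    return SimConfig(
        dependency_rules=(), emt=None, crispr=None, line_sd=0.05, seed=seed
    )


def _mutation_driven_config(seed):
    flat = {t: {"BCL2": 0.1, "BCLXL": 0.1, "MCL1": 0.1}
            for t in ("LAML", "OV", "COAD", "PAAD", "LUAD",
                      "SKCM", "LIHC", "BLCA", "BRCA", "GBM")}
    return SimConfig(
        base_dependency=flat,
        dependency_rules=(),
        mutation_rules=(
            MutationRule("TP53", "BCLXL", 40.0),
            MutationRule("KRAS", "MCL1", 40.0),
            MutationRule("PIK3CA", "BCL2", 30.0),
        ),
        emt=None,
        crispr=None,
        line_sd=0.05,
        seed=seed,
    )


def _comparison(config):
    bundle = simulate_screen(config)
    scores = score_matrix(build_profiles(bundle.viability_panel))
    return compare_predictors(scores, bundle.tissue_labels, bundle.mutations)


def test_tissue_generated_dependencies_favor_tissue():
    comp = _comparison(_tissue_driven_config(31))
    assert (comp["winner"] == "tissue").all()


def test_mutation_generated_dependencies_favor_mutation():
    comp = _comparison(_mutation_driven_config(32))
    singles = comp.set_index("phenotype").loc[["A199", "W539", "A121"]]
    assert (singles["winner"] == "mutation").all()


def test_compare_predictors_constant_scores_zero_r2():
    bundle = simulate_screen(_tissue_driven_config(33))
    scores = score_matrix(build_profiles(bundle.viability_panel))
    scores.loc[:, :] = 42.0
    with pytest.warns(UserWarning, match="constant"):
        comp = compare_predictors(scores, bundle.tissue_labels, bundle.mutations)
    assert (comp["r2_tissue"] == 0.0).all()
    assert (comp["r2_mutation"] == 0.0).all()


# ---------------------------------------------------------------------------
# Expression association
# ---------------------------------------------------------------------------

def test_planted_driver_is_top_association():
    """High-NOXA-driven BCL-X_L dependence: NOXA wins the association scan."""
    hits = 0
    for seed in range(20):
        cfg = threshold_recovery_config(seed)
        bundle = simulate_screen(cfg)
        scores = score_matrix(build_profiles(bundle.viability_panel))
        assoc = expression_association(scores, bundle.expression, phenotypes=["W539"])
        best = assoc.loc[assoc["p_value"].idxmin(), "gene"]
        hits += best == "PMAIP1"
    assert hits >= 18


def test_anticorrelated_driver_sign_recovered():
    """Low BCL-X_L expression driving MCL-1 dependence gives a negative slope."""
    cfg = SimConfig(
        dependency_rules=(DependencyRule("BCL2L1", "MCL1", "below", 7.3, 40.0),),
        emt=None,
        crispr=None,
        seed=41,
    )
    bundle = simulate_screen(cfg)
    scores = score_matrix(build_profiles(bundle.viability_panel))
    assoc = expression_association(
        scores, bundle.expression, genes=["BCL2L1"], phenotypes=["A121"]
    ).iloc[0]
    assert assoc["slope"] < 0
    assert assoc["p_value"] < 0.01


def test_permuted_expression_null_calibration():
    """With expression decoupled from response, ~5% of genes reach p < 0.05."""
    rng = np.random.default_rng(8)
    frac = []
    for seed in range(10):
        bundle = simulate_screen(_tissue_driven_config(100 + seed))
        scores = score_matrix(build_profiles(bundle.viability_panel))
        perm = bundle.expression.copy()
        perm.loc[:, :] = perm.to_numpy()[:, rng.permutation(perm.shape[1])]
        assoc = expression_association(scores, perm, phenotypes=["W539"])
        frac.append((assoc["p_value"] < 0.05).mean())
    assert 0.0 <= np.mean(frac) < 0.15


def test_zero_variance_gene_skipped(default_bundle):
    scores = score_matrix(build_profiles(default_bundle.viability_panel))
    expr = default_bundle.expression.copy()
    expr.loc["GF001"] = 5.0
    assoc = expression_association(scores, expr, phenotypes=["W539"])
    assert "GF001" not in set(assoc["gene"])


# ---------------------------------------------------------------------------
# Threshold finder
# ---------------------------------------------------------------------------

def brute_force_threshold(x, y, min_group_size=3, equal_var=True):
    """Independent exhaustive enumeration of every admissible split."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xs = np.sort(np.unique(x))
    candidates = []
    for a, b in zip(xs[:-1], xs[1:]):
        thr = (a + b) / 2.0
        below, above = y[x < thr], y[x >= thr]
        if len(below) < min_group_size or len(above) < min_group_size:
            continue
        if np.ptp(below) == 0 and np.ptp(above) == 0:
            p = 1.0 if below.mean() == above.mean() else 0.0
        else:
            _, p = stats.ttest_ind(above, below, equal_var=equal_var)
        candidates.append((p, -abs(above.mean() - below.mean()), thr))
    assert candidates
    return min(candidates)


@pytest.mark.parametrize("equal_var", [True, False])
def test_step_function_threshold(equal_var):
    x = np.arange(1.0, 11.0)
    y = np.where(x <= 5, 0.0, 80.0)
    res = find_threshold(x, y, min_group_size=3, equal_var=equal_var)
    assert res.threshold == pytest.approx(5.5)
    assert res.direction == "above-sensitive"
    _, p_ref = stats.ttest_ind([80.0] * 5, [0.0] * 5, equal_var=equal_var)
    assert res.p_value == pytest.approx(p_ref)
    assert res.n_below == res.n_above == 5


def test_constant_scores_flagged_nonsignificant():
    x = np.arange(1.0, 11.0)
    res = find_threshold(x, np.full(10, 7.0))
    assert res.p_value == 1.0
    assert not res.significant


def test_threshold_matches_brute_force_oracle():
    """Exhaustive-split equivalence, tie-breaking included, for n <= 12."""
    rng = np.random.default_rng(12)
    for n in range(6, 13):
        for trial in range(30):
            x = rng.normal(size=n)
            # mix of continuous and heavily tied score patterns
            y = rng.choice([0.0, 40.0, 80.0], size=n) if trial % 2 else rng.normal(size=n)
            if np.ptp(y) == 0:
                continue
            res = find_threshold(x, y, min_group_size=2)
            p_ref, negdiff_ref, thr_ref = brute_force_threshold(x, y, min_group_size=2)
            assert res.threshold == pytest.approx(thr_ref)
            assert res.p_value == pytest.approx(p_ref, abs=1e-10)


def test_threshold_tie_break_deterministic():
    # two exactly mirrored splits: lower threshold must win
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([0.0, 0.0, 50.0, 50.0, 100.0, 100.0])
    res = find_threshold(x, y, min_group_size=2)
    p_ref, _, thr_ref = brute_force_threshold(x, y, min_group_size=2)
    assert res.threshold == pytest.approx(thr_ref)


def test_threshold_errors():
    with pytest.raises(ValueError, match="distinct"):
        find_threshold(np.ones(10), np.arange(10.0))
    with pytest.raises(ValueError, match="admissible"):
        find_threshold(np.array([1.0, 1, 1, 1, 1, 2]), np.arange(6.0), min_group_size=3)
    with pytest.raises(ValueError):
        find_threshold(np.arange(4.0), np.arange(4.0), min_group_size=3)


def test_planted_threshold_recovery_single_cohort():
    cfg = threshold_recovery_config(77)
    bundle = simulate_screen(cfg)
    scores = score_matrix(build_profiles(bundle.viability_panel))
    expr = bundle.expression.loc["PMAIP1", scores.index]
    res = find_threshold(expr, scores["W539"])
    between = np.sum(
        (expr.to_numpy() > min(res.threshold, 10.0))
        & (expr.to_numpy() < max(res.threshold, 10.0))
    )
    assert between <= 1
    assert res.direction == "above-sensitive"


def test_permutation_adjusted_p_calibrated_under_null():
    """Raw min-p is selection-biased; the permutation p rejects at ~5%."""
    rng = np.random.default_rng(99)
    n_seeds, rejections, raw_small = 500, 0, 0
    for _ in range(n_seeds):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = find_threshold(x, y, min_group_size=3, n_permutations=199, rng=rng)
        rejections += res.p_permutation <= 0.05
        raw_small += res.p_value < 0.05
    assert 0.03 <= rejections / n_seeds <= 0.07
    # the unadjusted minimum p rejects far more often than nominal
    assert raw_small / n_seeds > 0.15


# ---------------------------------------------------------------------------
# Threshold validation on an external cohort
# ---------------------------------------------------------------------------

def test_validate_threshold_recovers_planted_rule():
    rng = np.random.default_rng(3)
    n = 100
    expr = rng.normal(10.0, 1.2, size=n)
    ic50 = np.where(expr > 10.0, -2.0, 1.0) + rng.normal(0, 0.8, size=n)
    res = validate_threshold(10.0, expr, ic50)
    assert res.mean_above < res.mean_below  # high expressers more sensitive
    assert res.p_value < 0.05
    assert res.n_below + res.n_above == n


def test_validate_threshold_null_is_uniform_ish():
    rng = np.random.default_rng(13)
    ps = []
    for _ in range(200):
        expr = rng.normal(10.0, 1.0, size=40)
        ic50 = rng.normal(0, 1, size=40)
        ps.append(validate_threshold(10.0, expr, ic50).p_value)
    assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.12


def test_validate_threshold_degenerate_split_errors():
    rng = np.random.default_rng(1)
    expr = rng.normal(10.0, 1.0, size=20)
    with pytest.raises(ValueError, match="degenerate"):
        validate_threshold(expr.max() + 5.0, expr, np.zeros(20))


# ---------------------------------------------------------------------------
# Tissue-average outliers
# ---------------------------------------------------------------------------

def _outlier_fixture():
    scores = pd.DataFrame(
        {"W539": [10.0, 10.0, 50.0, 0.0, 0.0]},
        index=["A1", "A2", "A3", "B1", "B2"],
    )
    expr = pd.DataFrame(
        {"A1": [10.0], "A2": [10.0], "A3": [12.0], "B1": [8.0], "B2": [8.0]},
        index=["PMAIP1"],
    )
    tissues = pd.Series(
        ["TA", "TA", "TA", "TB", "TB"], index=scores.index, name="tissue"
    )
    return scores, expr, tissues


def test_outlier_deltas_and_concordance():
    scores, expr, tissues = _outlier_fixture()
    rep = outlier_analysis(
        scores, expr, tissues, phenotypes=["W539"],
        association_directions={"W539": ("PMAIP1", +1)},
    ).set_index("cell_line")
    # A3: +50 vs tissue mean 23.33 -> +114.3%; expression +2 log2 -> +300% linear
    assert rep.loc["A3", "dep_delta_W539"] == pytest.approx(100 * (50 - 70 / 3) / (70 / 3))
    assert rep.loc["A3", "expr_delta_PMAIP1"] == pytest.approx(
        100 * (2**12 - (2**10 * 2 + 2**12) / 3) / ((2**10 * 2 + 2**12) / 3)
    )
    assert bool(rep.loc["A3", "concordant_W539"])
    # B lines sit exactly at a zero tissue mean: delta defined 0, not NaN
    assert rep.loc["B1", "dep_delta_W539"] == 0.0


def test_outlier_line_at_tissue_mean_is_zero():
    scores, expr, tissues = _outlier_fixture()
    rep = outlier_analysis(
        scores, expr, tissues, phenotypes=["W539"],
        association_directions={"W539": ("PMAIP1", +1)},
    ).set_index("cell_line")
    assert rep.loc["A1", "expr_delta_PMAIP1"] == pytest.approx(
        100 * (2**10 - (2**10 * 2 + 2**12) / 3) / ((2**10 * 2 + 2**12) / 3)
    )


def test_outlier_singleton_tissue_skipped():
    scores, expr, tissues = _outlier_fixture()
    tissues = tissues.copy()
    tissues["B2"] = "TC"
    rep = outlier_analysis(
        scores, expr, tissues, phenotypes=["W539"],
        association_directions={"W539": ("PMAIP1", +1)},
    )
    assert set(rep["cell_line"]) == {"A1", "A2", "A3"}
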