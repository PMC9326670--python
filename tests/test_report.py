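"""Reporting-layer tests with independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from matrixbank.errors import (
    CollinearityError,
    ConfigurationError,
    UndefinedStatisticError,
)
from matrixbank.report import (
    RULE_COLUMNS,
    correlate_with_trim,
    ctt_stats,
    oneway_anova,
    rule_regression,
)

from conftest import make_matrix


# ------------------------------------------------------------------- CTT

def test_ctt_toy_hand_oracle():
    """3 persons x 2 items [[1,1],[1,0],[0,0]]: p = (2/3, 1/3),
    r_pw = corr((1,1,0),(1,0,0)) = 0.5 for both items, and
    alpha = 2 (1 - (1/3 + 1/3) / 1) = 2/3."""
    matrix = make_matrix([[1, 1], [1, 0], [0, 0]])
    out = ctt_stats(matrix)
    stats = out.item_stats.set_index("item_id")
    assert abs(stats.loc["i0", "p"] - 2 / 3) < 1e-12
    assert abs(stats.loc["i1", "p"] - 1 / 3) < 1e-12
    assert abs(stats.loc["i0", "r_pw"] - 0.5) < 1e-12
    assert abs(stats.loc["i1", "r_pw"] - 0.5) < 1e-12
    assert abs(out.alpha["F1"] - 2 / 3) < 1e-12


def test_ctt_all_correct_item_undefined_pw():
    matrix = make_matrix([[1, 1, 0], [1, 0, 1], [1, 1, 1], [1, 0, 0]])
    out = ctt_stats(matrix)
    stats = out.item_stats.set_index("item_id")
    assert stats.loc["i0", "p"] == 1.0
    assert np.isnan(stats.loc["i0", "r_pw"])


def test_ctt_invariant_to_row_duplication():
    rng = np.random.default_rng(41)
    X = rng.integers(0, 2, size=(20, 5)).astype(float)
    single = ctt_stats(make_matrix(X))
    doubled = ctt_stats(make_matrix(np.vstack([X, X])))
    pd.testing.assert_frame_equal(
        single.item_stats, doubled.item_stats, check_exact=False, atol=1e-12
    )
    assert abs(single.alpha["F1"] - doubled.alpha["F1"]) < 1e-12


def test_ctt_brute_force_oracle():
    """Agreement with first-principles recomputation to 1e-10."""
    rng = np.random.default_rng(42)
    X = rng.integers(0, 2, size=(40, 6)).astype(float)
    out = ctt_stats(make_matrix(X))
    stats = out.item_stats.set_index("item_id")
    k = X.shape[1]
    total = X.sum(axis=1)
    for j in range(k):
        assert abs(stats.loc[f"i{j}", "p"] - X[:, j].mean()) < 1e-10
        rest = total - X[:, j]
        xm, rm = X[:, j].mean(), rest.mean()
        num = ((X[:, j] - xm) * (rest - rm)).sum()
        den = np.sqrt(((X[:, j] - xm) ** 2).sum() * ((rest - rm) ** 2).sum())
        assert abs(stats.loc[f"i{j}", "r_pw"] - num / den) < 1e-10
    item_vars = X.var(axis=0, ddof=1)
    alpha = k / (k - 1) * (1 - item_vars.sum() / total.var(ddof=1))
    assert abs(out.alpha["F1"] - alpha) < 1e-10


def test_ctt_multiple_forms_with_design_missingness():
    X = np.full((6, 4), np.nan)
    X[:3, :2] = [[1, 0], [1, 1], [0, 0]]
    X[3:, 2:] = [[1, 1], [0, 1], [1, 0]]
    matrix = make_matrix(X, form_ids=["F1"] * 3 + ["F2"] * 3)
    out = ctt_stats(matrix)
    assert set(out.alpha.index) == {"F1", "F2"}
    assert len(out.item_stats) == 4


def test_ctt_too_small_rejected():
    with pytest.raises(ConfigurationError):
        ctt_stats(make_matrix([[1, 0], [0, 1]]))


# ----------------------------------------------------------------- ANOVA

def test_anova_identical_groups():
    result = oneway_anova([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
    assert result.F == 0.0
    assert result.omega_sq == 0.0


def test_anova_hand_oracle():
    """Groups {0,1} and {2,3}: SSB = 4, SSW = 1, MSW = 0.5, F = 8."""
    result = oneway_anova([[0.0, 1.0], [2.0, 3.0]])
    assert abs(result.F - 8.0) < 1e-12
    assert result.df_between == 1
    assert result.df_within == 2
    # omega^2 = (4 - 1*0.5) / (5 + 0.5) = 0.636363...
    assert abs(result.omega_sq - 3.5 / 5.5) < 1e-12


def test_anova_against_scipy_oracle():
    rng = np.random.default_rng(43)
    groups = [rng.normal(m, 1, 12) for m in (0.0, 0.4, -0.3)]
    result = oneway_anova(groups)
    F, p = sps.f_oneway(*groups)
    assert abs(result.F - F) < 1e-10
    assert abs(result.p - p) < 1e-12


def test_omega_sq_bounded_by_eta_sq():
    rng = np.random.default_rng(44)
    for _ in range(20):
        groups = [rng.normal(rng.normal(), 1, 8) for _ in range(4)]
        result = oneway_anova(groups)
        values = np.concatenate(groups)
        grand = values.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        sst = ((values - grand) ** 2).sum()
        assert result.omega_sq <= ssb / sst + 1e-12
        assert 0.0 <= result.omega_sq <= 1.0


def test_anova_small_group_rejected():
    with pytest.raises(ConfigurationError):
        oneway_anova([[1.0], [2.0, 3.0]])


# ---------------------------------------------------------- trimmed corr

def test_trim_noop_without_outliers():
    rng = np.random.default_rng(45)
    x = rng.normal(0, 1, 50)
    y = 0.5 * x + rng.normal(0, 0.5, 50)
    out = correlate_with_trim(x, y)
    assert out.n_removed == 0
    assert out.r_trimmed == out.r_raw


def test_trim_removes_leverage_point():
    rng = np.random.default_rng(46)
    x = rng.normal(0, 1, 60)
    y = -0.8 * x + rng.normal(0, 0.3, 60)
    x = np.append(x, 30.0)  # ~10 SD leverage point breaking the trend
    y = np.append(y, 30.0)
    out = correlate_with_trim(x, y)
    assert out.n_removed == 1
    assert abs(out.r_trimmed) > abs(out.r_raw)
    assert out.r_trimmed < 0 < out.r_raw + 1  # direction restored


def test_trim_perfect_linear():
    x = np.arange(10.0)
    out = correlate_with_trim(x, 2 * x + 1)
    assert abs(out.r_raw - 1.0) < 1e-12


def test_trim_constant_vector_rejected():
    with pytest.raises(UndefinedStatisticError):
        correlate_with_trim(np.ones(10), np.arange(10.0))


def test_trim_oracle_recomputation():
    rng = np.random.default_rng(47)
    x = rng.normal(0, 1, 80)
    y = x + rng.normal(0, 1, 80)
    x[0], y[3] = 9.0, -8.0
    out = correlate_with_trim(x, y)
    keep = (np.abs(x - x.mean()) <= 3 * x.std(ddof=1)) & (
        np.abs(y - y.mean()) <= 3 * y.std(ddof=1)
    )
    r_oracle = np.corrcoef(x[keep], y[keep])[0, 1]
    assert abs(out.r_trimmed - r_oracle) < 1e-10
    assert out.n_removed == int((~keep).sum())


# ------------------------------------------------------------ regression

WEIGHTS = {
    "ADD": 0.41,
    "SUB": 0.51,
    "DIS": 0.77,
    "INT": 0.68,
    "ROT": 0.34,
    "COM": 0.12,
}
INTERCEPT = -1.56


def _random_indicator_table(rng, n=220, weights=WEIGHTS, noise_sd=0.0):
    rows = []
    for i in range(n):
        k = int(rng.integers(1, 6))
        kinds = rng.permutation(RULE_COLUMNS)[:k]
        row = {c: int(c in kinds) for c in RULE_COLUMNS}
        row["rule_count"] = k
        row["b"] = INTERCEPT + sum(weights[c] for c in kinds)
        if noise_sd:
            row["b"] += rng.normal(0, noise_sd)
        rows.append(row)
    return pd.DataFrame(rows)


def test_noiseless_regression_recovers_generating_weights():
    rng = np.random.default_rng(48)
    table = _random_indicator_table(rng)
    result = rule_regression(table)
    assert abs(result.intercept - INTERCEPT) < 1e-10
    for rule, w in WEIGHTS.items():
        assert abs(result.coef.loc[rule, "B"] - w) < 1e-10
    assert result.r_squared > 1 - 1e-12


def test_regression_against_statsmodels_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(49)
    table = _random_indicator_table(rng, noise_sd=0.3)
    result = rule_regression(table)
    X = sm.add_constant(table[RULE_COLUMNS].to_numpy())
    fit = sm.OLS(table["b"].to_numpy(), X).fit()
    assert abs(result.intercept - fit.params[0]) < 1e-10
    for j, rule in enumerate(RULE_COLUMNS):
        assert abs(result.coef.loc[rule, "B"] - fit.params[j + 1]) < 1e-10
        assert abs(result.coef.loc[rule, "t"] - fit.tvalues[j + 1]) < 1e-8
        assert abs(result.coef.loc[rule, "p"] - fit.pvalues[j + 1]) < 1e-10
    assert abs(result.r_squared - fit.rsquared) < 1e-10
    assert abs(result.f_model - fit.fvalue) < 1e-8
    # incremental F against the nested rule-count model
    X0 = sm.add_constant(table["rule_count"].to_numpy(dtype=float))
    fit0 = sm.OLS(table["b"].to_numpy(), X0).fit()
    f_inc = ((fit0.ssr - fit.ssr) / 5) / (fit.ssr / fit.df_resid)
    assert abs(result.f_increment - f_inc) < 1e-8


def test_standardized_weights_definition():
    rng = np.random.default_rng(50)
    table = _random_indicator_table(rng, noise_sd=0.3)
    result = rule_regression(table)
    sy = table["b"].std(ddof=1)
    for rule in RULE_COLUMNS:
        beta = result.coef.loc[rule, "B"] * table[rule].std(ddof=1) / sy
        assert abs(result.coef.loc[rule, "beta"] - beta) < 1e-12


def test_identical_indicators_collinear():
    table = pd.DataFrame(
        [
            {**{c: 1 for c in RULE_COLUMNS[:3]}, **{c: 0 for c in RULE_COLUMNS[3:]},
             "rule_count": 3, "b": 0.1 * i}
            for i in range(12)
        ]
    )
    with pytest.raises(CollinearityError):
        rule_regression(table)


def test_null_increment_mostly_nonsignificant():
    """With equal per-rule weights the six indicators add nothing beyond
    the rule count."""
    equal = {c: 0.5 for c in RULE_COLUMNS}
    nonsig = 0
    for seed in range(20):
        rng = np.random.default_rng(600 + seed)
        table = _random_indicator_table(rng, weights=equal, noise_sd=0.3)
        result = rule_regression(table)
        nonsig += result.p_increment >= 0.05
    assert nonsig >= 18


def test_too_few_items_rejected():
    rng = np.random.default_rng(51)
    with pytest.raises(ConfigurationError):
        rule_regression(_random_indicator_table(rng, n=5))
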