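"""Classical test theory statistics, ANOVA with omega-squared, trimmed
correlations, and the rule-based difficulty regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CollinearityError,
    ConfigurationError,
    UndefinedStatisticError,
)
from .rules import RULE_KINDS
from .simulate import ResponseMatrix


@dataclass
class CTTStats:
    """Per-item difficulty/part-whole table and per-set alpha.

    ``item_stats`` columns: form_id, item_id, p, r_pw (NaN marks an
    undefined part-whole correlation, e.g. a zero-variance item).
    """

    item_stats: pd.DataFrame
    alpha: pd.Series


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    omega_sq: float


@dataclass(frozen=True)
class TrimmedCorrelation:
    r_raw: float
    r_trimmed: float
    n_removed: int


@dataclass
class RegressionResult:
    intercept: float
    coef: pd.DataFrame  # index rule kind; columns B, beta, t, p
    r_squared: float
    f_model: float
    p_model: float
    df_model: tuple[int, int]
    f_increment: float
    p_increment: float
    df_increment: tuple[int, int]


def ctt_stats(matrix: ResponseMatrix) -> CTTStats:
    """Item difficulty, corrected item-total (part-whole) correlation, and
    Cronbach's alpha, computed per form on the administered columns."""
    rows = []
    alphas = {}
    for form_id, frame in matrix.data.groupby(matrix.form_assignment):
        frame = frame.dropna(axis=1, how="all")
        if frame.shape[1] < 2 or frame.shape[0] < 3:
            raise ConfigurationError(
                f"form {form_id} needs >= 2 items and >= 3 persons for CTT"
            )
        X = frame.to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ConfigurationError(
                f"form {form_id} has within-form missingness; CTT expects "
                "complete administered columns"
            )
        total = X.sum(axis=1)
        p = X.mean(axis=0)
        item_var = X.var(axis=0, ddof=1)
        k = X.shape[1]
        total_var = total.var(ddof=1)
        alphas[form_id] = (
            float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
            if total_var > 0
            else float("nan")
        )
        for j, iid in enumerate(frame.columns):
            rest = total - X[:, j]
            if item_var[j] == 0 or rest.var(ddof=1) == 0:
                r_pw = float("nan")  # undefined, reported not dropped
            else:
                r_pw = float(np.corrcoef(X[:, j], rest)[0, 1])
            rows.append(
                {"form_id": form_id, "item_id": iid, "p": float(p[j]), "r_pw": r_pw}
            )
    return CTTStats(
        item_stats=pd.DataFrame(rows),
        alpha=pd.Series(alphas, name="alpha"),
    )


def oneway_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA with the omega-squared effect size
    (truncated below at zero)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ConfigurationError("ANOVA needs at least 2 groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ConfigurationError(f"ANOVA group {i} has fewer than 2 values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    ss_total = ss_between + ss_within
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    ms_within = ss_within / df_within
    if ms_within == 0:
        F = 0.0 if ss_between == 0 else float("inf")
    else:
        F = float((ss_between / df_between) / ms_within)
    p = float(sps.f.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
    denom = ss_total + ms_within
    omega = (ss_between - df_between * ms_within) / denom if denom > 0 else 0.0
    return AnovaResult(
        F=F,
        df_between=df_between,
        df_within=df_within,
        p=p,
        omega_sq=float(max(omega, 0.0)),
    )


def correlate_with_trim(x, y, sd_multiplier: float = 3.0) -> TrimmedCorrelation:
    """Pearson correlation before and after one-pass marginal outlier
    removal (pairs with either coordinate beyond ``sd_multiplier`` SDs of
    its own raw mean are dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ConfigurationError("need at least 3 pairs")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    r_raw = float(np.corrcoef(x, y)[0, 1])
    keep = (np.abs(x - x.mean()) <= sd_multiplier * x.std(ddof=1)) & (
        np.abs(y - y.mean()) <= sd_multiplier * y.std(ddof=1)
    )
    n_removed = int((~keep).sum())
    if keep.sum() < 3:
        raise UndefinedStatisticError("trimming removed too many pairs")
    xt, yt = x[keep], y[keep]
    if xt.std(ddof=1) == 0 or yt.std(ddof=1) == 0:
        raise UndefinedStatisticError("trimmed vector is constant")
    r_trimmed = float(np.corrcoef(xt, yt)[0, 1])
    return TrimmedCorrelation(r_raw=r_raw, r_trimmed=r_trimmed, n_removed=n_removed)


RULE_COLUMNS = [r.value for r in RULE_KINDS]


def rule_regression(item_table: pd.DataFrame) -> RegressionResult:
    """OLS of item threshold on the six 0/1 rule indicators.

    ``item_table`` needs a ``b`` column and one 0/1 column per rule kind
    (ADD..COM).  The incremental F compares the six-indicator model with
    the nested rule-count-only model (rule count = row sum of indicators).
    """
    missing = [c for c in RULE_COLUMNS + ["b"] if c not in item_table.columns]
    if missing:
        raise ConfigurationError(f"item table is missing columns {missing}")
    n = len(item_table)
    if n < 8:
        raise ConfigurationError(f"need >= 8 items for the rule regression, got {n}")
    y = item_table["b"].to_numpy(dtype=float)
    X = item_table[RULE_COLUMNS].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns: those whose removal restores full rank
        bad = []
        for j, name in enumerate(RULE_COLUMNS):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(name)
        raise CollinearityError(
            f"rank-deficient design matrix (rank {rank} of {design.shape[1]})",
            columns=bad,
        )

    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    df_resid = n - design.shape[1]
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    sigma2 = rss / df_resid if df_resid > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)
    sy = y.std(ddof=1)
    betas = [
        coef[j + 1] * X[:, j].std(ddof=1) / sy if sy > 0 else float("nan")
        for j in range(len(RULE_COLUMNS))
    ]

    k_full = len(RULE_COLUMNS)
    if rss == 0:
        f_model = float("inf")
        p_model = 0.0
    else:
        f_model = float(((tss - rss) / k_full) / (rss / df_resid))
        p_model = float(sps.f.sf(f_model, k_full, df_resid))

    # nested baseline: intercept + rule count (sum of the six indicators)
    count = X.sum(axis=1)
    base = np.column_stack([np.ones(n), count])
    coef0, _, _, _ = np.linalg.lstsq(base, y, rcond=None)
    rss0 = float(((y - base @ coef0) ** 2).sum())
    df_inc = k_full - 1
    if rss == 0:
        f_inc = float("inf") if rss0 > 0 else 0.0
        p_inc = 0.0 if rss0 > 0 else 1.0
    else:
        f_inc = float(max((rss0 - rss) / df_inc, 0.0) / (rss / df_resid))
        p_inc = float(sps.f.sf(f_inc, df_inc, df_resid))

    table = pd.DataFrame(
        {
            "B": coef[1:],
            "beta": betas,
            "t": tvals[1:],
            "p": pvals[1:],
        },
        index=pd.Index(RULE_COLUMNS, name="rule"),
    )
    return RegressionResult(
        intercept=float(coef[0]),
        coef=table,
        r_squared=float(r2),
        f_model=f_model,
        p_model=p_model,
        df_model=(k_full, df_resid),
        f_increment=f_inc,
        p_increment=p_inc,
        df_increment=(df_inc, df_resid),
    )


def item_rule_table(items, params_by_id: dict) -> pd.DataFrame:
    """Build the regression input: per-item threshold plus 0/1 rule
    indicators and the rule count."""
    rows = []
    for item in items:
        if item.item_id not in params_by_id:
            continue
        kinds = {r.rule_kind.value for r in item.rules}
        row = {"item_id": item.item_id, "b": params_by_id[item.item_id].b}
        for kind in RULE_COLUMNS:
            row[kind] = int(kind in kinds)
        row["rule_count"] = item.rule_count
        rows.append(row)
    return pd.DataFrame(rows).set_index("item_id")
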