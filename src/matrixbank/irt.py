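"""Two-parameter logistic estimation and fit diagnostics.

Estimation is marginal maximum likelihood via EM: a Normal(0, 1) latent
prior discretised on 61 equally spaced nodes over [-6, 6], posterior
weights per person in the E-step, and per-item Newton-Raphson on the
expected complete-data logistic likelihood in the M-step.  A
common-slope (Rasch-type) variant shares one slope across items, which is
the parameterisation under which information-weighted (infit) and
unweighted (outfit) mean squares of standardised residuals are screened.

Misfit flagging follows the cutoff rule: a mean square below 0.75 or
above 1.33 combined with a significant standardised statistic
(Wilson-Hilferty cube-root transform, |z| >= 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateItemError, UsageError
from .simulate import ResponseMatrix

N_NODES = 61
NODE_RANGE = (-6.0, 6.0)
MAX_CYCLES = 500
TOL = 1e-5
SLOPE_FLOOR = 1e-3
MSQ_LOW = 0.75
MSQ_HIGH = 1.33
Z_CRIT = 1.96


@dataclass(frozen=True)
class ItemParams2PL:
    item_id: str
    a: float
    b: float
    se_a: float | None = None
    se_b: float | None = None

    def __post_init__(self):
        if self.a <= 0:
            raise ConfigurationError(f"discrimination must be positive, got {self.a}")
        if not np.isfinite(self.b):
            raise ConfigurationError(f"threshold must be finite, got {self.b}")


@dataclass(frozen=True)
class AbilityEstimate:
    person_id: str
    theta_eap: float
    posterior_sd: float


@dataclass(frozen=True)
class FitStatistics:
    item_id: str
    infit_msq: float
    outfit_msq: float
    infit_z: float
    outfit_z: float
    flagged: bool


@dataclass
class Fit2PLResult:
    params: list[ItemParams2PL]
    log_likelihood: float
    n_cycles: int
    converged: bool
    loglik_history: list[float] = field(default_factory=list)
    excluded_items: list[str] = field(default_factory=list)
    common_slope: bool = False

    def params_by_id(self) -> dict[str, ItemParams2PL]:
        return {p.item_id: p for p in self.params}


@dataclass
class AbilityResult:
    estimates: list[AbilityEstimate]
    excluded_persons: list[str] = field(default_factory=list)

    def by_id(self) -> dict[str, AbilityEstimate]:
        return {e.person_id: e for e in self.estimates}


def two_pl_probability(a, b, theta):
    """2PL response function 1 / (1 + exp(-a (theta - b))); vectorised."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise UsageError("discrimination a must be positive")
    z = a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float))
    return _sigmoid(z)


def probability_correct(params: ItemParams2PL, theta):
    """Response-function wrapper taking an :class:`ItemParams2PL`."""
    return two_pl_probability(params.a, params.b, theta)


def _sigmoid(z):
    out = np.empty_like(z, dtype=float) if isinstance(z, np.ndarray) else None
    z = np.asarray(z, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    return out if out.shape else float(out)


def quadrature_nodes(n_nodes: int = N_NODES, bounds=NODE_RANGE):
    """Equally spaced nodes with standard-normal density weights (normalised)."""
    nodes = np.linspace(bounds[0], bounds[1], n_nodes)
    w = np.exp(-0.5 * nodes**2)
    return nodes, w / w.sum()


def _matrix_arrays(matrix: ResponseMatrix):
    X = matrix.data.to_numpy(dtype=float)
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    return X0, M


def _posteriors(X0, M, a, b, nodes, weights):
    """Posterior node weights per person and the marginal log-likelihood."""
    z = a[:, None] * (nodes[None, :] - b[:, None])  # items x nodes
    P = _sigmoid(z)
    P = np.clip(P, 1e-10, 1 - 1e-10)
    logP, log1mP = np.log(P), np.log1p(-P)
    ll = (X0 * M) @ logP + ((1.0 - X0) * M) @ log1mP  # persons x nodes
    ll = ll + np.log(weights)[None, :]
    mx = ll.max(axis=1, keepdims=True)
    un = np.exp(ll - mx)
    denom = un.sum(axis=1, keepdims=True)
    post = un / denom
    loglik = float((np.log(denom) + mx).sum())
    return post, P, loglik


def _newton_item(r, n, nodes, alpha, c, n_iter=10):
    """Maximise sum_q r log P + (n - r) log(1-P), P = sigmoid(alpha*node + c)."""
    for _ in range(n_iter):
        P = _sigmoid(alpha * nodes + c)
        W = n * P * (1.0 - P)
        g = np.array([((r - n * P) * nodes).sum(), (r - n * P).sum()])
        H = np.array(
            [
                [(W * nodes**2).sum(), (W * nodes).sum()],
                [(W * nodes).sum(), W.sum()],
            ]
        )
        H[0, 0] += 1e-10
        H[1, 1] += 1e-10
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -2.0, 2.0)
        alpha += step[0]
        c += step[1]
        if np.abs(step).max() < 1e-10:
            break
    return max(alpha, SLOPE_FLOOR), c


def fit_2pl(
    matrix: ResponseMatrix,
    common_slope: bool = False,
    max_cycles: int = MAX_CYCLES,
    tol: float = TOL,
    drop_degenerate: bool = False,
) -> Fit2PLResult:
    """Calibrate items by MML-EM under a Normal(0, 1) latent prior.

    All-correct or all-wrong items have no maximum-likelihood estimate;
    they raise :class:`DegenerateItemError` unless ``drop_degenerate``,
    in which case they are excluded and reported in the result.
    Convergence status is always surfaced in the result, never silent.
    """
    item_ids = matrix.item_ids
    X0, M = _matrix_arrays(matrix)
    if M.sum() == 0:
        raise ConfigurationError("empty response matrix")

    observed = M.sum(axis=0)
    correct = (X0 * M).sum(axis=0)
    degenerate = (observed == 0) | (correct == 0) | (correct == observed)
    excluded = [iid for iid, d in zip(item_ids, degenerate) if d]
    if excluded and not drop_degenerate:
        raise DegenerateItemError(
            f"items with all-correct or all-wrong responses: {excluded}"
        )
    keep = ~degenerate
    item_ids = [iid for iid, k in zip(item_ids, keep) if k]
    X0, M = X0[:, keep], M[:, keep]
    if X0.shape[1] == 0:
        raise ConfigurationError("no estimable items remain")

    nodes, weights = quadrature_nodes()
    n_items = X0.shape[1]
    p_obs = (X0 * M).sum(axis=0) / M.sum(axis=0)
    b = -np.log(p_obs / (1.0 - p_obs))
    a = np.ones(n_items)

    history: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        post, _, loglik = _posteriors(X0, M, a, b, nodes, weights)
        history.append(loglik)
        nbar = M.T @ post  # items x nodes
        rbar = (X0 * M).T @ post

        alpha = a.copy()
        c = -a * b
        if common_slope:
            # alternate: per-item intercepts given shared slope, then slope
            for _ in range(5):
                a0 = float(alpha[0])
                for j in range(n_items):
                    P = _sigmoid(a0 * nodes + c[j])
                    g = (rbar[j] - nbar[j] * P).sum()
                    h = (nbar[j] * P * (1 - P)).sum() + 1e-10
                    c[j] += np.clip(g / h, -2.0, 2.0)
                num, den = 0.0, 0.0
                for j in range(n_items):
                    P = _sigmoid(a0 * nodes + c[j])
                    num += ((rbar[j] - nbar[j] * P) * nodes).sum()
                    den += (nbar[j] * P * (1 - P) * nodes**2).sum()
                a0 = max(a0 + np.clip(num / (den + 1e-10), -2.0, 2.0), SLOPE_FLOOR)
                alpha[:] = a0
        else:
            for j in range(n_items):
                alpha[j], c[j] = _newton_item(rbar[j], nbar[j], nodes, alpha[j], c[j])

        new_a = np.maximum(alpha, SLOPE_FLOOR)
        new_b = -c / new_a
        delta = max(np.abs(new_a - a).max(), np.abs(new_b - b).max())
        a, b = new_a, new_b
        if delta < tol:
            converged = True
            break

    _, _, loglik = _posteriors(X0, M, a, b, nodes, weights)

    # expected-information standard errors on (a, c), delta method to (a, b)
    post, _, _ = _posteriors(X0, M, a, b, nodes, weights)
    nbar = M.T @ post
    params: list[ItemParams2PL] = []
    for j, iid in enumerate(item_ids):
        P = _sigmoid(a[j] * (nodes - b[j]))
        W = nbar[j] * P * (1 - P)
        info = np.array(
            [
                [(W * nodes**2).sum(), (W * nodes).sum()],
                [(W * nodes).sum(), W.sum()],
            ]
        )
        se_a = se_b = None
        try:
            cov = np.linalg.inv(info)
            cj = -a[j] * b[j]
            jac = np.array([[1.0, 0.0], [cj / a[j] ** 2, -1.0 / a[j]]])
            cov_ab = jac @ cov @ jac.T
            if cov_ab[0, 0] > 0 and cov_ab[1, 1] > 0:
                se_a = float(np.sqrt(cov_ab[0, 0]))
                se_b = float(np.sqrt(cov_ab[1, 1]))
        except np.linalg.LinAlgError:
            pass
        params.append(ItemParams2PL(iid, float(a[j]), float(b[j]), se_a, se_b))

    return Fit2PLResult(
        params=params,
        log_likelihood=loglik,
        n_cycles=cycle,
        converged=converged,
        loglik_history=history,
        excluded_items=excluded,
        common_slope=common_slope,
    )


def estimate_abilities(
    params: list[ItemParams2PL] | dict[str, ItemParams2PL],
    matrix: ResponseMatrix,
) -> AbilityResult:
    """EAP ability estimates under the Normal(0, 1) prior.

    Persons without a single observed response among calibrated items are
    excluded and reported (not silently dropped).
    """
    by_id = params if isinstance(params, dict) else {p.item_id: p for p in params}
    common = [iid for iid in matrix.item_ids if iid in by_id]
    observed_items = matrix.data.notna().any(axis=0)
    missing = [
        iid for iid in matrix.item_ids if observed_items[iid] and iid not in by_id
    ]
    if missing:
        raise ConfigurationError(f"no calibrated parameters for observed items {missing}")
    sub = matrix.data[common]
    X = sub.to_numpy(dtype=float)
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    a = np.array([by_id[i].a for i in common])
    b = np.array([by_id[i].b for i in common])
    nodes, weights = quadrature_nodes()
    post, _, _ = _posteriors(X0, M, a, b, nodes, weights)
    eap = post @ nodes
    var = post @ nodes**2 - eap**2
    sd = np.sqrt(np.maximum(var, 1e-12))

    estimates, excluded = [], []
    n_obs = M.sum(axis=1)
    for i, pid in enumerate(matrix.person_ids):
        if n_obs[i] == 0:
            excluded.append(pid)
        else:
            estimates.append(AbilityEstimate(pid, float(eap[i]), float(sd[i])))
    return AbilityResult(estimates=estimates, excluded_persons=excluded)


def standardize_msq(msq: float, q: float) -> float:
    """Wilson-Hilferty cube-root standardisation of a mean square."""
    if q <= 0:
        return 0.0
    return float((np.cbrt(msq) - 1.0) * (3.0 / q) + q / 3.0)


def misfit_flag(infit_msq, outfit_msq, infit_z, outfit_z) -> bool:
    """Cutoff rule: mean square outside [0.75, 1.33] with a significant
    standardised statistic for the same mean square."""
    infit_out = (infit_msq < MSQ_LOW or infit_msq > MSQ_HIGH) and abs(infit_z) >= Z_CRIT
    outfit_out = (
        outfit_msq < MSQ_LOW or outfit_msq > MSQ_HIGH
    ) and abs(outfit_z) >= Z_CRIT
    return bool(infit_out or outfit_out)


def fit_statistics(
    params: list[ItemParams2PL] | dict[str, ItemParams2PL],
    abilities: AbilityResult | list[AbilityEstimate],
    matrix: ResponseMatrix,
) -> list[FitStatistics]:
    """Infit/outfit mean squares with Wilson-Hilferty z statistics.

    Residuals condition on EAP point abilities: z = (x - P) / sqrt(P(1-P))
    with P evaluated at theta_eap under the supplied parameters.  Items
    with zero observed variance are reported as degenerate (NaN msq,
    never flagged).
    """
    by_id = params if isinstance(params, dict) else {p.item_id: p for p in params}
    if isinstance(abilities, AbilityResult):
        abilities = abilities.estimates
    theta = {e.person_id: e.theta_eap for e in abilities}
    persons = [pid for pid in matrix.person_ids if pid in theta]
    if not persons:
        raise ConfigurationError("no persons with ability estimates")
    sub = matrix.data.loc[persons]
    th = np.array([theta[p] for p in persons])

    out: list[FitStatistics] = []
    for iid in matrix.item_ids:
        if iid not in by_id:
            continue
        x = sub[iid].to_numpy(dtype=float)
        obs = np.isfinite(x)
        if obs.sum() == 0:
            continue
        x = x[obs]
        if x.min() == x.max():  # zero observed variance
            out.append(FitStatistics(iid, float("nan"), float("nan"), 0.0, 0.0, False))
            continue
        p = two_pl_probability(by_id[iid].a, by_id[iid].b, th[obs])
        p = np.clip(p, 1e-10, 1 - 1e-10)
        w = p * (1.0 - p)
        resid2 = (x - p) ** 2
        n = len(x)
        outfit = float((resid2 / w).mean())
        infit = float(resid2.sum() / w.sum())
        kurt = w * (1.0 - 3.0 * w)  # E (x-P)^4 for a Bernoulli cell
        q2_out = max((kurt / w**2).sum() / n**2 - 1.0 / n, 0.0)
        q2_in = max((kurt - w**2).sum() / w.sum() ** 2, 0.0)
        outfit_z = standardize_msq(outfit, float(np.sqrt(q2_out)))
        infit_z = standardize_msq(infit, float(np.sqrt(q2_in)))
        out.append(
            FitStatistics(
                iid,
                infit,
                outfit,
                infit_z,
                outfit_z,
                misfit_flag(infit, outfit, infit_z, outfit_z),
            )
        )
    return out


def _loo_fit_statistics(X0, M, item_ids, a, b, calib_mask):
    """Infit/outfit from leave-one-out posterior-integrated residuals.

    For each item the person posterior is built from the calibration items
    excluding the item itself, which removes the self-fit deflation of the
    mean squares (point-EAP residuals are biased well below one because
    each response also shaped the ability it is compared against).
    ``calib_mask`` marks the items contributing to the posterior.
    """
    nodes, weights = quadrature_nodes()
    z = a[:, None] * (nodes[None, :] - b[:, None])
    P = np.clip(_sigmoid(z), 1e-10, 1 - 1e-10)
    logP, log1mP = np.log(P), np.log1p(-P)
    Xc = (X0 * M)[:, calib_mask]
    Mc = M[:, calib_mask]
    ll_full = (
        Xc @ logP[calib_mask]
        + ((1.0 - X0[:, calib_mask]) * Mc) @ log1mP[calib_mask]
        + np.log(weights)[None, :]
    )

    out: list[FitStatistics] = []
    for j, iid in enumerate(item_ids):
        obs = M[:, j]
        if obs.sum() == 0:
            continue
        x = X0[obs, j]
        if x.min() == x.max():
            out.append(FitStatistics(iid, float("nan"), float("nan"), 0.0, 0.0, False))
            continue
        llj = ll_full[obs]
        if calib_mask[j]:  # remove the item's own contribution
            llj = llj - (
                x[:, None] * logP[j][None, :]
                + (1.0 - x)[:, None] * log1mP[j][None, :]
            )
        mx = llj.max(axis=1, keepdims=True)
        post = np.exp(llj - mx)
        post /= post.sum(axis=1, keepdims=True)
        ep = post @ P[j]
        # residual about the posterior-mean probability over its Bernoulli
        # variance; unlike the fully integrated form this is unbiased (the
        # posterior-variance term inflates numerator and deflates
        # denominator in the same direction)
        num = (x - ep) ** 2
        den = np.clip(ep * (1.0 - ep), 1e-10, None)
        n = len(x)
        outfit = float((num / den).mean())
        infit = float(num.sum() / den.sum())
        kurt = den * (1.0 - 3.0 * den)
        q2_out = max((kurt / den**2).sum() / n**2 - 1.0 / n, 0.0)
        q2_in = max((kurt - den**2).sum() / den.sum() ** 2, 0.0)
        outfit_z = standardize_msq(outfit, float(np.sqrt(q2_out)))
        infit_z = standardize_msq(infit, float(np.sqrt(q2_in)))
        out.append(
            FitStatistics(
                iid,
                infit,
                outfit,
                infit_z,
                outfit_z,
                misfit_flag(infit, outfit, infit_z, outfit_z),
            )
        )
    return out


def misfit_screen(matrix: ResponseMatrix, max_cycles: int = MAX_CYCLES):
    """Two-pass misfit screening.

    Pass one calibrates a common-slope (Rasch-type) model on all items and
    computes leave-one-out infit/outfit; pass two recalibrates on the items
    that survived pass one and recomputes the statistics for every item
    against the purified calibration (locations of flagged items are
    re-estimated under the purified slope, their columns stay out of the
    posterior).  The common slope matters: a freely estimated per-item
    slope lets a degenerate near-zero estimate mask any misfit, because its
    predicted probabilities collapse to the observed proportion and both
    mean squares are forced to one.

    Returns ``(stats, fit)``; ``stats`` covers every estimable item, and
    ``fit`` is the calibration of the final pass.
    """
    item_ids = matrix.item_ids
    X0, M = _matrix_arrays(matrix)
    observed = M.sum(axis=0)
    correct = (X0 * M).sum(axis=0)
    degenerate = (observed == 0) | (correct == 0) | (correct == observed)
    est_ids = [iid for iid, d in zip(item_ids, degenerate) if not d]
    X0, M = X0[:, ~degenerate], M[:, ~degenerate]

    def _pass(exclude: set[str]):
        calib_mask = np.array([iid not in exclude for iid in est_ids])
        sub = ResponseMatrix(
            matrix.data[[i for i, k in zip(est_ids, calib_mask) if k]],
            matrix.form_assignment,
        )
        fit = fit_2pl(sub, common_slope=True, drop_degenerate=True, max_cycles=max_cycles)
        by_id = fit.params_by_id()
        slope = fit.params[0].a
        a = np.full(len(est_ids), slope)
        b = np.empty(len(est_ids))
        nodes, weights = quadrature_nodes()
        ac = np.array([by_id[i].a for i in est_ids if i in by_id])
        bc = np.array([by_id[i].b for i in est_ids if i in by_id])
        Xc = X0[:, calib_mask]
        Mc = M[:, calib_mask]
        post, _, _ = _posteriors(Xc, Mc, ac, bc, nodes, weights)
        for j, iid in enumerate(est_ids):
            if iid in by_id:
                b[j] = by_id[iid].b
            else:  # re-estimate location under the purified slope
                nbar = M[:, j] @ post
                rbar = (X0[:, j] * M[:, j]) @ post
                c = 0.0
                for _ in range(25):
                    Pj = _sigmoid(slope * nodes + c)
                    g = (rbar - nbar * Pj).sum()
                    h = (nbar * Pj * (1 - Pj)).sum() + 1e-10
                    c += np.clip(g / h, -2.0, 2.0)
                b[j] = -c / slope
        stats = _loo_fit_statistics(X0, M, est_ids, a, b, calib_mask)
        return stats, fit

    stats, fit = _pass(set())
    flagged = {s.item_id for s in stats if s.flagged}
    if flagged and flagged != set(est_ids):
        stats, fit = _pass(flagged)
    return stats, fit
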