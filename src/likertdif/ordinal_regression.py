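"""Proportional-odds fits and Nagelkerke pseudo-R2 for nested DIF models.

For an ordinal item response ``u`` with categories ``1..K`` the
cumulative-logit (proportional-odds) model is parameterized on the
"k or higher" orientation:

    logit P(u >= k) = alpha_k + x' beta,   k = 2..K.

Three nested models per item share this form and differ in ``x``:

    Model 1 (no DIF):          theta
    Model 2 (+ uniform DIF):   theta, group indicators
    Model 3 (+ non-uniform):   theta, group indicators, theta x group

DIF is judged by changes in Nagelkerke pseudo-R2 between these models:
Model 1 -> 2 captures uniform DIF (a group main effect constant over
trait levels), Model 2 -> 3 non-uniform DIF (a trait-by-group
interaction).  With G groups the designs carry G-1 indicator columns
and G-1 interaction columns, the reference group being the first level
in sorted label order; for G = 2 this reduces to the familiar
two-group formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .core_io import DataError, GroupAssignment
from .grm import FitError, ThetaScores

_MAX_ITER = 100
_TOL = 1e-8


@dataclass
class OLRFit:
    """Fitted cumulative-logit model on the P(u >= k) orientation."""

    alpha: np.ndarray  # intercepts alpha_k, k = 2..K (non-increasing)
    beta: np.ndarray  # slope coefficients, may be empty
    loglik: float
    n: int
    column_names: list[str] = field(default_factory=list)


def _cumulative_F(alpha: np.ndarray, eta_x: np.ndarray) -> np.ndarray:
    """F[:, k-2] = P(u >= k | x) for k = 2..K."""
    return expit(alpha[None, :] + eta_x[:, None])


def _loglik_terms(y: np.ndarray, alpha: np.ndarray, eta_x: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation category probability and full F with sentinels."""
    n = y.size
    F = np.empty((n, K + 1))
    F[:, 0] = 1.0
    F[:, 1:K] = _cumulative_F(alpha, eta_x)
    F[:, K] = 0.0
    p = F[np.arange(n), y - 1] - F[np.arange(n), y]
    return p, F


def proportional_odds_loglik(y: np.ndarray, X: np.ndarray, alpha: np.ndarray, beta: np.ndarray, K: int) -> float:
    """Log-likelihood of the cumulative model at given parameters."""
    eta_x = X @ beta if X.size else np.zeros(y.size)
    p, _ = _loglik_terms(y, alpha, eta_x, K)
    if (p <= 0).any():
        return -np.inf
    return float(np.log(p).sum())


def _category_order(y: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Stable ordering of observations by category, with segment starts.

    Used to turn per-observation score/curvature terms into
    per-category sums via ``np.add.reduceat``.
    """
    order = np.argsort(y, kind="stable")
    counts = np.bincount(y, minlength=K + 1)[1:]
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return order, starts


def _newton_state(y, X, X_ord, alpha, beta, K, order, starts):
    """Log-likelihood, gradient and Hessian at the current parameters.

    Observation i contributes to at most two linear predictors,
    ``eta_{y_i}`` (intercept slot ``y_i - 2``) and ``eta_{y_i + 1}``
    (slot ``y_i - 1``); the boundary terms need no masking because the
    logistic density factor ``F (1 - F)`` vanishes at the sentinels
    ``F = 1`` (y = 1) and ``F = 0`` (y = K).  The intercept block of
    the Hessian is therefore tridiagonal with per-category segment
    sums as entries.
    """
    n, p_dim = y.size, beta.size
    eta_x = X @ beta if p_dim else np.zeros(n)
    prob, F = _loglik_terms(y, alpha, eta_x, K)
    if (prob <= 1e-300).any():
        return -np.inf, None, None
    ll = float(np.log(prob).sum())

    rows = np.arange(n)
    F_hi = F[rows, y - 1]  # P(u >= y); == 1 when y == 1
    F_lo = F[rows, y]  # P(u >= y+1); == 0 when y == K
    f_hi = F_hi * (1 - F_hi)
    f_lo = F_lo * (1 - F_lo)
    g_hi = f_hi / prob
    g_lo = -f_lo / prob
    h_hh = f_hi * (1 - 2 * F_hi) / prob - g_hi**2
    h_ll = -f_lo * (1 - 2 * F_lo) / prob - g_lo**2
    h_hl = f_hi * f_lo / prob**2

    # per-category sums, index 0..K-1 <-> categories 1..K
    packed = np.stack([g_hi, g_lo, h_hh, h_ll, h_hl], axis=1)
    sums = np.add.reduceat(packed[order], starts, axis=0)
    S_ghi, S_glo, S_hhh, S_hll, S_hhl = sums.T

    n_alpha = K - 1
    dim = n_alpha + p_dim
    grad = np.empty(dim)
    H = np.zeros((dim, dim))

    grad[:n_alpha] = S_ghi[1:] + S_glo[:-1]
    idx = np.arange(n_alpha)
    H[idx, idx] = S_hhh[1:] + S_hll[:-1]
    if n_alpha > 1:
        # (y-2, y-1) cross terms for y = 2..K-1
        H[idx[:-1], idx[:-1] + 1] = S_hhl[1 : K - 1]
        H[idx[:-1] + 1, idx[:-1]] = S_hhl[1 : K - 1]
    if p_dim:
        grad[n_alpha:] = (g_hi + g_lo) @ X
        CX = np.stack([h_hh + h_hl, h_ll + h_hl], axis=1)[order]
        seg = np.add.reduceat(CX[:, :, None] * X_ord[:, None, :], starts, axis=0)  # (K, 2, p)
        Mab = seg[1:, 0, :] + seg[:-1, 1, :]
        H[:n_alpha, n_alpha:] = Mab
        H[n_alpha:, :n_alpha] = Mab.T
        H[n_alpha:, n_alpha:] = (X * (h_hh + h_ll + 2 * h_hl)[:, None]).T @ X
    return ll, grad, H


def fit_proportional_odds(
    y: np.ndarray,
    X: np.ndarray | None = None,
    column_names: list[str] | None = None,
    check_rank: bool = True,
    start: tuple[np.ndarray, np.ndarray] | None = None,
) -> OLRFit:
    """Maximum-likelihood fit of ``logit P(u >= k) = alpha_k + x' beta``.

    Newton-Raphson with step-halving; convergence when the largest
    parameter update falls below 1e-8.  ``y`` holds codes ``1..K`` with
    every category present; ``X`` may be ``None`` or empty for the
    intercept-only model.
    """
    y = np.asarray(y, dtype=int)
    K = int(y.max())
    if K < 2 or (y < 1).any():
        raise DataError("y must hold codes 1..K with K >= 2")
    counts = np.bincount(y, minlength=K + 1)[1:]
    if (counts == 0).any():
        missing = [int(k + 1) for k in range(K) if counts[k] == 0]
        raise DataError(f"categories {missing} unobserved in y")
    if X is None:
        X = np.empty((y.size, 0))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise DataError("X rows must align with y")
    if not np.isfinite(X).all():
        raise DataError("X contains non-finite values")
    p_dim = X.shape[1]
    if check_rank and p_dim:
        design = np.column_stack([np.ones(y.size), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise FitError("design matrix is rank deficient (collinear or constant column)")

    if start is not None:
        alpha = np.asarray(start[0], dtype=float).copy()
        beta = np.zeros(p_dim)
        beta[: start[1].size] = start[1]
    else:
        # start: empirical cumulative logits, zero slopes
        cum_ge = np.cumsum(counts[::-1])[::-1] / y.size  # P(u >= k), k = 1..K
        alpha = logit(np.clip(cum_ge[1:], 1e-10, 1 - 1e-10))
        beta = np.zeros(p_dim)

    order, starts = _category_order(y, K)
    X_ord = X[order] if p_dim else X
    ll, grad, H = _newton_state(y, X, X_ord, alpha, beta, K, order, starts)
    if not np.isfinite(ll):
        raise FitError("log-likelihood not finite at starting values")
    trace = [ll]
    for _ in range(_MAX_ITER):
        try:
            delta = np.linalg.solve(H, -grad)  # ascent direction: (-H)^{-1} grad
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, -grad, rcond=None)[0]
        step = 1.0
        accepted = False
        for _ in range(30):
            a_new = alpha + step * delta[: K - 1]
            b_new = beta + step * delta[K - 1 :]
            ll_new, g_new, H_new = _newton_state(y, X, X_ord, a_new, b_new, K, order, starts)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            raise FitError(f"proportional-odds step-halving failed; trace={trace[-5:]}")
        max_update = float(np.max(np.abs(step * delta))) if delta.size else 0.0
        alpha, beta, ll, grad, H = a_new, b_new, ll_new, g_new, H_new
        trace.append(ll)
        if max_update < _TOL:
            return OLRFit(alpha, beta, ll, int(y.size), column_names or [f"x{i}" for i in range(p_dim)])
    raise FitError(f"proportional-odds fit did not converge; trace={trace[-5:]}")


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Nagelkerke pseudo-R2 of a model against the intercept-only null.

    Cox-Snell R2 = 1 - exp(2 (ll_null - ll_model) / n), rescaled by its
    maximum 1 - exp(2 ll_null / n) so the statistic can reach 1.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if loglik_model < loglik_null - 1e-8:
        raise DataError("model log-likelihood below the null's (non-nested inputs?)")
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom <= 0:
        raise DataError("degenerate null likelihood; Nagelkerke maximum is zero")
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


@dataclass
class DIFItemStats:
    """Per-item nested-model log-likelihoods and pseudo-R2 changes."""

    item_id: str
    loglik0: float
    loglik1: float
    loglik2: float
    loglik3: float
    r2_1: float
    r2_2: float
    r2_3: float
    d12: float
    d23: float
    d13: float
    n: int

    @classmethod
    def from_logliks(cls, item_id: str, ll0: float, ll1: float, ll2: float, ll3: float, n: int) -> "DIFItemStats":
        r1 = nagelkerke_r2(ll0, ll1, n)
        r2 = nagelkerke_r2(ll0, ll2, n)
        r3 = nagelkerke_r2(ll0, ll3, n)
        return cls(item_id, ll0, ll1, ll2, ll3, r1, r2, r3, r2 - r1, r3 - r2, r3 - r1, n)


def _batch_state(Y, X, O, alphas, betas, K):
    """Vectorized Newton state for J items sharing one design matrix.

    ``Y`` is (J, n) codes, ``O`` the (J, n, K) category one-hot, and
    the returned gradient/Hessian stack is (J, dim) / (J, dim, dim).
    Items whose current parameters give a non-positive category
    probability get ``ll = -inf`` (handled by the caller's line
    search).  Same per-observation algebra as :func:`_newton_state`.
    """
    J, n = Y.shape
    p_dim = betas.shape[1]
    eta_x = (X @ betas.T).T if p_dim else np.zeros((J, n))
    F = np.empty((J, n, K + 1))
    F[:, :, 0] = 1.0
    F[:, :, K] = 0.0
    np.add(alphas[:, None, :], eta_x[:, :, None], out=F[:, :, 1:K])
    expit(F[:, :, 1:K], out=F[:, :, 1:K])
    idx = (Y - 1)[:, :, None]
    F_hi = np.take_along_axis(F, idx, 2)[:, :, 0]
    F_lo = np.take_along_axis(F, idx + 1, 2)[:, :, 0]
    prob = F_hi - F_lo
    bad = (prob <= 1e-300).any(axis=1)
    ll = np.where(bad, -np.inf, np.log(np.clip(prob, 1e-300, None)).sum(axis=1))

    packed = np.empty((J, n, 5))
    f_hi = F_hi * (1 - F_hi)
    f_lo = F_lo * (1 - F_lo)
    g_hi = np.divide(f_hi, prob, out=packed[:, :, 0])
    g_lo = np.divide(f_lo, -prob, out=packed[:, :, 1])
    packed[:, :, 2] = f_hi * (1 - 2 * F_hi) / prob - g_hi**2
    packed[:, :, 3] = -f_lo * (1 - 2 * F_lo) / prob - g_lo**2
    h_hl = np.divide(f_hi * f_lo, prob**2, out=packed[:, :, 4])
    h_hh = packed[:, :, 2]
    h_ll = packed[:, :, 3]

    S = np.einsum("jnk,jnq->jkq", O, packed)  # per-category sums (J, K, 5)
    S_ghi, S_glo, S_hhh, S_hll, S_hhl = (S[:, :, q] for q in range(5))

    n_alpha = K - 1
    dim = n_alpha + p_dim
    grad = np.empty((J, dim))
    H = np.zeros((J, dim, dim))
    grad[:, :n_alpha] = S_ghi[:, 1:] + S_glo[:, :-1]
    ar = np.arange(n_alpha)
    H[:, ar, ar] = S_hhh[:, 1:] + S_hll[:, :-1]
    if n_alpha > 1:
        H[:, ar[:-1], ar[:-1] + 1] = S_hhl[:, 1 : K - 1]
        H[:, ar[:-1] + 1, ar[:-1]] = S_hhl[:, 1 : K - 1]
    if p_dim:
        grad[:, n_alpha:] = np.einsum("jn,np->jp", g_hi + g_lo, X)
        CH = np.einsum("jnk,jn,np->jkp", O, h_hh + h_hl, X)
        CL = np.einsum("jnk,jn,np->jkp", O, h_ll + h_hl, X)
        Mab = CH[:, 1:, :] + CL[:, :-1, :]
        H[:, :n_alpha, n_alpha:] = Mab
        H[:, n_alpha:, :n_alpha] = Mab.transpose(0, 2, 1)
        H[:, n_alpha:, n_alpha:] = np.einsum("jn,np,nq->jpq", h_hh + h_ll + 2 * h_hl, X, X)
    return ll, grad, H


def _batch_fit(Y, X, O, alphas0, betas0, K):
    """Batched Newton-Raphson over J items; returns (alphas, betas, ll)."""
    J = Y.shape[0]
    p_dim = X.shape[1]
    alphas = alphas0.copy()
    betas = betas0.copy() if p_dim else np.zeros((J, 0))
    ll, grad, H = _batch_state(Y, X, O, alphas, betas, K)
    if not np.isfinite(ll).all():
        raise FitError("batched fit: non-finite log-likelihood at start")
    active = np.ones(J, dtype=bool)
    for _ in range(_MAX_ITER):
        delta = np.zeros((J, K - 1 + p_dim))
        try:
            delta[active] = np.linalg.solve(H[active], -grad[active][..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise FitError(f"batched fit: singular Hessian ({exc})") from exc
        step = np.where(active, 1.0, 0.0)
        a_new, b_new = alphas, betas
        for _ in range(30):
            a_new = alphas + step[:, None] * delta[:, : K - 1]
            b_new = betas + step[:, None] * delta[:, K - 1 :]
            ll_new, g_new, H_new = _batch_state(Y, X, O, a_new, b_new, K)
            rejected = active & ~(np.isfinite(ll_new) & (ll_new >= ll - 1e-10))
            if not rejected.any():
                break
            step[rejected] *= 0.5
        else:
            raise FitError("batched fit: step-halving failed")
        alphas, betas, ll, grad, H = a_new, b_new, ll_new, g_new, H_new
        updates = np.abs(step[:, None] * delta).max(axis=1)
        active = updates >= _TOL
        if not active.any():
            return alphas, betas, ll
    raise FitError("batched fit did not converge")


def batch_dif_statistics(
    Y: np.ndarray,
    theta: "ThetaScores | np.ndarray",
    g: GroupAssignment,
    item_ids: list[str],
    warm: dict | None = None,
) -> list[DIFItemStats]:
    """Nested-model DIF statistics for many items in one Newton sweep.

    Equivalent to calling :func:`dif_statistics_for_item` per column of
    ``Y`` (items sharing a category count are batched together); used
    by the Monte-Carlo threshold loop where thousands of small fits
    dominate the run time.
    """
    th = theta.theta if isinstance(theta, ThetaScores) else np.asarray(theta, dtype=float)
    Y = np.asarray(Y, dtype=int).T  # (J, n)
    ind, inter, _ = dif_design_columns(th, g)
    X1 = th[:, None]
    X2 = np.column_stack([th, ind])
    X3 = np.column_stack([th, ind, inter])

    out: list[DIFItemStats | None] = [None] * len(item_ids)
    Ks = Y.max(axis=1)
    for K in np.unique(Ks):
        K = int(K)
        sel = np.flatnonzero(Ks == K)
        Yk = Y[sel]
        counts = np.stack([np.bincount(Yk[j], minlength=K + 1)[1:] for j in range(sel.size)])
        if (counts == 0).any():
            j_bad = sel[np.flatnonzero((counts == 0).any(axis=1))[0]]
            raise FitError(f"item {item_ids[j_bad]!r}: not all categories observed")
        n = Yk.shape[1]
        ll0 = (counts * np.log(counts / n)).sum(axis=1)
        O = (Yk[:, :, None] == np.arange(1, K + 1)[None, None, :]).astype(float)
        cached = warm.get(K) if warm is not None else None
        if cached is not None and cached[0].shape[0] == sel.size:
            s1, s1b, s2, s2b, s3, s3b = cached
        else:
            cum_ge = np.cumsum(counts[:, ::-1], axis=1)[:, ::-1] / n
            s1 = logit(np.clip(cum_ge[:, 1:], 1e-10, 1 - 1e-10))
            s1b = np.zeros((sel.size, 1))
            s2 = s3 = None
        a1, b1, ll1 = _batch_fit(Yk, X1, O, s1, s1b, K)
        if s2 is None:
            s2 = a1
            s2b = np.zeros((sel.size, X2.shape[1]))
            s2b[:, :1] = b1
        a2, b2, ll2 = _batch_fit(Yk, X2, O, s2, s2b, K)
        if s3 is None:
            s3 = a2
            s3b = np.zeros((sel.size, X3.shape[1]))
            s3b[:, : X2.shape[1]] = b2
        a3, b3, ll3 = _batch_fit(Yk, X3, O, s3, s3b, K)
        if warm is not None:
            warm[K] = (a1, b1, a2, b2, a3, b3)
        for i, j in enumerate(sel):
            out[j] = DIFItemStats.from_logliks(
                item_ids[j], float(ll0[i]), float(ll1[i]), float(ll2[i]), float(ll3[i]), n
            )
    return out  # type: ignore[return-value]


def dif_design_columns(theta: np.ndarray, g: GroupAssignment) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Group-indicator and trait-by-group interaction columns.

    Reference level is the first in sorted order; the remaining G-1
    levels get indicators and matching theta interactions.
    """
    levels = g.levels
    if len(levels) < 2:
        raise DataError("DIF designs need >= 2 group levels")
    ind = np.column_stack([(g.labels == lv).astype(float) for lv in levels[1:]])
    inter = ind * theta[:, None]
    names = [f"group[{lv}]" for lv in levels[1:]]
    return ind, inter, names


def dif_statistics_for_item(
    y: np.ndarray,
    theta: ThetaScores | np.ndarray,
    g: GroupAssignment,
    item_id: str = "item",
    warm: dict | None = None,
) -> DIFItemStats:
    """Nested-model DIF statistics for one item.

    Fits the intercept-only model and Models 1-3 on the same rows and
    returns Nagelkerke pseudo-R2 changes: ``d12`` (uniform DIF),
    ``d23`` (non-uniform DIF) and their telescoping sum ``d13``.

    ``warm``, if given, caches converged coefficients under ``item_id``
    across repeated calls on same-design data (the Monte-Carlo loop)
    to cut Newton iterations; it never changes the optimum.
    """
    th = theta.theta if isinstance(theta, ThetaScores) else np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.size != th.size or y.size != g.n_persons:
        raise DataError(f"item {item_id!r}: misaligned y/theta/group")
    if g.missing_mask.any():
        raise DataError(f"item {item_id!r}: persons with missing group must be removed first")

    ind, inter, names = dif_design_columns(th, g)
    try:
        # intercept-only log-likelihood has the closed multinomial form
        K = int(y.max())
        counts = np.bincount(y, minlength=K + 1)[1:]
        if (counts == 0).any():
            raise DataError(f"item {item_id!r}: not all categories observed")
        ll0 = float((counts[counts > 0] * np.log(counts[counts > 0] / y.size)).sum())
        cached = warm.get(item_id) if warm is not None else None
        if cached is not None and cached[0][0].size != K - 1:
            cached = None  # category count changed; cache unusable
        s1, s2, s3 = cached if cached is not None else (None, None, None)
        f1 = fit_proportional_odds(y, th[:, None], ["theta"], check_rank=False, start=s1)
        f2 = fit_proportional_odds(
            y,
            np.column_stack([th, ind]),
            ["theta"] + names,
            check_rank=False,
            start=s2 if s2 is not None else (f1.alpha, f1.beta),
        )
        f3 = fit_proportional_odds(
            y,
            np.column_stack([th, ind, inter]),
            ["theta"] + names + [f"theta:{nm}" for nm in names],
            check_rank=False,
            start=s3 if s3 is not None else (f2.alpha, f2.beta),
        )
        if warm is not None:
            warm[item_id] = (
                (f1.alpha, f1.beta),
                (f2.alpha, f2.beta),
                (f3.alpha, f3.beta),
            )
    except (FitError, DataError) as exc:
        raise FitError(f"item {item_id!r}: {exc}") from exc
    return DIFItemStats.from_logliks(item_id, ll0, f1.loglik, f2.loglik, f3.loglik, int(y.size))
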