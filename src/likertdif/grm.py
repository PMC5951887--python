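"""Samejima graded response model (GRM).

Marginal-maximum-likelihood calibration by EM with a fixed N(0,1)
latent-trait prior on an equally spaced quadrature grid, expected a
posteriori (EAP) trait scoring, and response simulation.

For an item with discrimination ``a > 0`` and ordered thresholds
``b_2 < ... < b_K`` the cumulative ("operating characteristic")
probability of responding in category ``k`` or higher is

    P(u >= k | theta) = sigma(a (theta - b_k)),   sigma = logistic,

with ``b_1 = -inf`` and ``b_{K+1} = +inf``; category probabilities are
adjacent differences of these curves.  The N(0,1) prior anchors the
latent metric (mean 0, SD 1), so thresholds and EAP scores are in
trait-SD units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, ndtri
from scipy.stats import norm

from .core_io import DataError, ResponseMatrix

# Quadrature: 101 equally spaced points on [-6, 6] with N(0,1) weights.
QUAD_POINTS = 101
QUAD_RANGE = 6.0


class FitError(RuntimeError):
    """Raised when an iterative fit fails to converge or is ill-posed."""


def quadrature_grid(n_points: int = QUAD_POINTS, bound: float = QUAD_RANGE) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced grid with normalized standard-normal weights."""
    nodes = np.linspace(-bound, bound, n_points)
    w = norm.pdf(nodes)
    return nodes, w / w.sum()


@dataclass
class GRMItemParams:
    """Discrimination ``a`` and strictly increasing thresholds ``b``."""

    item_id: str
    a: float
    b: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if not self.a > 0:
            raise DataError(f"item {self.item_id!r}: discrimination must be > 0")
        if self.b.size > 1 and not (np.diff(self.b) > 0).all():
            raise DataError(f"item {self.item_id!r}: thresholds must be strictly increasing")

    @property
    def n_categories(self) -> int:
        return self.b.size + 1


@dataclass
class ThetaScores:
    """EAP trait estimates with posterior SDs, aligned with persons."""

    theta: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.theta.shape != self.se.shape:
            raise DataError("theta and se must be aligned")


def grm_category_probs(p: GRMItemParams, theta: float | np.ndarray) -> np.ndarray:
    """Category probabilities ``P(u = k | theta)`` for k = 1..K.

    Returns shape ``(K,)`` for scalar theta, else ``(len(theta), K)``.
    Probabilities are adjacent differences of the cumulative logistic
    curves and sum to one.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    cum = expit(p.a * (th[:, None] - p.b[None, :]))  # (n, K-1)
    ones = np.ones((th.size, 1))
    zeros = np.zeros((th.size, 1))
    star = np.concatenate([ones, cum, zeros], axis=1)  # P(u>=k), k=1..K+1
    probs = star[:, :-1] - star[:, 1:]
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return probs[0]
    return probs


def _log_prob_tables(params: Sequence[GRMItemParams], nodes: np.ndarray) -> list[np.ndarray]:
    """Per item: (K_j, Q) table of log P(u=k | node)."""
    out = []
    for p in params:
        probs = grm_category_probs(p, nodes)  # (Q, K)
        out.append(np.log(np.clip(probs, 1e-300, None)).T)
    return out


def _posterior_weights(
    params: Sequence[GRMItemParams],
    responses: np.ndarray,
    nodes: np.ndarray,
    prior_w: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior over nodes per person and marginal log-likelihood.

    Missing responses are skipped in the likelihood; an all-missing row
    gets the prior back.
    """
    n = responses.shape[0]
    loglik = np.zeros((n, nodes.size))
    tables = _log_prob_tables(params, nodes)
    for j, tab in enumerate(tables):
        col = responses[:, j]
        obs = ~np.isnan(col)
        if obs.any():
            loglik[obs] += tab[col[obs].astype(int) - 1]
    logpost = loglik + np.log(prior_w)[None, :]
    m = logpost.max(axis=1, keepdims=True)
    un = np.exp(logpost - m)
    norm_c = un.sum(axis=1, keepdims=True)
    post = un / norm_c
    marginal = float((np.log(norm_c[:, 0]) + m[:, 0]).sum())
    return post, marginal


def _pack(p: GRMItemParams) -> np.ndarray:
    """(log a, b_2, log gaps) — keeps a > 0 and thresholds ordered."""
    if p.b.size == 1:
        return np.array([np.log(p.a), p.b[0]])
    return np.concatenate([[np.log(p.a), p.b[0]], np.log(np.diff(p.b))])


def _unpack(item_id: str, x: np.ndarray) -> GRMItemParams:
    a = float(np.exp(x[0]))
    b = np.empty(x.size - 1)
    b[0] = x[1]
    if x.size > 2:
        b[1:] = x[1] + np.cumsum(np.exp(x[2:]))
    return GRMItemParams(item_id, a, b)


def _expected_negloglik(x: np.ndarray, item_id: str, r: np.ndarray, nodes: np.ndarray) -> tuple[float, np.ndarray]:
    """E-step objective for one item: -sum_kq r_kq log P_k(node_q).

    Returns value and gradient in the packed parameterization.
    """
    p = _unpack(item_id, x)
    a, b = p.a, p.b
    K = b.size + 1
    cum = expit(a * (nodes[:, None] - b[None, :]))  # (Q, K-1) = P(u>=k+1)
    star = np.concatenate([np.ones((nodes.size, 1)), cum, np.zeros((nodes.size, 1))], axis=1)
    probs = np.clip(star[:, :-1] - star[:, 1:], 1e-12, None)  # (Q, K)
    val = -(r.T * np.log(probs)).sum()

    # dP*_k/da = P*(1-P*)(node - b_k); dP*_k/db_k = -a P*(1-P*)
    f = cum * (1 - cum)  # (Q, K-1)
    w = r.T / probs  # (Q, K)
    # cumulative curve k (cum column k-2, k=2..K) enters P_k with +1 and
    # P_{k-1} with -1, so d val / d star_k = -(w_k - w_{k-1})
    dstar = -(w[:, 1:] - w[:, :-1])
    grad_a = float((dstar * f * (nodes[:, None] - b[None, :])).sum())
    grad_b = -(dstar * f).sum(axis=0) * a  # (K-1,)

    g = np.empty_like(x)
    g[0] = grad_a * a  # chain through log a
    if b.size == 1:
        g[1] = grad_b[0]
    else:
        g[1] = grad_b.sum()
        gaps = np.exp(x[2:])
        # b_m = b_2 + sum_{i<m} gap_i: gap_i affects b_{i+2}..b_K
        tail = np.cumsum(grad_b[::-1])[::-1]
        g[2:] = tail[1:] * gaps
    return val, g


def _starting_values(item_id: str, col: np.ndarray, k: int) -> GRMItemParams:
    """a = 1; thresholds at normal quantiles of the cumulative margins."""
    obs = col[~np.isnan(col)].astype(int)
    b = np.empty(k - 1)
    n = obs.size
    for c in range(2, k + 1):
        frac_below = ((obs < c).sum() + 0.5) / (n + 1.0)
        b[c - 2] = ndtri(np.clip(frac_below, 1e-4, 1 - 1e-4))
    # enforce a minimal gap so the packed log-gap form is finite
    for i in range(1, b.size):
        b[i] = max(b[i], b[i - 1] + 1e-3)
    return GRMItemParams(item_id, 1.0, b)


def fit_grm(
    m: ResponseMatrix,
    max_cycles: int = 500,
    tol: float = 1e-4,
    init: Sequence[GRMItemParams] | None = None,
    trace_out: list[float] | None = None,
) -> tuple[list[GRMItemParams], float]:
    """Calibrate the GRM by marginal-maximum-likelihood EM.

    E-step: posterior weights over the quadrature grid under the N(0,1)
    prior.  M-step: per-item maximization of the expected complete-data
    log-likelihood (quasi-Newton on log-discrimination and log threshold
    gaps).  Convergence: max absolute parameter change below ``tol``.
    The marginal log-likelihood is non-decreasing over cycles.

    Returns the per-item parameter list and the marginal log-likelihood
    at the estimate.
    """
    if m.n_items < 2:
        raise DataError("GRM calibration needs >= 2 items")
    resp = m.responses
    for j, item in enumerate(m.item_ids):
        col = resp[:, j]
        obs = col[~np.isnan(col)].astype(int)
        if obs.size == 0:
            raise DataError(f"item {item!r} has no observed responses")
        k = int(m.item_categories[j])
        present = set(obs.tolist())
        missing_cats = [c for c in range(1, k + 1) if c not in present]
        if missing_cats:
            raise DataError(
                f"item {item!r}: categories {missing_cats} unobserved; "
                "collapse categories before calibration"
            )

    nodes, prior_w = quadrature_grid()
    if init is not None:
        if len(init) != m.n_items:
            raise DataError("init parameter list not aligned with items")
        params = list(init)
    else:
        params = [
            _starting_values(item, resp[:, j], int(m.item_categories[j]))
            for j, item in enumerate(m.item_ids)
        ]
    trace = trace_out if trace_out is not None else []
    for cycle in range(max_cycles):
        post, marginal = _posterior_weights(params, resp, nodes, prior_w)
        trace.append(marginal)
        max_change = 0.0
        new_params: list[GRMItemParams] = []
        for j, p in enumerate(params):
            col = resp[:, j]
            obs = ~np.isnan(col)
            k = int(m.item_categories[j])
            codes = col[obs].astype(int) - 1
            r = np.zeros((k, nodes.size))
            np.add.at(r, codes, post[obs])
            x0 = _pack(p)
            res = minimize(
                _expected_negloglik,
                x0,
                args=(p.item_id, r, nodes),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 50, "ftol": 1e-12, "gtol": 1e-8},
            )
            x1 = res.x if np.isfinite(res.fun) else x0
            newp = _unpack(p.item_id, x1)
            change = max(abs(newp.a - p.a), float(np.max(np.abs(newp.b - p.b))))
            max_change = max(max_change, change)
            new_params.append(newp)
        params = new_params
        if max_change < tol:
            _, marginal = _posterior_weights(params, resp, nodes, prior_w)
            trace.append(marginal)
            return params, marginal
    raise FitError(
        f"GRM EM did not converge in {max_cycles} cycles; "
        f"last log-likelihoods: {trace[-5:]}"
    )


def marginal_loglik(params: Sequence[GRMItemParams], m: ResponseMatrix) -> float:
    """Marginal log-likelihood of ``m`` under fixed item parameters."""
    nodes, prior_w = quadrature_grid()
    _, ll = _posterior_weights(params, m.responses, nodes, prior_w)
    return ll


class EAPScorer:
    """EAP scoring with item log-probability tables cached.

    Useful when the same calibration scores many matrices (the
    Monte-Carlo threshold loop); one-shot use goes through
    :func:`eap_scores`.
    """

    def __init__(
        self,
        params: Sequence[GRMItemParams],
        n_points: int = QUAD_POINTS,
        bound: float = QUAD_RANGE,
    ) -> None:
        self.params = list(params)
        self.nodes, self.prior_w = quadrature_grid(n_points, bound)
        self._tables = _log_prob_tables(self.params, self.nodes)
        self._log_prior = np.log(self.prior_w)

    def score(self, responses: np.ndarray) -> ThetaScores:
        n = responses.shape[0]
        loglik = np.zeros((n, self.nodes.size))
        for j, tab in enumerate(self._tables):
            col = responses[:, j]
            obs = ~np.isnan(col)
            if obs.all():
                loglik += tab[col.astype(int) - 1]
            elif obs.any():
                loglik[obs] += tab[col[obs].astype(int) - 1]
        logpost = loglik + self._log_prior[None, :]
        m = logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost - m)
        post /= post.sum(axis=1, keepdims=True)
        theta = post @ self.nodes
        var = np.clip(post @ self.nodes**2 - theta**2, 0.0, None)
        se = np.sqrt(var)
        all_missing = np.isnan(responses).all(axis=1)
        theta[all_missing] = 0.0
        se[all_missing] = 1.0
        return ThetaScores(theta, se)


def eap_scores(
    params: Sequence[GRMItemParams],
    m: ResponseMatrix,
    n_points: int = QUAD_POINTS,
    bound: float = QUAD_RANGE,
) -> ThetaScores:
    """Expected a posteriori trait scores under the N(0,1) prior.

    Missing responses are skipped; an all-missing row returns the prior
    mean 0 with SD 1.
    """
    if len(params) != m.n_items:
        raise DataError("parameter list not aligned with items")
    return EAPScorer(params, n_points, bound).score(m.responses)


def simulate_grm_codes(
    params: Sequence[GRMItemParams],
    theta: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw simulated code array (persons x items), no container."""
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    out = np.empty((n, len(params)))
    u = rng.random((n, len(params)))
    for j, p in enumerate(params):
        # inverse-CDF draw: count how many cumulative P(u>=k) exceed u
        cum = expit(p.a * (theta[:, None] - p.b[None, :]))  # P(u>=2..K)
        out[:, j] = 1 + (u[:, j, None] < cum).sum(axis=1)
    return out


def simulate_grm(
    params: Sequence[GRMItemParams],
    theta: np.ndarray,
    seed: int | np.random.Generator,
) -> ResponseMatrix:
    """Draw a response matrix from the GRM at the given trait values."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    out = simulate_grm_codes(params, theta, rng)
    cats = np.array([p.n_categories for p in params])
    return ResponseMatrix(
        out,
        [f"p{i}" for i in range(n)],
        [p.item_id for p in params],
        int(cats.max()),
        cats,
    )


def params_to_json(params: Sequence[GRMItemParams], path: str | Path) -> None:
    payload = [{"item_id": p.item_id, "a": p.a, "b": p.b.tolist()} for p in params]
    Path(path).write_text(json.dumps(payload, indent=2))


def params_from_json(path: str | Path) -> list[GRMItemParams]:
    payload = json.loads(Path(path).read_text())
    return [GRMItemParams(d["item_id"], d["a"], np.asarray(d["b"])) for d in payload]
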