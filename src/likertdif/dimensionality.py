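"""Exploratory unidimensionality checks for ordinal item sets.

Polychoric correlations treat each observed Likert item as a
discretized standard-normal variable; the two-step estimator fixes the
discretization thresholds at the normal quantiles of the observed
margins and maximizes the bivariate-normal likelihood of the
contingency table over the latent correlation alone.  Factor-retention
counts come from permutation-based parallel analysis (reference
eigenvalues from column-permuted copies of the data, which destroy
inter-item structure while keeping the ordinal margins) and from the
Empirical Kaiser Criterion, whose sample-size-adjusted reference value
for the j-th eigenvalue is

    ref_j = max( (p - sum_{i<j} l_i) / (p - j + 1) * (1 + sqrt(p/n))^2 , 1 ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

from .core_io import DataError, ResponseMatrix

_GL_NODES, _GL_WEIGHTS = leggauss(24)
_TRUNC = 7.5  # effective infinity for normal thresholds


def _thresholds_from_margin(codes: np.ndarray, k: int) -> np.ndarray:
    """Normal quantiles of the cumulative margins, with +-inf ends."""
    n = codes.size
    tau = np.empty(k + 1)
    tau[0] = -_TRUNC
    tau[k] = _TRUNC
    for c in range(1, k):
        frac = (codes <= c).sum() / n
        tau[c] = ndtri(np.clip(frac, 1e-10, 1 - 1e-10))
    return tau


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for all cells.

    Integrates phi(x) * [Phi((t_{d+1}-rho x)/s) - Phi((t_d-rho x)/s)]
    over each x-interval with fixed Gauss-Legendre nodes.
    """
    kx = tau_x.size - 1
    s = np.sqrt(max(1.0 - rho * rho, 1e-12))
    lo = tau_x[:-1]
    hi = tau_x[1:]
    mid = 0.5 * (hi + lo)
    half = 0.5 * (hi - lo)
    x = mid[:, None] + half[:, None] * _GL_NODES[None, :]  # (kx, m)
    w = half[:, None] * _GL_WEIGHTS[None, :] * np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
    z = (tau_y[None, None, :] - rho * x[:, :, None]) / s  # (kx, m, ky+1)
    cdf = ndtr(z)
    inner = cdf[:, :, 1:] - cdf[:, :, :-1]  # (kx, m, ky)
    return np.einsum("im,imj->ij", w, inner)


def polychoric_pair(
    x: np.ndarray, y: np.ndarray, kx: int, ky: int
) -> float:
    """Two-step ML polychoric correlation of two coded items.

    Thresholds come from the margins; the correlation maximizes the
    contingency-table likelihood.  Degenerate tables (an observed
    margin with a single category, or a flat likelihood pushing the
    estimate to the boundary) fall back to the Pearson correlation of
    the codes with a warning.
    """
    obs = ~(np.isnan(x) | np.isnan(y))
    xs = x[obs].astype(int)
    ys = y[obs].astype(int)
    if xs.size < 4:
        raise DataError("too few complete pairs for a polychoric estimate")

    def _pearson(reason: str) -> float:
        warnings.warn(f"polychoric fallback to Pearson: {reason}", stacklevel=3)
        if xs.std() == 0 or ys.std() == 0:
            return 0.0
        return float(np.corrcoef(xs, ys)[0, 1])

    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        return _pearson("margin with a single observed category")
    tau_x = _thresholds_from_margin(xs, kx)
    tau_y = _thresholds_from_margin(ys, ky)
    table = np.zeros((kx, ky))
    np.add.at(table, (xs - 1, ys - 1), 1.0)

    def nll(rho: float) -> float:
        p = np.clip(_cell_probs(tau_x, tau_y, rho), 1e-12, None)
        return -float((table * np.log(p)).sum())

    res = minimize_scalar(nll, bounds=(-0.995, 0.995), method="bounded", options={"xatol": 1e-5})
    rho = float(res.x)
    if not np.isfinite(res.fun) or abs(rho) > 0.99:
        return _pearson("flat or boundary likelihood")
    return rho


def _nearest_psd_correlation(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at zero and renormalize the diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= -1e-10:
        return R
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def polychoric_matrix(m: ResponseMatrix) -> np.ndarray:
    """Symmetric polychoric correlation matrix with unit diagonal.

    Repaired to the nearest positive-semidefinite correlation matrix
    (eigenvalue clipping) if the pairwise estimates are incompatible.
    """
    p = m.n_items
    if p < 2:
        raise DataError("polychoric matrix needs >= 2 items")
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            r = polychoric_pair(
                m.responses[:, i],
                m.responses[:, j],
                int(m.item_categories[i]),
                int(m.item_categories[j]),
            )
            R[i, j] = R[j, i] = r
    return _nearest_psd_correlation(R)


@dataclass
class EigenReport:
    """Observed spectrum with per-method references and retention counts."""

    observed_eigenvalues: np.ndarray
    reference_eigenvalues: dict[str, np.ndarray]
    n_factors_retained: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "observed_eigenvalues": self.observed_eigenvalues.tolist(),
            "reference_eigenvalues": {k: v.tolist() for k, v in self.reference_eigenvalues.items()},
            "n_factors_retained": self.n_factors_retained,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _eigenvalues(R: np.ndarray) -> np.ndarray:
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def parallel_analysis(
    m: ResponseMatrix,
    R: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> EigenReport:
    """Permutation-based parallel analysis on polychoric eigenvalues.

    Each replicate permutes every item column independently (breaking
    inter-item correlation, preserving margins), recomputes the
    polychoric matrix, and records its spectrum.  Factors are retained
    while the observed eigenvalue exceeds the reference quantile,
    stopping at the first failure.
    """
    if R < 1:
        raise DataError("parallel analysis needs R >= 1")
    rng = np.random.default_rng(seed)
    observed = _eigenvalues(polychoric_matrix(m))
    null_eigs = np.empty((R, m.n_items))
    perm = ResponseMatrix(
        m.responses.copy(), list(m.person_ids), list(m.item_ids), m.K, m.item_categories.copy()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(R):
            for j in range(m.n_items):
                perm.responses[:, j] = rng.permutation(m.responses[:, j])
            null_eigs[r] = _eigenvalues(polychoric_matrix(perm))
    reference = np.quantile(null_eigs, quantile, axis=0)
    retained = 0
    for obs_l, ref_l in zip(observed, reference):
        if obs_l > ref_l:
            retained += 1
        else:
            break
    return EigenReport(observed, {"parallel_analysis": reference}, {"parallel_analysis": retained})


def empirical_kaiser_criterion(eigenvalues: np.ndarray, n: int, p: int) -> tuple[int, np.ndarray]:
    """Retention count and reference values under the EKC.

    ``eigenvalues`` is the descending spectrum of a p-item correlation
    matrix from n observations.  Retention stops at the first
    eigenvalue that fails to exceed its reference value.
    """
    if n <= 0 or p <= 0:
        raise DataError("n and p must be positive")
    l = np.asarray(eigenvalues, dtype=float)
    if (np.diff(l) > 1e-8).any():
        raise DataError("eigenvalues must be in descending order")
    if abs(l.sum() - p) > 0.05 * p:
        raise DataError("eigenvalues do not sum to p; not a correlation spectrum?")
    inflation = (1.0 + np.sqrt(p / n)) ** 2
    refs = np.empty(l.size)
    used = 0.0
    for j in range(l.size):
        refs[j] = max((p - used) / (p - j) * inflation, 1.0)
        used += l[j]
    retained = 0
    for lj, ref in zip(l, refs):
        if lj > ref:
            retained += 1
        else:
            break
    return retained, refs


def dimensionality_report(
    m: ResponseMatrix,
    R: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> EigenReport:
    """Parallel analysis and EKC on the same polychoric spectrum."""
    pa = parallel_analysis(m, R=R, quantile=quantile, seed=seed)
    n_complete = int((~np.isnan(m.responses).any(axis=1)).sum())
    ekc_n, ekc_refs = empirical_kaiser_criterion(
        pa.observed_eigenvalues, n_complete, m.n_items
    )
    pa.reference_eigenvalues["ekc"] = ekc_refs
    pa.n_factors_retained["ekc"] = ekc_n
    return pa
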