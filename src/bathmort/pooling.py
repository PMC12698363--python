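"""Multivariate random-effects meta-analysis of region coefficient vectors.

Stage two of the two-stage design: region-specific coefficient sub-vectors
``b_i`` with within-region covariances ``V_i`` are combined under

    b_i ~ N(beta, V_i + Psi),

where ``Psi`` is the between-region covariance.  Three estimators are
provided: ``fixed`` (Psi = 0, inverse-variance weighting), ``mm`` (a
non-iterative moment estimator of Psi), and ``reml`` (restricted maximum
likelihood over the Cholesky factor of Psi, the default, falling back to
``mm`` on non-convergence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["PooledEstimate", "pool"]


@dataclass
class PooledEstimate:
    """Pooled coefficient vector, its covariance and the heterogeneity Psi."""

    coef: np.ndarray
    vcov: np.ndarray
    psi: np.ndarray
    k: int
    method: str

    @property
    def dim(self) -> int:
        return len(self.coef)


def _gls(bs: np.ndarray, Vs: np.ndarray, psi: np.ndarray):
    """Generalised-least-squares pooling at a fixed Psi."""
    p = bs.shape[1]
    wsum = np.zeros((p, p))
    wb = np.zeros(p)
    Winvs = []
    for b, V in zip(bs, Vs):
        try:
            W = np.linalg.inv(V + psi)
        except np.linalg.LinAlgError as e:
            raise ValueError("singular total covariance V_i + Psi") from e
        Winvs.append(W)
        wsum += W
        wb += W @ b
    vcov = np.linalg.inv(wsum)
    coef = vcov @ wb
    return coef, vcov, Winvs


def _psd_project(M: np.ndarray) -> np.ndarray:
    M = (M + M.T) / 2
    w, U = np.linalg.eigh(M)
    return (U * np.maximum(w, 0.0)) @ U.T


def _mm_psi(bs: np.ndarray, Vs: np.ndarray) -> np.ndarray:
    """Unweighted moment estimator: between-region scatter minus mean V_i,
    projected onto the PSD cone."""
    k = len(bs)
    bbar = bs.mean(axis=0)
    S = (bs - bbar).T @ (bs - bbar) / (k - 1)
    return _psd_project(S - Vs.mean(axis=0))


def _reml_nll(theta: np.ndarray, bs: np.ndarray, Vs: np.ndarray, p: int) -> float:
    L = np.zeros((p, p))
    L[np.tril_indices(p)] = theta
    psi = L @ L.T
    try:
        coef, _, Winvs = _gls(bs, Vs, psi)
    except ValueError:
        return np.inf
    nll = 0.0
    wsum = np.zeros((p, p))
    for b, V, W in zip(bs, Vs, Winvs):
        sign, logdet = np.linalg.slogdet(V + psi)
        if sign <= 0:
            return np.inf
        r = b - coef
        nll += 0.5 * (logdet + r @ W @ r)
        wsum += W
    sign, logdet = np.linalg.slogdet(wsum)
    nll += 0.5 * logdet
    return float(nll)


def pool(estimates, method: str = "reml") -> PooledEstimate:
    """Pool per-region ``(coef, vcov)`` pairs.

    ``estimates`` is a sequence of ``(b_i, V_i)`` with common dimension.
    ``method`` is one of ``fixed``, ``mm``, ``reml``.  Random-effects methods
    require at least two regions; REML with dimension exceeding the number of
    regions emits a weak-identification warning.
    """
    bs = np.asarray([np.asarray(b, float).ravel() for b, _ in estimates])
    Vs = np.asarray([np.asarray(V, float).reshape(bs.shape[1], bs.shape[1])
                     for _, V in estimates])
    k, p = bs.shape
    if k == 1:
        if method != "fixed":
            raise ValueError("random-effects pooling needs k >= 2 regions")
        # exact identity: avoid the round trip through two matrix inversions
        return PooledEstimate(bs[0], Vs[0], np.zeros((p, p)), 1, "fixed")
    if method == "fixed":
        coef, vcov, _ = _gls(bs, Vs, np.zeros((p, p)))
        return PooledEstimate(coef, vcov, np.zeros((p, p)), k, "fixed")
    if method == "mm":
        psi = _mm_psi(bs, Vs)
        coef, vcov, _ = _gls(bs, Vs, psi)
        return PooledEstimate(coef, vcov, psi, k, "mm")
    if method == "reml":
        if p > k:
            warnings.warn(
                f"REML with dimension {p} > {k} regions: Psi weakly identified",
                stacklevel=2,
            )
        psi0 = _mm_psi(bs, Vs) + 1e-8 * np.eye(p)
        L0 = np.linalg.cholesky(psi0)
        theta0 = L0[np.tril_indices(p)]
        res = optimize.minimize(
            _reml_nll, theta0, args=(bs, Vs, p), method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if not res.success or not np.isfinite(res.fun):
            warnings.warn(
                "REML did not converge; falling back to the moment estimator",
                stacklevel=2,
            )
            return pool(estimates, method="mm")
        L = np.zeros((p, p))
        L[np.tril_indices(p)] = res.x
        psi = L @ L.T
        coef, vcov, _ = _gls(bs, Vs, psi)
        return PooledEstimate(coef, vcov, psi, k, "reml")
    raise ValueError(f"unknown pooling method {method!r}")
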