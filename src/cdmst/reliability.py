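"""Attribute-mastery posteriors and the tetrachoric attribute-reliability index.

The reliability of a diagnostic classification is quantified per attribute
as the correlation of a hypothetical test-retest replication: from each
examinee's marginal mastery probability ``p_ek`` a 2x2 replication
contingency table is accumulated, and the attribute reliability is the
tetrachoric correlation of that table — the correlation of the latent
bivariate standard normal whose quadrant probabilities reproduce it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri, owens_t

from .gdina import GDINAItem, enumerate_states

__all__ = [
    "ReplicationTable",
    "posterior_over_states",
    "update_posterior",
    "marginal_mastery",
    "replication_table",
    "bivariate_normal_quadrant",
    "tetrachoric",
    "attribute_reliability",
    "reliability_from_posterior",
]


def posterior_over_states(
    responses: np.ndarray,
    bank_subset: Sequence[GDINAItem] | np.ndarray,
    prior: np.ndarray | None = None,
    *,
    K: int | None = None,
) -> np.ndarray:
    """Posterior over the ``2**K`` knowledge states for each examinee.

    Parameters
    ----------
    responses : (N, J) 0/1 array
        Responses to exactly the items of ``bank_subset`` (in order).
    bank_subset : sequence of GDINAItem, or (J, 2**K) array
        The scoring items, either as objects or as their per-state
        probability rows.
    prior : (2**K,) array, optional
        Defaults to the uniform distribution, matching a population in
        which states are drawn uniformly.

    Returns
    -------
    (N, 2**K) array with nonnegative rows summing to 1:
    ``w_ec ∝ prior(c) * prod_j P_j(c)^x_ej (1-P_j(c))^(1-x_ej)``.
    """
    X = np.atleast_2d(np.asarray(responses))
    if isinstance(bank_subset, np.ndarray):
        P = np.atleast_2d(bank_subset)
    else:
        if K is None:
            K = len(bank_subset[0].q_row) if bank_subset else None
        if K is None:
            raise ValueError("K required for an empty item subset")
        states = enumerate_states(K)
        P = (
            np.array([it.state_probabilities(states) for it in bank_subset])
            if len(bank_subset)
            else np.empty((0, 2**K))
        )
    n_states = P.shape[1]
    if X.shape[1] != P.shape[0]:
        raise ValueError("responses do not match the item subset")
    if prior is None:
        prior = np.full(n_states, 1.0 / n_states)
    # log-domain accumulation is unnecessary for the test lengths used here,
    # but guard against underflow by renormalizing per item
    w = np.broadcast_to(prior, (X.shape[0], prior.shape[0])).astype(float).copy()
    for j in range(P.shape[0]):
        w = update_posterior(w, X[:, j], P[j])
    return w


def update_posterior(w: np.ndarray, x_col: np.ndarray, state_prob: np.ndarray) -> np.ndarray:
    """Append one item to a posterior: multiply its likelihood and renormalize.

    Algebraically identical to recomputing the posterior from scratch with
    the extended item set.
    """
    x = np.asarray(x_col)[:, None]
    like = np.where(x == 1, state_prob[None, :], 1.0 - state_prob[None, :])
    w = w * like
    tot = w.sum(axis=1, keepdims=True)
    if (tot <= 0).any():
        raise ValueError("zero total likelihood for at least one examinee")
    return w / tot


def marginal_mastery(posterior: np.ndarray, K: int | None = None) -> np.ndarray:
    """Marginal mastery probabilities ``p_ek = sum_{c: alpha_ck=1} w_ec``.

    Returns an ``(N, K)`` array.
    """
    w = np.atleast_2d(posterior)
    n_states = w.shape[1]
    if K is None:
        K = int(round(np.log2(n_states)))
    if 2**K != n_states:
        raise ValueError("posterior width is not 2**K")
    return w @ enumerate_states(K)


@dataclass(frozen=True)
class ReplicationTable:
    """2x2 test-retest replication table for one attribute.

    Entries are probabilities summing to 1; symmetry ``p10 == p01`` holds
    by construction.
    """

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        vals = (self.p11, self.p10, self.p01, self.p00)
        if any(v < -1e-12 or v > 1 + 1e-12 for v in vals):
            raise ValueError("table entries must be probabilities")
        if abs(sum(vals) - 1.0) > 1e-8:
            raise ValueError("table entries must sum to 1")

    @property
    def margin1(self) -> float:
        """P(mastery on the first replicate)."""
        return self.p11 + self.p10

    @property
    def margin2(self) -> float:
        return self.p11 + self.p01


def replication_table(p_hat_col: np.ndarray) -> ReplicationTable:
    """Replication table of one attribute from its marginal mastery column.

    ``p11 = mean(p^2)``, ``p10 = p01 = mean(p(1-p))``, ``p00 = mean((1-p)^2)``.
    """
    p = np.asarray(p_hat_col, dtype=float)
    if p.size == 0:
        raise ValueError("empty mastery column")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("mastery probabilities must be in [0, 1]")
    p11 = float(np.mean(p * p))
    p10 = float(np.mean(p * (1.0 - p)))
    p00 = float(np.mean((1.0 - p) ** 2))
    return ReplicationTable(p11=p11, p10=p10, p01=p10, p00=p00)


def _phi2(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """CDF of the bivariate standard normal, Phi2(h, k; rho), via Owen's T.

    Uses the identity
    ``Phi2 = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - delta`` with
    ``a_h = (k - rho h) / (h sqrt(1-rho^2))`` (and symmetrically),
    ``delta = 1/2`` iff ``h k < 0`` or (``h k = 0`` and ``h + k < 0``).
    Arguments at exactly zero are nudged to keep the ratios finite; the
    formula is continuous there.
    """
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    rho = np.clip(rho, -0.999999, 0.999999)
    d = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * d)
    ak = (h - rho * k) / (k * d)
    delta = np.where(h * k < 0, 0.5, 0.0)
    return 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - delta


def bivariate_normal_quadrant(tau1, tau2, rho):
    """Upper-quadrant probability ``P(X > tau1, Y > tau2)`` under BVN(rho).

    Vectorized over all arguments.
    """
    tau1, tau2, rho = np.broadcast_arrays(
        np.asarray(tau1, float), np.asarray(tau2, float), np.asarray(rho, float)
    )
    return _phi2(-tau1, -tau2, rho)


def _tetrachoric_arrays(
    p11: np.ndarray, tau1: np.ndarray, tau2: np.ndarray, iters: int = 60
) -> np.ndarray:
    """Vectorized bisection for the tetrachoric correlation.

    The quadrant probability is strictly increasing in rho at fixed
    thresholds, so plain bisection on (-0.999999, 0.999999) converges; 60
    halvings put the bracket far below any tolerance of interest.
    """
    lo = np.full_like(p11, -0.999999)
    hi = np.full_like(p11, 0.999999)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f = bivariate_normal_quadrant(tau1, tau2, mid) - p11
        lo = np.where(f < 0, mid, lo)
        hi = np.where(f < 0, hi, mid)
    return 0.5 * (lo + hi)


def tetrachoric(table: ReplicationTable, *, tol: float = 1e-8) -> float:
    """Tetrachoric correlation of a 2x2 probability table.

    Finds rho such that a bivariate standard normal with thresholds
    ``tau1 = ndtri(p00 + p01)``, ``tau2 = ndtri(p00 + p10)`` reproduces the
    ``p11`` quadrant probability, by bracketed root search.  Raises for
    degenerate margins (exactly 0 or 1), where the correlation is
    undefined.
    """
    m1, m2 = table.margin1, table.margin2
    if not (0.0 < m1 < 1.0 and 0.0 < m2 < 1.0):
        raise ValueError("degenerate table: a margin is exactly 0 or 1")
    tau1 = ndtri(1.0 - m1)
    tau2 = ndtri(1.0 - m2)

    def f(rho: float) -> float:
        return float(bivariate_normal_quadrant(tau1, tau2, rho)) - table.p11

    lo, hi = -0.999999, 0.999999
    if f(lo) > 0:
        return -1.0
    if f(hi) < 0:
        return 1.0
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200))


def reliability_from_posterior(posterior: np.ndarray, K: int | None = None) -> np.ndarray:
    """Attribute reliabilities (length K) from a state posterior.

    Degenerate margins (an attribute mastered by everyone or no one with
    certainty) are mapped to reliability 1 with a warning: such an
    attribute is perfectly determined.
    """
    p_hat = marginal_mastery(posterior, K)
    u = np.empty(p_hat.shape[1])
    for k in range(p_hat.shape[1]):
        table = replication_table(p_hat[:, k])
        try:
            u[k] = tetrachoric(table)
        except ValueError:
            warnings.warn(
                f"attribute {k}: degenerate replication table, reliability set to 1"
            )
            u[k] = 1.0
    return u


def attribute_reliability(
    responses: np.ndarray,
    bank_subset: Sequence[GDINAItem] | np.ndarray,
    prior: np.ndarray | None = None,
    *,
    K: int | None = None,
) -> np.ndarray:
    """Attribute reliabilities of an item set: posterior -> mastery -> tetrachoric."""
    w = posterior_over_states(responses, bank_subset, prior, K=K)
    return reliability_from_posterior(w, K)
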