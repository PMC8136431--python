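"""Evaluation of assembled pathways: reliability deviations, constraint
violations, expected scores, Cronbach's alpha and Rasch cross-validation.

The Rasch calibration here exists only to cross-validate the CD difficulty
index: a high-magnitude Pearson correlation between ``Diff_j`` (mean
correct-response probability over knowledge states; higher = easier) and
the Rasch difficulty ``b_j`` (higher = harder) shows the index orders
items the way a unidimensional IRT calibration would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .assembly import ConstraintCategory
from .gdina import ItemBank

__all__ = [
    "reliability_deviation",
    "count_violations",
    "expected_number_correct",
    "cronbach_alpha",
    "rasch_calibrate",
    "difficulty_correlation",
    "RaschResult",
]


def reliability_deviation(observed: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Signed deviation ``D_ik = R_ik - T_ik`` (elementwise)."""
    observed = np.asarray(observed, float)
    targets = np.broadcast_to(np.asarray(targets, float), observed.shape)
    return observed - targets


def count_violations(
    pathway_items: list[int],
    bank: ItemBank,
    constraints: list[ConstraintCategory],
) -> dict[str, int]:
    """Per-category violation indicators for one pathway, plus the total.

    A count category is violated when the number of pathway items bearing
    it falls below ``z_min`` (or above a finite ``z_max``); the enemy
    category is violated when any enemy pair co-occurs.  Returns a mapping
    ``"group:value" -> 0/1`` with an additional ``"total"`` entry equal to
    the sum.
    """
    feats = bank.features_array()
    idx = np.asarray(pathway_items, dtype=int)
    out: dict[str, int] = {}
    total = 0
    for cat in constraints:
        if cat.group == "enemy":
            groups = feats["enemy_group"][idx]
            groups = groups[groups >= 0]
            pairs = len(groups) - len(set(groups.tolist()))
            v = int(pairs > cat.z_max)
        else:
            if cat.group == "content":
                col = feats["content_category"]
            elif cat.group == "item_type":
                col = feats["item_type"]
            elif cat.group == "answer_key":
                col = feats["answer_key"]
            elif cat.group == "attribute":
                col = None
            else:
                raise ValueError(f"unknown constraint group {cat.group!r}")
            if col is None:
                count = int(bank.Q[idx, cat.value].sum())
            else:
                count = int((col[idx] == cat.value).sum())
            v = int(count < cat.z_min or count > cat.z_max)
        out[f"{cat.group}:{cat.value}"] = v
        total += v
    out["total"] = total
    return out


def expected_number_correct(
    pathway_items: list[int], bank: ItemBank, states: np.ndarray
) -> np.ndarray:
    """Per-examinee expected score: ``sum_j P_j(alpha_e)`` over the pathway items.

    Items may repeat (cross-panel aggregation keeps multiplicity).
    """
    states = np.atleast_2d(states)
    idx = states @ (1 << np.arange(bank.K))
    P = bank.state_probs[np.asarray(pathway_items, int)][:, idx]  # (J, N)
    return P.sum(axis=0)


def cronbach_alpha(responses: np.ndarray) -> float:
    """Cronbach's alpha: ``(J/(J-1)) * (1 - sum var_j / var(total))``.

    Sample variances (ddof=1).  Raises when the total score has zero
    variance, where the coefficient is undefined.
    """
    X = np.atleast_2d(np.asarray(responses, float))
    N, J = X.shape
    if J < 2 or N < 2:
        raise ValueError("alpha needs at least 2 items and 2 examinees")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(J / (J - 1) * (1.0 - item_var.sum() / total_var))


@dataclass
class RaschResult:
    """Rasch marginal-ML calibration output."""

    b: np.ndarray  # difficulties, aligned with kept item columns
    kept: np.ndarray  # indices of calibrated items (all-0/1 columns dropped)
    n_iter: int
    converged: bool


def rasch_calibrate(
    responses: np.ndarray,
    *,
    n_quadrature: int = 41,
    tol: float = 1e-6,
    max_iter: int = 500,
    center: bool = True,
) -> RaschResult:
    """Rasch item difficulties by marginal maximum likelihood (EM).

    Ability is integrated over a standard-normal prior on a fixed
    Gauss-Hermite grid.  Items answered all-correct or all-incorrect are
    dropped with a warning (their difficulty is unbounded).  With
    ``center=True`` the estimates are mean-centered, which leaves every
    use here (correlations, pathway orderings) unchanged.
    """
    X = np.atleast_2d(np.asarray(responses, float))
    pvals = X.mean(axis=0)
    kept = np.flatnonzero((pvals > 0) & (pvals < 1))
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} item(s) with all-0/all-1 responses"
        )
    X = X[:, kept]
    N, J = X.shape
    if J == 0:
        raise ValueError("no calibratable items")
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_quadrature)
    # probabilists' Hermite: nodes ~ N(0,1) support, weights need 1/sqrt(2*pi)
    wts = wts / np.sqrt(2.0 * np.pi)
    b = np.log((1.0 - pvals[kept]) / pvals[kept])  # classical logit start
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-(nodes[None, :] - b[:, None])))  # (J, Q)
        ll = X @ np.log(p) + (1.0 - X) @ np.log(1.0 - p)  # (N, Q)
        ll -= ll.max(axis=1, keepdims=True)
        post = np.exp(ll) * wts[None, :]
        post /= post.sum(axis=1, keepdims=True)
        nq = post.sum(axis=0)  # (Q,) expected examinees per node
        rj = X.sum(axis=0)  # (J,) observed correct counts
        # M-step: solve sum_q nq * sigma(theta_q - b_j) = r_j per item (Newton)
        b_new = b.copy()
        for _ in range(25):
            pj = 1.0 / (1.0 + np.exp(-(nodes[None, :] - b_new[:, None])))
            f = pj @ nq - rj
            fp = -(pj * (1.0 - pj)) @ nq
            step = f / fp
            b_new -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        delta = np.max(np.abs(b_new - b))
        b = b_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"Rasch MML did not converge in {it} iterations (delta={delta:.2e})")
    if center:
        b = b - b.mean()
    return RaschResult(b=b, kept=kept, n_iter=it, converged=converged)


def difficulty_correlation(diff: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of the CD difficulty index with Rasch ``b``.

    Returns ``(r, |r|)``; the expected sign is negative (high Diff = easy
    = low b).
    """
    diff = np.asarray(diff, float)
    b = np.asarray(b, float)
    if diff.shape != b.shape:
        raise ValueError("difficulty vectors must align")
    if diff.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a difficulty vector")
    r = float(pearsonr(diff, b).statistic)
    return r, abs(r)
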