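"""G-DINA response model, item-bank simulation and the CD item-difficulty index.

Conventions used throughout the package
---------------------------------------
* A *knowledge state* is a length-``K`` 0/1 vector of attribute masteries.
  The universe of states is enumerated by :func:`enumerate_states`; state
  ``c`` has attribute ``k`` mastered iff bit ``k`` of ``c`` is set
  (attribute 0 is the least-significant bit).
* A *Q-matrix* is a ``(J, K)`` 0/1 array; row ``j`` lists the attributes
  item ``j`` measures.  Rows are never all-zero.
* A *reduced pattern* of an item is the restriction of a knowledge state to
  the item's measured attributes, indexed as a bitmask over those
  attributes in increasing attribute order.
* A *response matrix* is an ``(N, J)`` 0/1 array, examinees by items.

The saturated identity-link G-DINA model assigns each reduced pattern its
own correct-response probability.  The probability table and the delta
(intercept / main-effect / interaction) parameterization are exact
bijections of one another (Moebius inversion over attribute subsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "enumerate_states",
    "nonzero_patterns",
    "GDINAItem",
    "ItemFeatures",
    "ItemBank",
    "DifficultyBins",
    "delta_from_prob_table",
    "prob_table_from_delta",
    "response_probability",
    "item_difficulty",
    "bin_difficulty",
    "simulate_knowledge_states",
    "simulate_q_matrix",
    "simulate_item_parameters",
    "simulate_item_features",
    "simulate_item_bank",
    "simulate_responses",
]

BIN_LABELS = ("hard", "medium", "easy")


def enumerate_states(K: int) -> np.ndarray:
    """All ``2**K`` knowledge states as a ``(2**K, K)`` 0/1 array.

    State ``c`` is the binary expansion of ``c`` with attribute 0 in the
    least-significant bit, so ``states[c, k] = (c >> k) & 1``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    c = np.arange(2**K)
    return ((c[:, None] >> np.arange(K)[None, :]) & 1).astype(np.int8)


def nonzero_patterns(K: int) -> np.ndarray:
    """The ``2**K - 1`` admissible Q-matrix row patterns (all-zero excluded)."""
    return enumerate_states(K)[1:]


def _popcount(n: np.ndarray) -> np.ndarray:
    return np.array([bin(int(v)).count("1") for v in np.atleast_1d(n)])


def delta_from_prob_table(prob_table: np.ndarray) -> np.ndarray:
    """Delta coefficients of the identity-link model from a probability table.

    ``prob_table[l]`` is P(X=1) for reduced pattern bitmask ``l``;
    ``delta[s]`` is the coefficient of the attribute subset with bitmask
    ``s`` (``delta[0]`` the intercept).  Since
    ``P(l) = sum_{s subset of l} delta[s]``, the inverse is the Moebius sum
    ``delta[s] = sum_{t subset of s} (-1)^{|s|-|t|} P(t)``.
    """
    pt = np.asarray(prob_table, dtype=float)
    L = pt.shape[0]
    if L & (L - 1):
        raise ValueError("prob_table length must be a power of 2")
    delta = np.zeros(L)
    for s in range(L):
        t = s
        acc = 0.0
        # iterate over subsets of s
        while True:
            sign = -1.0 if (bin(s ^ t).count("1") % 2) else 1.0
            acc += sign * pt[t]
            if t == 0:
                break
            t = (t - 1) & s
        delta[s] = acc
    return delta


def prob_table_from_delta(delta: np.ndarray) -> np.ndarray:
    """Inverse of :func:`delta_from_prob_table`: subset sums of delta."""
    d = np.asarray(delta, dtype=float)
    L = d.shape[0]
    if L & (L - 1):
        raise ValueError("delta length must be a power of 2")
    pt = np.zeros(L)
    for l in range(L):
        t = l
        acc = 0.0
        while True:
            acc += d[t]
            if t == 0:
                break
            t = (t - 1) & l
        pt[l] = acc
    return pt


@dataclass(frozen=True)
class ItemFeatures:
    """Non-statistical item features used by the assembly constraints.

    ``content_category`` and ``answer_key`` range over 1..4, ``item_type``
    over 1..2; ``enemy_group`` is shared by the members of an enemy pair
    (items that must not co-occur in a pathway) and ``None`` otherwise.
    """

    content_category: int
    item_type: int
    answer_key: int
    enemy_group: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.content_category <= 4:
            raise ValueError("content_category must be in 1..4")
        if not 1 <= self.item_type <= 2:
            raise ValueError("item_type must be in 1..2")
        if not 1 <= self.answer_key <= 4:
            raise ValueError("answer_key must be in 1..4")


@dataclass
class GDINAItem:
    """A saturated identity-link G-DINA item.

    Parameters
    ----------
    item_id : int
        Unique identifier within a bank.
    q_row : (K,) array of 0/1
        Attributes the item measures; at least one entry is 1.
    prob_table : (2**Kstar,) array
        Correct-response probability per reduced pattern, indexed by the
        bitmask over the measured attributes (in increasing attribute
        order).  Must be monotone: mastering a superset of measured
        attributes never lowers the probability.
    features : ItemFeatures, optional
    """

    item_id: int
    q_row: np.ndarray
    prob_table: np.ndarray
    features: ItemFeatures | None = None

    def __post_init__(self) -> None:
        self.q_row = np.asarray(self.q_row, dtype=np.int8)
        self.prob_table = np.asarray(self.prob_table, dtype=float)
        if not np.isin(self.q_row, (0, 1)).all() or self.q_row.sum() < 1:
            raise ValueError("q_row must be 0/1 with at least one 1")
        if self.prob_table.shape != (2 ** self.n_measured,):
            raise ValueError(
                f"prob_table must have length 2**{self.n_measured}"
            )
        if ((self.prob_table < 0) | (self.prob_table > 1)).any():
            raise ValueError("reduced-pattern probabilities must be in [0, 1]")
        L = self.prob_table.shape[0]
        for l in range(L):
            for k in range(self.n_measured):
                if not (l >> k) & 1:
                    if self.prob_table[l] > self.prob_table[l | (1 << k)] + 1e-12:
                        raise ValueError("prob_table violates monotonicity")

    @property
    def n_measured(self) -> int:
        """K*_j, the number of attributes the item measures."""
        return int(self.q_row.sum())

    @property
    def delta(self) -> np.ndarray:
        """Identity-link delta coefficients (intercept, main effects, interactions)."""
        return delta_from_prob_table(self.prob_table)

    @classmethod
    def from_delta(
        cls,
        item_id: int,
        q_row: np.ndarray,
        delta: np.ndarray,
        features: ItemFeatures | None = None,
    ) -> "GDINAItem":
        return cls(item_id, q_row, prob_table_from_delta(delta), features)

    def reduced_index(self, states: np.ndarray) -> np.ndarray:
        """Reduced-pattern bitmask of each row of ``states`` for this item."""
        states = np.atleast_2d(states)
        if states.shape[1] != self.q_row.shape[0]:
            raise ValueError("knowledge-state length does not match q_row")
        measured = np.flatnonzero(self.q_row)
        return states[:, measured] @ (1 << np.arange(measured.size))

    def state_probabilities(self, states: np.ndarray) -> np.ndarray:
        """P(X=1 | state) for each row of ``states``."""
        return self.prob_table[self.reduced_index(states)]


def response_probability(item: GDINAItem, ks: np.ndarray) -> float:
    """Correct-response probability of one knowledge state on one item.

    Depends only on the entries of ``ks`` at the item's measured
    attributes (the reduced pattern).
    """
    ks = np.asarray(ks)
    if ks.ndim != 1:
        raise ValueError("ks must be a single knowledge state")
    return float(item.state_probabilities(ks[None, :])[0])


def item_difficulty(item: GDINAItem, K: int | None = None) -> float:
    """CD item-difficulty index: mean correct-response probability over all states.

    ``Diff_j = 2^-K sum_c P_j(alpha_c)``.  Every reduced pattern of the
    item corresponds to the same number (``2^(K - K*_j)``) of full states,
    so the index equals the unweighted mean of the probability table.
    Lower values mean harder items.
    """
    if K is not None and K < item.n_measured:
        raise ValueError("K smaller than the number of measured attributes")
    return float(item.prob_table.mean())


@dataclass(frozen=True)
class DifficultyBins:
    """Three equal-width difficulty intervals over a bank's realized range.

    ``cut_points`` are the 4 boundaries from min to max Diff.  Intervals
    are half-open ``[lower, upper)`` except the topmost, which is closed.
    Higher Diff means easier, so the topmost interval is labelled *easy*
    and the lowest *hard*.
    """

    cut_points: np.ndarray
    labels: tuple[str, ...] = BIN_LABELS

    def assign(self, diff: np.ndarray) -> np.ndarray:
        """Bin index (0=hard, 1=medium, 2=easy) for each difficulty value."""
        diff = np.asarray(diff, dtype=float)
        idx = np.clip(np.searchsorted(self.cut_points, diff, side="right") - 1, 0, 2)
        return idx

    def label(self, diff: float) -> str:
        return self.labels[int(self.assign(np.array([diff]))[0])]

    def midpoint(self, bin_index: int) -> float:
        return float(0.5 * (self.cut_points[bin_index] + self.cut_points[bin_index + 1]))

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class ItemBank:
    """A calibrated item bank with cached per-state probabilities.

    Attributes
    ----------
    items : list of GDINAItem
    K : number of attributes
    Q : (J, K) int array — the Q-matrix
    state_probs : (J, 2**K) array — P_j(alpha_c) for every item and state
    difficulty : (J,) array — Diff_j per item
    """

    items: list[GDINAItem]
    K: int
    Q: np.ndarray = field(init=False)
    state_probs: np.ndarray = field(init=False)
    difficulty: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        states = enumerate_states(self.K)
        self.Q = np.array([it.q_row for it in self.items], dtype=np.int8)
        self.state_probs = np.array(
            [it.state_probabilities(states) for it in self.items]
        )
        self.difficulty = np.array([item_difficulty(it, self.K) for it in self.items])

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> np.ndarray:
        return np.array([it.item_id for it in self.items])

    def features_array(self) -> dict[str, np.ndarray]:
        """Feature columns as arrays (enemy_group -1 where absent)."""
        feats = [it.features for it in self.items]
        if any(f is None for f in feats):
            raise ValueError("bank items lack features")
        return {
            "content_category": np.array([f.content_category for f in feats]),
            "item_type": np.array([f.item_type for f in feats]),
            "answer_key": np.array([f.answer_key for f in feats]),
            "enemy_group": np.array(
                [-1 if f.enemy_group is None else f.enemy_group for f in feats]
            ),
        }


def bin_difficulty(bank: ItemBank) -> DifficultyBins:
    """Equal-width easy/medium/hard bins over the bank's realized Diff range.

    Raises for a degenerate bank whose difficulties are all equal.
    """
    lo, hi = float(bank.difficulty.min()), float(bank.difficulty.max())
    if hi - lo <= 0:
        raise ValueError("degenerate bank: all item difficulties are equal")
    return DifficultyBins(cut_points=np.linspace(lo, hi, 4))


# ---------------------------------------------------------------------------
# Simulation


def simulate_knowledge_states(
    N: int, K: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw ``N`` states uniformly (with replacement) from all ``2**K`` states.

    Returns an ``(N, K)`` 0/1 array.
    """
    rng = np.random.default_rng(rng)
    if N < 1 or K < 1:
        raise ValueError("N and K must be >= 1")
    idx = rng.integers(0, 2**K, size=N)
    return enumerate_states(K)[idx]


def simulate_q_matrix(
    J: int, K: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw ``J`` rows uniformly from the ``2**K - 1`` nonzero attribute patterns."""
    rng = np.random.default_rng(rng)
    if J < 1 or K < 1:
        raise ValueError("J and K must be >= 1")
    pats = nonzero_patterns(K)
    return pats[rng.integers(0, pats.shape[0], size=J)]


def simulate_item_parameters(
    q_row: np.ndarray,
    rng: np.random.Generator | int | None = None,
    *,
    guess_slip_max: float = 0.25,
) -> np.ndarray:
    """Monotone reduced-pattern probability table for one item.

    The endpoints follow the standard generating scheme
    ``P(0) ~ U(0, guess_slip_max)`` and ``1 - P(1) ~ U(0, guess_slip_max)``.
    The interior reduced-pattern probabilities are drawn i.i.d.
    ``U(P(0), P(1))`` and then sorted in increasing mastery-count order,
    which guarantees monotonicity (a superset pattern always has a higher
    mastery count here because sorting is applied across all interior
    cells jointly).
    """
    rng = np.random.default_rng(rng)
    q_row = np.asarray(q_row)
    kstar = int(q_row.sum())
    if kstar < 1:
        raise ValueError("q_row must measure at least one attribute")
    L = 2**kstar
    p0 = rng.uniform(0.0, guess_slip_max)
    p1 = 1.0 - rng.uniform(0.0, guess_slip_max)
    table = np.empty(L)
    order = np.argsort(_popcount(np.arange(L)), kind="stable")
    table[order[0]] = p0
    table[order[-1]] = p1
    if L > 2:
        table[order[1:-1]] = np.sort(rng.uniform(p0, p1, size=L - 2))
    return table


def simulate_item_features(
    J: int,
    rng: np.random.Generator | int | None = None,
    *,
    enemy_fraction: float = 0.02,
) -> list[ItemFeatures]:
    """Assign categorical features uniformly; ``enemy_fraction`` of items form pairs."""
    rng = np.random.default_rng(rng)
    content = rng.integers(1, 5, size=J)
    itype = rng.integers(1, 3, size=J)
    answer = rng.integers(1, 5, size=J)
    enemy = np.full(J, -1)
    n_pairs = int(J * enemy_fraction) // 2
    if n_pairs:
        chosen = rng.choice(J, size=2 * n_pairs, replace=False)
        for g in range(n_pairs):
            enemy[chosen[2 * g]] = g
            enemy[chosen[2 * g + 1]] = g
    return [
        ItemFeatures(
            int(content[j]),
            int(itype[j]),
            int(answer[j]),
            None if enemy[j] < 0 else int(enemy[j]),
        )
        for j in range(J)
    ]


def simulate_item_bank(
    J: int,
    K: int,
    rng: np.random.Generator | int | None = None,
    *,
    guess_slip_max: float = 0.25,
    enemy_fraction: float = 0.02,
) -> ItemBank:
    """Simulate a full bank: Q-matrix, G-DINA parameters and features."""
    rng = np.random.default_rng(rng)
    Q = simulate_q_matrix(J, K, rng)
    feats = simulate_item_features(J, rng, enemy_fraction=enemy_fraction)
    items = [
        GDINAItem(
            j,
            Q[j],
            simulate_item_parameters(Q[j], rng, guess_slip_max=guess_slip_max),
            feats[j],
        )
        for j in range(J)
    ]
    return ItemBank(items, K)


def simulate_responses(
    bank: ItemBank | Sequence[GDINAItem],
    states: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Bernoulli responses ``x_ej ~ Bern(P_j(alpha_e))``, independent across cells.

    Returns an ``(N, J)`` 0/1 array aligned with the bank's item order.
    """
    rng = np.random.default_rng(rng)
    states = np.atleast_2d(states)
    if isinstance(bank, ItemBank):
        if states.shape[1] != bank.K:
            raise ValueError("state length does not match bank K")
        idx = states @ (1 << np.arange(bank.K))
        P = bank.state_probs[:, idx].T  # (N, J)
    else:
        P = np.column_stack([it.state_probabilities(states) for it in bank])
    return (rng.random(P.shape) < P).astype(np.int8)
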