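"""NWADH item selection and top-down assembly of parallel CD-MST panels.

The normalized weighted absolute deviation heuristic (NWADH) assembles a
test greedily.  With ``J`` items selected and reliability targets ``T_k``,
each remaining candidate ``i`` is scored by the mean absolute deviation of
the candidate-extended test's attribute reliabilities from the targets,

    d_i = (1/K) sum_k | T_k - u_k^(J+1 with i) |,

normalized into a priority index ``e_i = 1 - d_i / sum_i d_i`` and, when
non-statistical constraints are active, augmented with a content term,

    e*_i = e_i + c_i / sum_i c_i,
    c_i  = sum_g [ v_ig W_g + (1 - v_ig) Wbar ],
    Wbar = W_max - (1/G) sum_g W_g,

where ``v_ig`` indicates that item ``i`` bears constraint category ``g``
and the category weights are ``W_g = 2`` while the category's minimum
count is unmet and ``1`` otherwise.  The candidate maximizing ``e*_i`` is
selected; selection repeats until the module sizes are filled.

Panels follow the three-stage multistage design: a shared medium-difficulty
first stage of single-attribute items, then easy / medium / hard primary
pathways whose stage-2 and stage-3 modules are restricted to the matching
difficulty bin of the bank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .gdina import BIN_LABELS, DifficultyBins, ItemBank, bin_difficulty, enumerate_states
from .reliability import _tetrachoric_arrays, update_posterior

__all__ = [
    "ConstraintCategory",
    "TestSpecification",
    "Pathway",
    "Panel",
    "AssemblyState",
    "AssemblyInfeasibleError",
    "NWADHAssembler",
    "default_constraints",
    "mean_absolute_deviation",
    "priority_index",
    "update_weights",
    "content_weight",
    "constrained_priority",
    "assemble_panels",
]


class AssemblyInfeasibleError(RuntimeError):
    """Raised when a selection step finds no eligible candidate."""


@dataclass(frozen=True)
class ConstraintCategory:
    """One category of a non-statistical constraint group.

    ``z_min``/``z_max`` bound the number of pathway items bearing the
    category.  ``group='enemy'`` is special: membership means the item has
    an enemy partner, the bound is on co-occurring enemy *pairs* (always
    ``z_max = 0``), and the category is enforced as a hard candidate
    filter rather than through the weighting.
    """

    group: str
    value: int
    z_min: int = 0
    z_max: float = math.inf

    def __post_init__(self) -> None:
        if self.z_min < 0 or self.z_max < self.z_min:
            raise ValueError("need 0 <= z_min <= z_max")


def default_constraints(K: int = 5) -> list[ConstraintCategory]:
    """The study's constraint table: 16 categories over 5 groups.

    Content balance (4 categories, min 4 each), item types (2, min 8),
    answer keys (4, min 4), enemy pairs (max 0), attribute coverage
    (K categories, min 3 each).
    """
    cats = [ConstraintCategory("content", v, z_min=4) for v in range(1, 5)]
    cats += [ConstraintCategory("item_type", v, z_min=8) for v in range(1, 3)]
    cats += [ConstraintCategory("answer_key", v, z_min=4) for v in range(1, 5)]
    cats += [ConstraintCategory("enemy", 0, z_min=0, z_max=0)]
    cats += [ConstraintCategory("attribute", k, z_min=3) for k in range(K)]
    return cats


_DEFAULT_PLAN = {
    "easy": ("medium", "easy", "easy"),
    "medium": ("medium", "medium", "medium"),
    "hard": ("medium", "hard", "hard"),
}


@dataclass
class TestSpecification:
    """Targets, stage structure and constraints of one assembly condition."""

    __test__ = False  # keep pytest from collecting this domain class

    K: int = 5
    targets: np.ndarray = None  # type: ignore[assignment]
    stage_sizes: tuple[int, int, int] = (5, 8, 8)
    n_panels: int = 5
    constraints: list[ConstraintCategory] = None  # type: ignore[assignment]
    difficulty_plan: dict[str, tuple[str, str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_PLAN)
    )
    pathway_order: tuple[str, ...] = ("hard", "medium", "easy")
    printed_content_weight: bool = False

    def __post_init__(self) -> None:
        if self.targets is None:
            self.targets = np.full(self.K, 0.90)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.shape != (self.K,):
            raise ValueError("targets must have length K")
        if ((self.targets <= 0) | (self.targets > 1)).any():
            raise ValueError("targets must lie in (0, 1]")
        if self.constraints is None:
            self.constraints = default_constraints(self.K)
        if any(s < 1 for s in self.stage_sizes):
            raise ValueError("stage sizes must be positive")
        # feasibility: within each mutually exclusive group the minimum counts
        # must fit in the test (attribute coverage can overlap, so skip it)
        total = sum(self.stage_sizes)
        by_group: dict[str, int] = {}
        for c in self.constraints:
            if c.group != "attribute":
                by_group[c.group] = by_group.get(c.group, 0) + c.z_min
        if by_group and max(by_group.values()) > total:
            raise ValueError("a constraint group's minimum counts exceed the test length")

    @property
    def test_length(self) -> int:
        return sum(self.stage_sizes)

    @classmethod
    def for_condition(
        cls, test_length: int, n_panels: int, K: int = 5, target: float = 0.90
    ) -> "TestSpecification":
        """Stage structure of the study design: (5,8,8) for 21, (5,10,10) for 25."""
        if test_length == 21:
            sizes = (5, 8, 8)
        elif test_length == 25:
            sizes = (5, 10, 10)
        else:
            per = (test_length - 5) // 2
            if 5 + 2 * per != test_length:
                raise ValueError("test_length must be 5 + 2*m")
            sizes = (5, per, per)
        return cls(
            K=K,
            targets=np.full(K, target),
            stage_sizes=sizes,
            n_panels=n_panels,
        )


@dataclass
class Pathway:
    """One route through a panel: the shared stage-1 module plus its own
    stage-2 and stage-3 modules."""

    label: str
    panel_id: int
    stage_modules: list[list[int]]

    @property
    def items(self) -> list[int]:
        return [j for stage in self.stage_modules for j in stage]


@dataclass
class Panel:
    """A pre-assembled test panel: shared first stage and three primary pathways."""

    panel_id: int
    stage1: list[int]
    pathways: dict[str, Pathway]

    def all_items(self) -> list[int]:
        out = list(self.stage1)
        for pw in self.pathways.values():
            for stage in pw.stage_modules[1:]:
                out.extend(stage)
        return out


@dataclass
class AssemblyState:
    """Mutable selection state of one pathway under construction."""

    selected: list[int]
    posterior: np.ndarray  # (N, 2**K), current calibration-sample posterior
    counts: np.ndarray  # per constraint category, over `selected`


# ---------------------------------------------------------------------------
# NWADH primitive operations (array/dict level)


def mean_absolute_deviation(u: np.ndarray, targets: np.ndarray) -> float:
    """``d = (1/K) sum_k |T_k - u_k|``."""
    u = np.asarray(u, float)
    targets = np.asarray(targets, float)
    if u.shape != targets.shape:
        raise ValueError("length mismatch between reliabilities and targets")
    return float(np.mean(np.abs(targets - u)))


def priority_index(devs: dict[int, float]) -> dict[int, float]:
    """``e_i = 1 - d_i / sum d`` over the candidate pool (all zero if sum d = 0)."""
    if not devs:
        raise ValueError("empty candidate pool")
    total = sum(devs.values())
    if total <= 0:
        return {i: 0.0 for i in devs}
    return {i: 1.0 - d / total for i, d in devs.items()}


def update_weights(
    counts: np.ndarray, z_min: np.ndarray, z_max: np.ndarray
) -> np.ndarray:
    """Constraint weights: 2 while a category's minimum is unmet, else 1.

    (A category at or above its maximum also has weight 1; between the
    bounds the weight is the satisfied baseline 1.)
    """
    counts = np.asarray(counts)
    w = np.where(counts < np.asarray(z_min), 2.0, 1.0)
    return np.where(counts >= np.asarray(z_max), 1.0, w)


def content_weight(
    v_row: np.ndarray, weights: np.ndarray, *, printed_variant: bool = False
) -> float:
    """Content-constraint weight ``c_i`` of one candidate.

    Default reading: ``c_i = sum_g [v_ig W_g + (1 - v_ig) Wbar]`` with the
    scalar mean-gap weight ``Wbar = max(W) - mean(W)``.  The
    ``printed_variant`` replaces ``(1 - v_ig)`` by ``(1 + v_ig)``.
    """
    v = np.asarray(v_row, float)
    w = np.asarray(weights, float)
    wbar = w.max() - w.mean()
    comp = (1.0 + v) if printed_variant else (1.0 - v)
    return float(np.sum(v * w + comp * wbar))


def constrained_priority(e: dict[int, float], c: dict[int, float]) -> dict[int, float]:
    """``e*_i = e_i + c_i / sum c`` (content term 0 when all ``c`` vanish)."""
    if set(e) != set(c):
        raise ValueError("e and c must cover the same candidates")
    total = sum(c.values())
    if total <= 0:
        return dict(e)
    return {i: e[i] + c[i] / total for i in e}


# ---------------------------------------------------------------------------
# Engine


class NWADHAssembler:
    """Greedy NWADH assembly of parallel panels from a calibrated bank.

    Parameters
    ----------
    bank : ItemBank
    spec : TestSpecification
    calib_responses : (N, J) 0/1 array
        Calibration-sample responses to every bank item; candidate
        reliabilities are evaluated on this fixed sample.
    bins : DifficultyBins, optional
        Defaults to :func:`cdmst.gdina.bin_difficulty` of the bank.

    The engine is fully deterministic: greedy argmax with ties broken by
    smallest distance of Diff to the active bin midpoint, then lowest
    item id.
    """

    def __init__(
        self,
        bank: ItemBank,
        spec: TestSpecification,
        calib_responses: np.ndarray,
        bins: DifficultyBins | None = None,
    ) -> None:
        if bank.K != spec.K:
            raise ValueError("bank and specification disagree on K")
        self.bank = bank
        self.spec = spec
        self.X = np.asarray(calib_responses)
        if self.X.shape[1] != len(bank):
            raise ValueError("calibration responses do not cover the bank")
        self.N = self.X.shape[0]
        self.K = bank.K
        self.A = enumerate_states(self.K).astype(float)  # (S, K)
        self.bins = bins if bins is not None else bin_difficulty(bank)
        self.bin_idx = self.bins.assign(bank.difficulty)
        P = bank.state_probs  # (J, S)
        self.M0 = np.ascontiguousarray((1.0 - P).T)  # (S, J)
        self.M1 = np.ascontiguousarray((2.0 * P - 1.0).T)
        feats = bank.features_array()
        self.enemy = feats["enemy_group"]
        self.single_attr = bank.Q.sum(axis=1) == 1
        # category indicator matrix V (J, G), aligned with spec.constraints
        cols = []
        for cat in spec.constraints:
            if cat.group == "content":
                cols.append(feats["content_category"] == cat.value)
            elif cat.group == "item_type":
                cols.append(feats["item_type"] == cat.value)
            elif cat.group == "answer_key":
                cols.append(feats["answer_key"] == cat.value)
            elif cat.group == "attribute":
                cols.append(bank.Q[:, cat.value] == 1)
            elif cat.group == "enemy":
                cols.append(self.enemy >= 0)
            else:
                raise ValueError(f"unknown constraint group {cat.group!r}")
        self.V = np.column_stack(cols).astype(float)
        self.z_min = np.array([c.z_min for c in spec.constraints], float)
        self.z_max = np.array([c.z_max for c in spec.constraints], float)

    # -- candidate scoring ---------------------------------------------------

    def candidate_reliabilities(
        self, posterior: np.ndarray, candidates: np.ndarray
    ) -> np.ndarray:
        """Attribute reliabilities ``u_k^(J+1)`` of every candidate extension.

        Implements the single-item incremental posterior update in closed
        form: with current posterior ``w`` and candidate state
        probabilities ``p``, the updated (unnormalized) posterior is
        ``w * [(1-p) + x (2p-1)]``, so marginal masteries for all
        candidates reduce to two matrix products per attribute.
        Returns a ``(C, K)`` array.
        """
        w = posterior
        C = candidates.size
        Xc = self.X[:, candidates].astype(float)  # (N, C)
        M0 = self.M0[:, candidates]
        M1 = self.M1[:, candidates]
        # stacked multipliers: plain posterior + per-attribute masked posterior
        stack = np.empty((self.K + 1, self.N, w.shape[1]))
        stack[0] = w
        for k in range(self.K):
            stack[k + 1] = w * self.A[:, k]
        flat = stack.reshape((self.K + 1) * self.N, w.shape[1])
        R0 = (flat @ M0).reshape(self.K + 1, self.N, C)
        R1 = (flat @ M1).reshape(self.K + 1, self.N, C)
        den = R0[0] + Xc * R1[0]
        p11 = np.empty((C, self.K))
        p10 = np.empty((C, self.K))
        for k in range(self.K):
            ph = (R0[k + 1] + Xc * R1[k + 1]) / den
            p11[:, k] = np.mean(ph * ph, axis=0)
            p10[:, k] = np.mean(ph * (1.0 - ph), axis=0)
        margin = np.clip(p11 + p10, 1e-12, 1.0 - 1e-12)
        tau = ndtri(1.0 - margin)
        return _tetrachoric_arrays(p11, tau, tau)

    def candidate_deviations(
        self, state: AssemblyState, candidates: np.ndarray
    ) -> np.ndarray:
        """``d_i^(J+1)`` for each candidate (aligned with ``candidates``)."""
        if candidates.size == 0:
            raise AssemblyInfeasibleError("empty eligible pool")
        u = self.candidate_reliabilities(state.posterior, candidates)
        return np.mean(np.abs(self.spec.targets[None, :] - u), axis=1)

    def score_candidates(
        self, state: AssemblyState, candidates: np.ndarray
    ) -> np.ndarray:
        """Constrained priority ``e*_i`` for each candidate."""
        d = self.candidate_deviations(state, candidates)
        total_d = d.sum()
        e = np.zeros_like(d) if total_d <= 0 else 1.0 - d / total_d
        W = update_weights(state.counts, self.z_min, self.z_max)
        wbar = W.max() - W.mean()
        Vc = self.V[candidates]
        comp = (1.0 + Vc) if self.spec.printed_content_weight else (1.0 - Vc)
        c = Vc @ W + comp.sum(axis=1) * wbar
        total_c = c.sum()
        if total_c > 0:
            e = e + c / total_c
        return e

    def _eligible(
        self,
        used: np.ndarray,
        pathway_items: list[int],
        bin_index: int | None,
        *,
        single_attribute_of: int | None = None,
    ) -> np.ndarray:
        mask = ~used
        if bin_index is not None:
            mask &= self.bin_idx == bin_index
        if single_attribute_of is not None:
            mask &= self.single_attr & (self.bank.Q[:, single_attribute_of] == 1)
        blocked = {
            int(self.enemy[j]) for j in pathway_items if self.enemy[j] >= 0
        }
        if blocked:
            mask &= ~np.isin(self.enemy, list(blocked))
        return np.flatnonzero(mask)

    def select_next_item(
        self,
        state: AssemblyState,
        candidates: np.ndarray,
        bin_index: int | None,
    ) -> int:
        """Argmax of ``e*`` with the deterministic tie-break; updates ``state``."""
        if candidates.size == 0:
            raise AssemblyInfeasibleError("empty eligible pool")
        scores = self.score_candidates(state, candidates)
        best = scores.max()
        near = candidates[scores >= best - 1e-12]
        if near.size > 1:
            mid = (
                self.bins.midpoint(bin_index)
                if bin_index is not None
                else float(self.bins.cut_points[[0, -1]].mean())
            )
            gap = np.abs(self.bank.difficulty[near] - mid)
            order = np.lexsort((near, gap))
            choice = int(near[order[0]])
        else:
            choice = int(near[0])
        state.selected.append(choice)
        state.posterior = update_posterior(
            state.posterior, self.X[:, choice], self.bank.state_probs[choice]
        )
        state.counts = state.counts + self.V[choice]
        return choice

    # -- module / pathway / panel assembly ------------------------------------

    def _fresh_state(self) -> AssemblyState:
        S = 2**self.K
        w = np.full((self.N, S), 1.0 / S)
        return AssemblyState(selected=[], posterior=w, counts=np.zeros(self.V.shape[1]))

    def _seeded_state(self, items: list[int]) -> AssemblyState:
        state = self._fresh_state()
        for j in items:
            state.selected.append(j)
            state.posterior = update_posterior(
                state.posterior, self.X[:, j], self.bank.state_probs[j]
            )
            state.counts = state.counts + self.V[j]
        return state

    def assemble_first_stage(self, used: np.ndarray) -> list[int]:
        """Shared stage-1 module: one single-attribute medium item per attribute."""
        stage1_bin = self.bins.index_of(self.spec.difficulty_plan["medium"][0])
        if self.spec.stage_sizes[0] != self.K:
            raise AssemblyInfeasibleError(
                "first-stage size must equal K (one single-attribute item per attribute)"
            )
        state = self._fresh_state()
        for k in range(self.K):
            cand = self._eligible(
                used, state.selected, stage1_bin, single_attribute_of=k
            )
            if cand.size == 0:
                raise AssemblyInfeasibleError(
                    f"stage 1: no unused single-attribute medium item measures attribute {k}"
                )
            self.select_next_item(state, cand, stage1_bin)
        return list(state.selected)

    def assemble_pathway(
        self,
        label: str,
        stage1: list[int],
        used_in_panel: np.ndarray,
        panel_id: int,
    ) -> Pathway:
        """Fill one pathway's stage-2/3 modules by greedy NWADH selection."""
        plan = self.spec.difficulty_plan[label]
        state = self._seeded_state(stage1)
        modules: list[list[int]] = [list(stage1)]
        for stage in (1, 2):
            bin_index = self.bins.index_of(plan[stage])
            module: list[int] = []
            for _ in range(self.spec.stage_sizes[stage]):
                cand = self._eligible(used_in_panel, state.selected, bin_index)
                if cand.size == 0:
                    raise AssemblyInfeasibleError(
                        f"pathway {label!r} stage {stage + 1}: "
                        f"difficulty-bin/enemy filters emptied the pool"
                    )
                j = self.select_next_item(state, cand, bin_index)
                used_in_panel[j] = True
                module.append(j)
            modules.append(module)
        return Pathway(label=label, panel_id=panel_id, stage_modules=modules)

    def assemble_panels(self) -> list[Panel]:
        """Assemble ``n_panels`` panels.

        Stage-1 modules are item-exclusive across panels (so successive
        panels diverge); stage-2/3 items are exclusive within a panel.
        Bank sizes in the study design cannot support full cross-panel
        exclusivity because the outer difficulty bins are small.
        """
        used_stage1 = np.zeros(len(self.bank), dtype=bool)
        panels = []
        for pid in range(self.spec.n_panels):
            stage1 = self.assemble_first_stage(used_stage1)
            for j in stage1:
                used_stage1[j] = True
            used_in_panel = np.zeros(len(self.bank), dtype=bool)
            used_in_panel[stage1] = True
            pathways = {}
            for label in self.spec.pathway_order:
                pathways[label] = self.assemble_pathway(
                    label, stage1, used_in_panel, pid
                )
            panels.append(Panel(panel_id=pid, stage1=list(stage1), pathways=pathways))
        return panels


def assemble_panels(
    bank: ItemBank,
    spec: TestSpecification,
    calib_responses: np.ndarray,
    bins: DifficultyBins | None = None,
) -> list[Panel]:
    """Convenience wrapper: build the engine and assemble all panels."""
    return NWADHAssembler(bank, spec, calib_responses, bins=bins).assemble_panels()
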