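"""Simulation-study orchestration: the condition grid, replications and reports.

One replication of one condition regenerates everything from sub-seeded
random streams: a 1,000-item bank, a calibration sample whose responses
drive NWADH selection, the assembled panels, and a fresh evaluation
sample on which reliability deviations, constraint violations, expected
scores, Cronbach's alpha and the Rasch cross-calibration are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import (
    AssemblyInfeasibleError,
    ConstraintCategory,
    NWADHAssembler,
    Panel,
    TestSpecification,
)
from .evaluation import (
    count_violations,
    cronbach_alpha,
    expected_number_correct,
    rasch_calibrate,
    reliability_deviation,
)
from .gdina import (
    ItemBank,
    bin_difficulty,
    simulate_item_bank,
    simulate_knowledge_states,
    simulate_responses,
)
from .reliability import attribute_reliability

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "ReplicationRecord",
    "StudyResult",
    "run_replication",
    "run_study",
    "generate_fixture",
    "STUDY_CONDITIONS",
]

STUDY_CONDITIONS: tuple[tuple[int, int], ...] = ((21, 5), (21, 10), (25, 5), (25, 10))


@dataclass
class StudyConfig:
    """Design of the replication study.

    ``conditions`` are (test_length, n_panels) pairs; ``replications`` may
    be a single count or a per-condition mapping.  The full design uses
    100 replications; the default is scaled to 10 for desk-scale runs.
    """

    K: int = 5
    bank_size: int = 1000
    n_examinees: int = 1000
    conditions: tuple[tuple[int, int], ...] = STUDY_CONDITIONS
    replications: int | dict[tuple[int, int], int] = 10
    target: float = 0.90
    master_seed: int = 12345
    enemy_fraction: float = 0.02

    def replications_for(self, condition: tuple[int, int]) -> int:
        if isinstance(self.replications, dict):
            return int(self.replications[condition])
        return int(self.replications)


@dataclass
class ReplicationRecord:
    """All evaluation output of one (condition, replication) cell."""

    condition: tuple[int, int]
    replication: int
    panels: list[Panel]
    reliabilities: dict[str, np.ndarray]  # label -> (n_panels, K) observed R
    deviations: dict[str, np.ndarray]  # label -> (n_panels, K) D = R - T
    violations: pd.DataFrame  # columns: panel, pathway, category, violated
    pathway_stats: pd.DataFrame  # per-pathway summary statistics
    failed: str | None = None


def _seed_rng(master_seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, *path]))


def run_replication(
    config: StudyConfig, condition: tuple[int, int], replication: int
) -> ReplicationRecord:
    """Execute one replication: generate, assemble, evaluate."""
    ci = STUDY_CONDITIONS.index(condition) if condition in STUDY_CONDITIONS else 99
    bank_rng = _seed_rng(config.master_seed, ci, replication, 0)
    calib_rng = _seed_rng(config.master_seed, ci, replication, 1)
    eval_rng = _seed_rng(config.master_seed, ci, replication, 2)

    test_length, n_panels = condition
    bank = simulate_item_bank(
        config.bank_size, config.K, bank_rng, enemy_fraction=config.enemy_fraction
    )
    calib_states = simulate_knowledge_states(config.n_examinees, config.K, calib_rng)
    calib_X = simulate_responses(bank, calib_states, calib_rng)
    spec = TestSpecification.for_condition(
        test_length, n_panels, K=config.K, target=config.target
    )
    engine = NWADHAssembler(bank, spec, calib_X)
    panels = engine.assemble_panels()

    eval_states = simulate_knowledge_states(config.n_examinees, config.K, eval_rng)
    eval_X = simulate_responses(bank, eval_states, eval_rng)
    record = evaluate_panels(bank, spec, panels, eval_states, eval_X)
    record.condition = condition
    record.replication = replication
    return record


def evaluate_panels(
    bank: ItemBank,
    spec: TestSpecification,
    panels: list[Panel],
    eval_states: np.ndarray,
    eval_X: np.ndarray,
) -> ReplicationRecord:
    """Full evaluation of an assembled panel set on an evaluation sample."""
    labels = list(spec.pathway_order)
    # Rasch calibration once, on the union of distinct items in the panels
    union = sorted({j for p in panels for j in p.all_items()})
    rasch = rasch_calibrate(eval_X[:, union])
    b_by_item = dict(zip(np.asarray(union)[rasch.kept].tolist(), rasch.b.tolist()))

    reliabilities: dict[str, np.ndarray] = {}
    deviations: dict[str, np.ndarray] = {}
    viol_rows = []
    stat_rows = []
    for label in labels:
        R = np.empty((len(panels), spec.K))
        concat_items: list[int] = []
        per_panel_alpha = []
        per_panel_score_mean = []
        for p_i, panel in enumerate(panels):
            items = panel.pathways[label].items
            concat_items.extend(items)
            R[p_i] = attribute_reliability(
                eval_X[:, items], bank.state_probs[items], K=spec.K
            )
            vio = count_violations(items, bank, spec.constraints)
            for key, v in vio.items():
                if key != "total":
                    viol_rows.append(
                        {
                            "panel": panel.panel_id,
                            "pathway": label,
                            "category": key,
                            "violated": v,
                        }
                    )
            per_panel_alpha.append(cronbach_alpha(eval_X[:, items]))
            per_panel_score_mean.append(
                float(expected_number_correct(items, bank, eval_states).mean())
            )
        reliabilities[label] = R
        deviations[label] = reliability_deviation(R, spec.targets[None, :])

        diffs = bank.difficulty[concat_items]
        b = np.array([b_by_item[j] for j in concat_items if j in b_by_item])
        scores = expected_number_correct(concat_items, bank, eval_states)
        stat_rows.append(
            {
                "pathway": label,
                "n_item_slots": len(concat_items),
                "cd_diff_mean": float(diffs.mean()),
                "cd_diff_sd": float(diffs.std(ddof=1)),
                "rasch_mean": float(b.mean()),
                "rasch_sd": float(b.std(ddof=1)),
                "score_mean": float(scores.mean()),
                "score_sd": float(scores.std(ddof=1)),
                "alpha": cronbach_alpha(eval_X[:, concat_items]),
                "alpha_per_panel_mean": float(np.mean(per_panel_alpha)),
                "score_per_panel_mean": float(np.mean(per_panel_score_mean)),
            }
        )
    return ReplicationRecord(
        condition=(spec.test_length, spec.n_panels),
        replication=-1,
        panels=panels,
        reliabilities=reliabilities,
        deviations=deviations,
        violations=pd.DataFrame(viol_rows),
        pathway_stats=pd.DataFrame(stat_rows),
    )


@dataclass
class StudyResult:
    """Records of every (condition, replication) cell plus aggregation helpers."""

    config: StudyConfig
    records: list[ReplicationRecord] = field(default_factory=list)

    def _ok(self) -> list[ReplicationRecord]:
        return [r for r in self.records if r.failed is None]

    def max_abs_deviation(self, condition: tuple[int, int] | None = None) -> float:
        """Largest |D_ik| over panels, pathways, attributes and replications."""
        worst = 0.0
        for r in self._ok():
            if condition is not None and r.condition != condition:
                continue
            for D in r.deviations.values():
                worst = max(worst, float(np.abs(D).max()))
        return worst

    def violation_rate(self) -> float:
        """Violated pathway-level constraint instances as a percentage.

        Every evaluated (panel, pathway, category, replication) instance
        counts in the denominator.
        """
        num = 0
        den = 0
        for r in self._ok():
            num += int(r.violations["violated"].sum())
            den += len(r.violations)
        return 100.0 * num / den if den else 0.0

    def min_alpha(self) -> float:
        """Minimum over (condition, pathway) of the replication-mean cross-panel alpha."""
        frame = self.pathway_table()
        by = frame.groupby(["test_length", "n_panels", "pathway"])["alpha"].mean()
        return float(by.min())

    def pathway_table(self) -> pd.DataFrame:
        rows = []
        for r in self._ok():
            t = r.pathway_stats.copy()
            t.insert(0, "replication", r.replication)
            t.insert(0, "n_panels", r.condition[1])
            t.insert(0, "test_length", r.condition[0])
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def deviation_table(self) -> pd.DataFrame:
        rows = []
        for r in self._ok():
            for label, D in r.deviations.items():
                for p_i in range(D.shape[0]):
                    for k in range(D.shape[1]):
                        rows.append(
                            {
                                "test_length": r.condition[0],
                                "n_panels": r.condition[1],
                                "replication": r.replication,
                                "pathway": label,
                                "panel": p_i,
                                "attribute": k,
                                "observed": r.reliabilities[label][p_i, k],
                                "target": self.config.target,
                                "deviation": D[p_i, k],
                            }
                        )
        return pd.DataFrame(rows)

    def violation_table(self) -> pd.DataFrame:
        rows = []
        for r in self._ok():
            t = r.violations.copy()
            t.insert(0, "replication", r.replication)
            t.insert(0, "n_panels", r.condition[1])
            t.insert(0, "test_length", r.condition[0])
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def aggregate(self) -> pd.DataFrame:
        """Condition x pathway means of the per-pathway summary statistics."""
        t = self.pathway_table()
        return (
            t.groupby(["test_length", "n_panels", "pathway"])
            .mean(numeric_only=True)
            .drop(columns=["replication"])
            .reset_index()
        )


def run_study(config: StudyConfig, out_dir=None) -> StudyResult:
    """Run the full condition grid; per-replication failures are recorded,
    not fatal.  Deterministic under ``config.master_seed``."""
    result = StudyResult(config=config)
    for condition in config.conditions:
        for rep in range(config.replications_for(condition)):
            logger.info("condition %s replication %d", condition, rep)
            try:
                record = run_replication(config, condition, rep)
            except AssemblyInfeasibleError as err:
                logger.warning("replication failed: %s", err)
                record = ReplicationRecord(
                    condition=condition,
                    replication=rep,
                    panels=[],
                    reliabilities={},
                    deviations={},
                    violations=pd.DataFrame(),
                    pathway_stats=pd.DataFrame(),
                    failed=str(err),
                )
            result.records.append(record)
    if out_dir is not None:
        from . import io as _io

        _io.write_study_reports(result, out_dir)
    return result


def generate_fixture(seed: int, scale: str = "tiny") -> dict:
    """Self-contained miniature (or full-design) inputs for tests and demos.

    ``tiny``: K=3, 60 items, 100 examinees, one panel with 3+3+3 stages
    and scaled-down constraint minimums.  ``full``: the full study
    configuration (1,000 items, 1,000 examinees, K=5).
    """
    if scale == "tiny":
        K, J, N = 3, 60, 100
        rng = _seed_rng(seed, 0)
        bank = simulate_item_bank(J, K, rng, enemy_fraction=0.05)
        states = simulate_knowledge_states(N, K, _seed_rng(seed, 1))
        responses = simulate_responses(bank, states, _seed_rng(seed, 2))
        constraints = (
            [ConstraintCategory("content", v, z_min=1) for v in range(1, 5)]
            + [ConstraintCategory("item_type", v, z_min=2) for v in range(1, 3)]
            + [ConstraintCategory("answer_key", v, z_min=1) for v in range(1, 5)]
            + [ConstraintCategory("enemy", 0, z_min=0, z_max=0)]
            + [ConstraintCategory("attribute", k, z_min=1) for k in range(K)]
        )
        spec = TestSpecification(
            K=K,
            targets=np.full(K, 0.90),
            stage_sizes=(3, 3, 3),
            n_panels=1,
            constraints=constraints,
        )
    elif scale == "full":
        K, J, N = 5, 1000, 1000
        rng = _seed_rng(seed, 0)
        bank = simulate_item_bank(J, K, rng)
        states = simulate_knowledge_states(N, K, _seed_rng(seed, 1))
        responses = simulate_responses(bank, states, _seed_rng(seed, 2))
        spec = TestSpecification.for_condition(21, 5, K=K)
    else:
        raise ValueError("scale must be 'tiny' or 'full'")
    return {
        "bank": bank,
        "spec": spec,
        "states": states,
        "responses": responses,
        "bins": bin_difficulty(bank),
    }
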