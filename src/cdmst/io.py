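"""On-disk interchange: item banks and responses as CSV, panels and test
specifications as JSON/YAML, study reports as CSV."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assembly import ConstraintCategory, Panel, Pathway, TestSpecification
from .gdina import GDINAItem, ItemBank, ItemFeatures

__all__ = [
    "bank_to_csv",
    "bank_from_csv",
    "qmatrix_to_csv",
    "qmatrix_from_csv",
    "responses_to_csv",
    "responses_from_csv",
    "panels_to_json",
    "panels_from_json",
    "spec_to_yaml",
    "spec_from_yaml",
    "write_study_reports",
]


def bank_to_csv(bank: ItemBank, path) -> None:
    """One row per item; the reduced-pattern probability table is a JSON cell."""
    rows = []
    for it in bank.items:
        f = it.features
        row = {"item_id": it.item_id}
        for k in range(bank.K):
            row[f"q{k + 1}"] = int(it.q_row[k])
        row["prob_table"] = json.dumps([round(float(p), 12) for p in it.prob_table])
        row["diff"] = float(it.prob_table.mean())
        row["content_category"] = f.content_category if f else ""
        row["item_type"] = f.item_type if f else ""
        row["answer_key"] = f.answer_key if f else ""
        row["enemy_group"] = "" if (f is None or f.enemy_group is None) else f.enemy_group
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def bank_from_csv(path) -> ItemBank:
    df = pd.read_csv(path)
    qcols = sorted(
        (c for c in df.columns if c.startswith("q") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    K = len(qcols)
    items = []
    for _, row in df.iterrows():
        feats = None
        if not pd.isna(row.get("content_category")):
            eg = row.get("enemy_group")
            feats = ItemFeatures(
                int(row["content_category"]),
                int(row["item_type"]),
                int(row["answer_key"]),
                None if (eg is None or (isinstance(eg, float) and math.isnan(eg))) else int(eg),
            )
        items.append(
            GDINAItem(
                int(row["item_id"]),
                np.array([int(row[c]) for c in qcols]),
                np.array(json.loads(row["prob_table"])),
                feats,
            )
        )
    return ItemBank(items, K)


def qmatrix_to_csv(Q: np.ndarray, path) -> None:
    Q = np.atleast_2d(Q)
    pd.DataFrame(Q, columns=[f"q{k + 1}" for k in range(Q.shape[1])]).to_csv(
        path, index=False
    )


def qmatrix_from_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.int8)


def responses_to_csv(X: np.ndarray, item_ids, path) -> None:
    pd.DataFrame(np.atleast_2d(X), columns=[str(i) for i in item_ids]).to_csv(
        path, index=False
    )


def responses_from_csv(path) -> tuple[np.ndarray, list[int]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=np.int8), [int(c) for c in df.columns]


def panels_to_json(panels: list[Panel], path=None) -> str:
    payload = [
        {
            "panel_id": p.panel_id,
            "stage1": list(map(int, p.stage1)),
            "pathways": {
                label: {
                    f"stage{s + 1}": list(map(int, mod))
                    for s, mod in enumerate(pw.stage_modules)
                    if s > 0
                }
                for label, pw in p.pathways.items()
            },
        }
        for p in panels
    ]
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def panels_from_json(path) -> list[Panel]:
    payload = json.loads(Path(path).read_text())
    panels = []
    for entry in payload:
        stage1 = list(entry["stage1"])
        pathways = {}
        for label, mods in entry["pathways"].items():
            stages = [stage1] + [mods[k] for k in sorted(mods)]
            pathways[label] = Pathway(
                label=label, panel_id=entry["panel_id"], stage_modules=stages
            )
        panels.append(
            Panel(panel_id=entry["panel_id"], stage1=stage1, pathways=pathways)
        )
    return panels


def spec_to_yaml(spec: TestSpecification, path=None) -> str:
    payload = {
        "K": spec.K,
        "targets": [float(t) for t in spec.targets],
        "stage_sizes": list(spec.stage_sizes),
        "n_panels": spec.n_panels,
        "pathway_order": list(spec.pathway_order),
        "difficulty_plan": {k: list(v) for k, v in spec.difficulty_plan.items()},
        "printed_content_weight": spec.printed_content_weight,
        "constraints": [
            {
                "group": c.group,
                "value": c.value,
                "z_min": c.z_min,
                "z_max": None if math.isinf(c.z_max) else c.z_max,
            }
            for c in spec.constraints
        ],
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def spec_from_yaml(path) -> TestSpecification:
    payload = yaml.safe_load(Path(path).read_text())
    constraints = [
        ConstraintCategory(
            c["group"],
            c["value"],
            z_min=c.get("z_min", 0),
            z_max=math.inf if c.get("z_max") is None else c["z_max"],
        )
        for c in payload["constraints"]
    ]
    return TestSpecification(
        K=payload["K"],
        targets=np.array(payload["targets"]),
        stage_sizes=tuple(payload["stage_sizes"]),
        n_panels=payload["n_panels"],
        constraints=constraints,
        difficulty_plan={k: tuple(v) for k, v in payload["difficulty_plan"].items()},
        pathway_order=tuple(payload["pathway_order"]),
        printed_content_weight=payload.get("printed_content_weight", False),
    )


def write_study_reports(result, out_dir) -> None:
    """Persist the per-replication tables and the condition aggregates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.deviation_table().to_csv(out / "reliability_deviations.csv", index=False)
    result.violation_table().to_csv(out / "constraint_violations.csv", index=False)
    result.pathway_table().to_csv(out / "pathway_statistics.csv", index=False)
    result.aggregate().to_csv(out / "condition_aggregates.csv", index=False)
    for r in result.records:
        if r.failed is None:
            name = f"panels_L{r.condition[0]}_P{r.condition[1]}_rep{r.replication}.json"
            panels_to_json(r.panels, out / name)
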