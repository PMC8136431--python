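"""NWADH selection-engine and panel-assembly tests."""

import numpy as np
import pytest

from cdmst.assembly import (
    AssemblyInfeasibleError,
    ConstraintCategory,
    NWADHAssembler,
    TestSpecification,
    constrained_priority,
    content_weight,
    default_constraints,
    mean_absolute_deviation,
    priority_index,
    update_weights,
)
from cdmst.gdina import (
    DifficultyBins,
    GDINAItem,
    ItemBank,
    ItemFeatures,
    simulate_item_bank,
    simulate_knowledge_states,
    simulate_responses,
)
from cdmst.reliability import attribute_reliability, reliability_from_posterior


def small_spec(K=3, n_panels=1):
    constraints = (
        [ConstraintCategory("content", v, z_min=1) for v in range(1, 5)]
        + [ConstraintCategory("item_type", v, z_min=2) for v in range(1, 3)]
        + [ConstraintCategory("answer_key", v, z_min=1) for v in range(1, 5)]
        + [ConstraintCategory("enemy", 0, z_min=0, z_max=0)]
        + [ConstraintCategory("attribute", k, z_min=1) for k in range(K)]
    )
    return TestSpecification(
        K=K, stage_sizes=(K, 3, 3), n_panels=n_panels, constraints=constraints
    )


@pytest.fixture(scope="module")
def engine(small_bank, small_sample):
    _, X = small_sample
    return NWADHAssembler(small_bank, small_spec(), X)


class TestPrimitives:
    def test_mad_at_target(self):
        assert mean_absolute_deviation(np.full(5, 0.9), np.full(5, 0.9)) == 0.0

    def test_mad_uniform_gap(self):
        assert mean_absolute_deviation(np.full(5, 0.8), np.full(5, 0.9)) == pytest.approx(0.1)

    def test_mad_hand_value(self):
        assert mean_absolute_deviation(
            np.array([0.85, 0.7]), np.array([0.9, 0.9])
        ) == pytest.approx(0.125)

    def test_mad_length_mismatch(self):
        with pytest.raises(ValueError):
            mean_absolute_deviation(np.ones(2), np.ones(3))

    def test_priority_single_candidate_zero(self):
        assert priority_index({7: 0.2}) == {7: 0.0}

    def test_priority_equal_deviations(self):
        e = priority_index({1: 0.3, 2: 0.3})
        assert e[1] == pytest.approx(0.5)
        assert e[2] == pytest.approx(0.5)

    def test_priority_hand_values(self):
        e = priority_index({1: 0.1, 2: 0.3})
        assert e[1] == pytest.approx(0.75)
        assert e[2] == pytest.approx(0.25)

    def test_priority_all_zero_ties(self):
        assert priority_index({1: 0.0, 2: 0.0}) == {1: 0.0, 2: 0.0}

    def test_update_weights_rules(self):
        z_min = np.array([4, 4, 4])
        z_max = np.array([np.inf, np.inf, 4])
        counts = np.array([3, 0, 4])  # Zmin-1 -> 2; below -> 2; at Zmax -> 1
        np.testing.assert_array_equal(
            update_weights(counts, z_min, z_max), [2.0, 2.0, 1.0]
        )

    def test_update_weights_between_bounds_is_one(self):
        assert update_weights(np.array([5]), np.array([4]), np.array([np.inf]))[0] == 1.0

    def test_content_weight_mean_gap(self):
        # G=4, W=(2,1,1,1): Wbar = 2 - 5/4 = 0.75; bearing nothing -> 4*0.75
        W = np.array([2.0, 1.0, 1.0, 1.0])
        assert content_weight(np.zeros(4), W) == pytest.approx(3.0)
        assert content_weight(np.array([1, 0, 0, 0]), W) == pytest.approx(2 + 3 * 0.75)

    def test_content_weight_all_satisfied_is_coverage(self):
        W = np.ones(4)
        assert content_weight(np.array([1, 0, 1, 0]), W) == pytest.approx(2.0)

    def test_constrained_priority_constant_content_keeps_ranking(self):
        e = {1: 0.75, 2: 0.25}
        star = constrained_priority(e, {1: 2.0, 2: 2.0})
        assert star[1] > star[2]

    def test_constrained_priority_content_can_offset(self):
        star = constrained_priority({1: 0.75, 2: 0.25}, {1: 1.0, 2: 3.0})
        assert star[1] == pytest.approx(1.0)
        assert star[2] == pytest.approx(1.0)

    def test_constrained_priority_single_candidate(self):
        assert constrained_priority({5: 0.0}, {5: 2.0})[5] == pytest.approx(1.0)

    def test_constrained_priority_zero_content_sum(self):
        assert constrained_priority({1: 0.4}, {1: 0.0}) == {1: 0.4}


class TestSpecificationConstruction:
    def test_condition_21_stage_sizes(self):
        assert TestSpecification.for_condition(21, 5).stage_sizes == (5, 8, 8)

    def test_condition_25_stage_sizes(self):
        assert TestSpecification.for_condition(25, 10).stage_sizes == (5, 10, 10)

    def test_default_constraint_table(self):
        cats = default_constraints(5)
        assert len(cats) == 16
        groups = {}
        for c in cats:
            groups.setdefault(c.group, []).append(c.z_min)
        assert groups["content"] == [4] * 4
        assert groups["item_type"] == [8] * 2
        assert groups["answer_key"] == [4] * 4
        assert groups["attribute"] == [3] * 5

    def test_infeasible_minimums_rejected(self):
        cats = [ConstraintCategory("content", v, z_min=10) for v in range(1, 5)]
        with pytest.raises(ValueError):
            TestSpecification(K=3, stage_sizes=(3, 3, 3), constraints=cats)


def oracle_one_step(bank, spec, X, selected, candidates, bin_index, bins):
    """Brute-force next-item oracle built from the public primitives only:
    score every candidate by a from-scratch reliability fit."""
    devs = {}
    for i in candidates:
        sel = selected + [int(i)]
        u = attribute_reliability(X[:, sel], bank.state_probs[sel], K=bank.K)
        devs[int(i)] = mean_absolute_deviation(u, spec.targets)
    e = priority_index(devs)
    counts = np.zeros(len(spec.constraints))
    feats = bank.features_array()
    for g, cat in enumerate(spec.constraints):
        for j in selected:
            if cat.group == "content":
                counts[g] += feats["content_category"][j] == cat.value
            elif cat.group == "item_type":
                counts[g] += feats["item_type"][j] == cat.value
            elif cat.group == "answer_key":
                counts[g] += feats["answer_key"][j] == cat.value
            elif cat.group == "attribute":
                counts[g] += bank.Q[j, cat.value] == 1
            elif cat.group == "enemy":
                counts[g] += feats["enemy_group"][j] >= 0
    W = update_weights(
        counts,
        np.array([c.z_min for c in spec.constraints]),
        np.array([c.z_max for c in spec.constraints]),
    )
    V = {}
    for i in candidates:
        row = []
        for cat in spec.constraints:
            if cat.group == "content":
                row.append(feats["content_category"][i] == cat.value)
            elif cat.group == "item_type":
                row.append(feats["item_type"][i] == cat.value)
            elif cat.group == "answer_key":
                row.append(feats["answer_key"][i] == cat.value)
            elif cat.group == "attribute":
                row.append(bank.Q[i, cat.value] == 1)
            else:
                row.append(feats["enemy_group"][i] >= 0)
        V[int(i)] = np.array(row, dtype=float)
    c = {i: content_weight(V[i], W) for i in map(int, candidates)}
    estar = constrained_priority(e, c)
    best = max(estar.values())
    near = [i for i, v in estar.items() if v >= best - 1e-12]
    mid = bins.midpoint(bin_index)
    near.sort(key=lambda i: (abs(bank.difficulty[i] - mid), i))
    return near[0], devs


class TestSelectionAgainstOracle:
    def test_candidate_deviations_match_batch_refit(self, small_bank, small_sample, engine):
        _, X = small_sample
        state = engine._seeded_state([0, 10, 20])
        candidates = np.arange(30, 55)
        fast = engine.candidate_deviations(state, candidates)
        for pos, i in enumerate(candidates[::5]):
            sel = [0, 10, 20, int(i)]
            u = attribute_reliability(X[:, sel], small_bank.state_probs[sel], K=3)
            slow = mean_absolute_deviation(u, engine.spec.targets)
            assert fast[5 * pos] == pytest.approx(slow, abs=1e-8)

    def test_greedy_equals_exhaustive_oracle(self, small_bank, small_sample, engine):
        _, X = small_sample
        spec = engine.spec
        bin_index = 1  # medium
        pool = np.flatnonzero(engine.bin_idx == bin_index)[:40]
        selected = [int(pool[0]), int(pool[1])]
        candidates = pool[2:]
        expected, _ = oracle_one_step(
            small_bank, spec, X, selected, candidates, bin_index, engine.bins
        )
        state = engine._seeded_state(selected)
        got = engine.select_next_item(state, candidates, bin_index)
        assert got == expected

    def test_zero_information_item_leaves_deviation_unchanged(self, small_sample):
        rng = np.random.default_rng(0)
        feats = ItemFeatures(1, 1, 1)
        items = [
            GDINAItem(0, np.array([1, 0, 0]), np.array([0.1, 0.9]), feats),
            GDINAItem(1, np.array([0, 1, 0]), np.array([0.2, 0.85]), feats),
            GDINAItem(2, np.array([1, 1, 0]), np.array([0.5, 0.5, 0.5, 0.5]), feats),
            GDINAItem(3, np.array([0, 0, 1]), np.array([0.3, 0.8]), feats),
        ]
        bank = ItemBank(items, 3)
        states = simulate_knowledge_states(150, 3, rng)
        X = simulate_responses(bank, states, rng)
        spec = TestSpecification(
            K=3,
            stage_sizes=(3, 1, 1),
            constraints=[ConstraintCategory("attribute", k) for k in range(3)],
        )
        eng = NWADHAssembler(bank, spec, X)
        state = eng._seeded_state([0, 1])
        u_now = reliability_from_posterior(state.posterior, 3)
        d_now = mean_absolute_deviation(u_now, spec.targets)
        d_flat = eng.candidate_deviations(state, np.array([2]))[0]
        assert d_flat == pytest.approx(d_now, abs=1e-8)

    def test_more_discriminating_item_gives_smaller_deviation(self):
        rng = np.random.default_rng(1)
        feats = ItemFeatures(1, 1, 1)
        items = [
            GDINAItem(0, np.array([0, 1]), np.array([0.2, 0.8]), feats),
            GDINAItem(1, np.array([1, 0]), np.array([0.3, 0.7]), feats),  # weak
            GDINAItem(2, np.array([1, 0]), np.array([0.02, 0.98]), feats),  # strong
        ]
        bank = ItemBank(items, 2)
        states = simulate_knowledge_states(400, 2, rng)
        X = simulate_responses(bank, states, rng)
        spec = TestSpecification(
            K=2,
            stage_sizes=(2, 1, 1),
            constraints=[ConstraintCategory("attribute", k) for k in range(2)],
        )
        bins = DifficultyBins(cut_points=np.linspace(0, 1, 4))
        eng = NWADHAssembler(bank, spec, X, bins=bins)
        state = eng._seeded_state([0])
        d = eng.candidate_deviations(state, np.array([1, 2]))
        assert d[1] < d[0]  # the more discriminating candidate deviates less


class TestPanelAssembly:
    def test_tiny_panel_structure(self, tiny):
        eng = NWADHAssembler(tiny["bank"], tiny["spec"], tiny["responses"])
        panels = eng.assemble_panels()
        assert len(panels) == 1
        panel = panels[0]
        assert len(panel.stage1) == 3
        for pw in panel.pathways.values():
            assert [len(m) for m in pw.stage_modules] == [3, 3, 3]

    def test_stage1_unit_vectors_medium_bin(self, tiny):
        eng = NWADHAssembler(tiny["bank"], tiny["spec"], tiny["responses"])
        panel = eng.assemble_panels()[0]
        q_rows = tiny["bank"].Q[panel.stage1]
        assert sorted(map(tuple, q_rows)) == sorted(map(tuple, np.eye(3, dtype=int)))
        labels = [tiny["bins"].label(tiny["bank"].difficulty[j]) for j in panel.stage1]
        assert set(labels) == {"medium"}

    def test_stage23_items_in_pathway_bin(self, tiny):
        eng = NWADHAssembler(tiny["bank"], tiny["spec"], tiny["responses"])
        panel = eng.assemble_panels()[0]
        for label, pw in panel.pathways.items():
            for stage in pw.stage_modules[1:]:
                for j in stage:
                    assert tiny["bins"].label(tiny["bank"].difficulty[j]) == label

    def test_no_duplicates_within_panel(self, tiny):
        eng = NWADHAssembler(tiny["bank"], tiny["spec"], tiny["responses"])
        panel = eng.assemble_panels()[0]
        items = panel.all_items()
        assert len(items) == len(set(items))

    def test_no_enemy_pair_within_pathway(self, tiny):
        eng = NWADHAssembler(tiny["bank"], tiny["spec"], tiny["responses"])
        panel = eng.assemble_panels()[0]
        enemy = tiny["bank"].features_array()["enemy_group"]
        for pw in panel.pathways.values():
            groups = [enemy[j] for j in pw.items if enemy[j] >= 0]
            assert len(groups) == len(set(groups))

    def test_deterministic(self, tiny):
        a = NWADHAssembler(tiny["bank"], tiny["spec"], tiny["responses"]).assemble_panels()
        b = NWADHAssembler(tiny["bank"], tiny["spec"], tiny["responses"]).assemble_panels()
        for pa, pb in zip(a, b):
            assert pa.stage1 == pb.stage1
            for label in pa.pathways:
                assert pa.pathways[label].stage_modules == pb.pathways[label].stage_modules

    def test_stage1_exclusive_across_panels(self):
        rng = np.random.default_rng(123)
        bank = simulate_item_bank(300, 3, rng, enemy_fraction=0.04)
        states = simulate_knowledge_states(150, 3, rng)
        X = simulate_responses(bank, states, rng)
        spec = small_spec(n_panels=3)
        panels = NWADHAssembler(bank, spec, X).assemble_panels()
        stage1_all = [j for p in panels for j in p.stage1]
        assert len(stage1_all) == len(set(stage1_all))

    def test_single_eligible_item_is_selected(self, engine):
        state = engine._fresh_state()
        cand = np.array([12])
        assert engine.select_next_item(state, cand, None) == 12

    def test_empty_pool_raises_with_diagnostics(self, engine):
        state = engine._fresh_state()
        with pytest.raises(AssemblyInfeasibleError):
            engine.select_next_item(state, np.array([], dtype=int), None)
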