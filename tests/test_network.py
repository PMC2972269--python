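"""Synchronous engine: stepping, clamping, attractors, basins."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootscn import (
    NetworkError,
    RuleTable,
    build_network,
    clamp,
    find_attractors,
    sync_step,
    trajectory,
)
from rootscn.network import batch_step, step_int, transition_table
from rootscn.synthetic import RandomNetSpec, random_network

QC = (1, 1, 1, 0, 1, 1, 1, 0, 1)


def identity_net(n=1):
    names = [f"n{i}" for i in range(n)]
    return build_network(names, [RuleTable.from_expression(x, x) for x in names])


class TestConstruction:
    def test_reference_model_has_nine_nodes(self, model_a):
        assert model_a.n == 9
        assert model_a.nodes == (
            "PLT", "Auxin", "ARF", "Aux/IAA", "SHR", "SCR", "JKD", "MGP", "WOX5",
        )

    def test_single_self_copy_node(self):
        assert identity_net(1).n == 1

    def test_dangling_input_names_offender(self):
        rules = [RuleTable.from_expression("A", "A AND X")]
        with pytest.raises(NetworkError, match="X"):
            build_network(["A"], rules)

    def test_missing_and_duplicate_rules_rejected(self):
        ra = RuleTable.from_expression("A", "A")
        with pytest.raises(NetworkError, match="B"):
            build_network(["A", "B"], [ra])
        with pytest.raises(NetworkError, match="A"):
            build_network(["A"], [ra, ra])


class TestSyncStep:
    def test_qc_profile_is_a_fixed_point(self, model_a):
        assert sync_step(model_a, QC) == QC

    def test_all_zeros_update(self, model_a):
        # auxin source turns on; Aux/IAA responds to absent auxin; ARF to
        # absent Aux/IAA; everything downstream of SHR/SCR stays off
        assert sync_step(model_a, (0,) * 9) == (0, 1, 1, 1, 0, 0, 0, 0, 0)

    def test_fully_clamped_model_outputs_clamp_vector(self, model_a):
        m = model_a
        target = (0, 1, 0, 1, 0, 1, 0, 1, 0)
        for node, v in zip(m.nodes, target):
            m = clamp(m, node, v)
        for probe in [(0,) * 9, (1,) * 9, QC]:
            assert sync_step(m, probe) == target

    def test_length_mismatch_rejected(self, model_a):
        with pytest.raises(NetworkError):
            sync_step(model_a, (0, 1))

    def test_batch_step_matches_scalar_step(self, model_a):
        states = np.arange(512, dtype=np.uint64)
        nxt = batch_step(model_a, states)
        for s in (0, 7, 100, 511):
            assert int(nxt[s]) == step_int(model_a, s)


class TestAttractors:
    def test_identity_node_has_two_unit_basins(self):
        aset = find_attractors(identity_net(1))
        assert sorted(a.states[0] for a in aset.attractors) == [(0,), (1,)]
        assert aset.basin_counts == [1, 1]

    def test_basin_counts_sum_to_space_size(self, model_a):
        aset = find_attractors(model_a)
        assert sum(aset.basin_counts) == 512 == aset.space_size

    def test_exhaustive_above_cap_advises_sampled_mode(self):
        net = random_network(RandomNetSpec(N=30, K=2, p=0.5, seed=0))
        with pytest.raises(NetworkError, match="sampled"):
            find_attractors(net, cap=24)

    def test_sampled_requires_samples_and_seed(self, model_a):
        with pytest.raises(NetworkError):
            find_attractors(model_a, mode="sampled", n_samples=0, seed=1)
        with pytest.raises(NetworkError):
            find_attractors(model_a, mode="sampled", n_samples=10)

    def test_cycle_detection_on_a_two_cycle(self):
        # a NOT-loop of two nodes has one 2-cycle and two fixed points
        net = build_network(
            ["a", "b"],
            [RuleTable.from_expression("a", "NOT b"),
             RuleTable.from_expression("b", "NOT a")],
        )
        aset = find_attractors(net)
        periods = sorted(a.period for a in aset.attractors)
        assert periods == [1, 1, 2]
        cyc = next(a for a in aset.attractors if a.period == 2)
        assert cyc.states[0] == min(cyc.states)  # canonical rotation

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_random_nets(self, seed):
        """Independent per-state python enumeration agrees with the engine."""
        net = random_network(RandomNetSpec(N=8, K=2, p=0.5, seed=seed))

        def oracle_next(s):
            bits = [(s >> (net.n - 1 - i)) & 1 for i in range(net.n)]
            out = 0
            for i, rule in enumerate(net.rules):
                row = 0
                for name in rule.inputs:
                    row = (row << 1) | bits[net.node_index[name]]
                out |= int(rule.outputs[row]) << (net.n - 1 - i)
            return out

        basins = {}
        for s in range(256):
            seen = []
            cur = s
            while cur not in seen:
                seen.append(cur)
                cur = oracle_next(cur)
            cyc = seen[seen.index(cur):]
            k = cyc.index(min(cyc))
            basins.setdefault(tuple(cyc[k:] + cyc[:k]), 0)
            basins[tuple(cyc[k:] + cyc[:k])] += 1

        aset = find_attractors(net)
        engine = {
            tuple(net.encode(x) for x in a.states): c
            for a, c in zip(aset.attractors, aset.basin_counts)
        }
        assert engine == basins

    def test_sampled_attractors_subset_of_exhaustive(self):
        net = random_network(RandomNetSpec(N=10, K=3, p=0.5, seed=7))
        full = find_attractors(net).states_set()
        sampled = find_attractors(net, mode="sampled", n_samples=200, seed=11)
        assert sampled.states_set() <= full
        assert sum(sampled.basin_counts) == 200


class TestClamp:
    def test_clamp_shr_collapses_to_cepi(self, model_a):
        aset = find_attractors(clamp(model_a, "SHR", 0))
        assert [a.states[0] for a in aset.attractors] == [(1, 1, 1, 0, 0, 0, 0, 0, 0)]
        assert aset.basin_counts == [512]

    def test_clamp_mgp_redirects_cei_basin_to_qc(self, model_a):
        wild = find_attractors(model_a)
        cei = (1, 1, 1, 0, 1, 1, 1, 1, 0)
        mutant = clamp(model_a, "MGP", 0)
        cei_states = [
            s for s in range(512)
            if wild.attractors[wild.assignments[s]].states[0] == cei
        ]
        for s in cei_states[::17]:
            assert trajectory(mutant, s).attractor.states[0] == QC

    def test_clamp_consistent_with_fixed_point(self, model_a):
        # clamping a node at its fixed-point value preserves the fixed point
        m = clamp(model_a, "WOX5", 1)
        assert sync_step(m, QC) == QC

    def test_unknown_node_rejected(self, model_a):
        with pytest.raises(NetworkError):
            clamp(model_a, "XYZ", 1)


class TestDeterminismAndTermination:
    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 511))
    def test_trajectories_are_deterministic_and_terminate(self, s):
        from rootscn import build_scn_model

        model = build_scn_model("A")
        t1 = trajectory(model, s)
        t2 = trajectory(model, s)
        assert t1.states == t2.states
        assert t1.transient_length < 512
        # last block repeats with the attractor's period
        a = t1.attractor
        assert sync_step(model, a.states[0]) == a.states[1 % a.period]
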