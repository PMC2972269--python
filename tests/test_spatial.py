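"""Four-cell coupled meta-GRN: structure, convergence, mutants."""

import numpy as np
import pytest

from rootscn import build_meta_grn, find_global_attractors, run_spatial
from rootscn.network import NetworkError
from rootscn.spatial import (
    CELLS,
    EXPECTED_FATE,
    MobilitySpec,
    pattern_of,
    simulate_spatial_mutant,
)


class TestConstruction:
    def test_forty_variables_and_clamps(self, meta_grn):
        net = meta_grn.network
        assert net.n == 40
        assert net.clamps == {"SHR@V": 1, "SCR@V": 0, "Auxin@V": 1, "Auxin@C": 1}
        assert set(net.nodes) == {f"{n}@{c}" for c in CELLS for n in meta_grn.cell_nodes}

    def test_only_b_prime_is_supported(self):
        with pytest.raises(NetworkError, match="B_prime"):
            build_meta_grn("A")

    def test_shr_movement_is_gated_by_absent_scr(self, meta_grn):
        net = meta_grn.network
        rule = net.rules[net.node_index["SHR@E"]]
        assert set(rule.inputs) == {"SHR@Q", "SCR@Q"}  # E's only neighbour is Q
        # movement requires SHR present and SCR absent in the source cell
        assert rule.outputs[int("10", 2)] == 1 and rule.outputs[int("11", 2)] == 0

    def test_clex_rule_reads_wox5_outside_qc_only(self, meta_grn):
        net = meta_grn.network
        clex_c = net.rules[net.node_index["CLEX@C"]]
        clex_q = net.rules[net.node_index["CLEX@Q"]]
        assert any(i.startswith("WOX5@") for i in clex_c.inputs)
        assert clex_q.inputs == () and clex_q.outputs[0] == 0

    def test_immobile_nodes_never_cross_cells(self, meta_grn):
        net = meta_grn.network
        mobile = set(meta_grn.mobility.mobile)
        for rule in net.rules:
            node, cell = rule.target.split("@")
            if node in mobile:
                continue
            for inp in rule.inputs:
                iname, icell = inp.split("@")
                # a non-mobile regulated node may read mobile inputs from
                # other cells only through the mobile nodes themselves
                assert icell == cell or iname in mobile

    def test_malformed_mobility_rejected(self):
        with pytest.raises(NetworkError):
            MobilitySpec(adjacency=frozenset({frozenset({"V", "X"})}))
        with pytest.raises(NetworkError):
            MobilitySpec(mobile=("SHR",))


class TestWildType:
    def test_convergence_from_arbitrary_states_with_convention(self, meta_grn):
        aset = find_global_attractors(meta_grn, n_samples=3000, seed=11)
        assert len(aset) == 1
        a = aset.attractors[0]
        assert a.is_fixed_point
        pat = pattern_of(meta_grn, a.states[0])
        assert pat.labels == EXPECTED_FATE
        assert sum(aset.basin_counts) == 3000

    def test_wox5_confined_to_the_qc(self, meta_grn):
        a = find_global_attractors(meta_grn, n_samples=500, seed=3).attractors[0]
        pat = pattern_of(meta_grn, a.states[0])
        assert pat.cells["Q"]["WOX5"] == 1
        assert all(pat.cells[c]["WOX5"] == 0 for c in "VCE")

    def test_single_sample_returns_one_attractor(self, meta_grn):
        aset = find_global_attractors(meta_grn, n_samples=1, seed=9)
        assert len(aset) == 1 and aset.basin_counts == [1]

    def test_all_zeros_without_convention_never_bootstraps_scr(self, meta_grn):
        traj, pat = run_spatial(meta_grn, 0, scr_convention=False)
        assert all(pat.cells[c]["SCR"] == 0 for c in CELLS)
        assert not pat.matches_wild_type()

    def test_run_spatial_reaches_the_wild_type_pattern(self, meta_grn):
        rng = np.random.default_rng(21)
        for _ in range(5):
            init = int(rng.integers(0, 2**40))
            traj, pat = run_spatial(meta_grn, init, scr_convention=True)
            assert pat.matches_wild_type()
            assert traj.attractor.is_fixed_point


class TestMutants:
    def test_scr_loss_removes_qc_and_cei_and_spreads_shr(self, meta_grn):
        aset = simulate_spatial_mutant(meta_grn, "SCR", "loss", n_samples=2000, seed=5)
        for a in aset.attractors:
            pat = pattern_of(meta_grn, a.states[0])
            assert "QC" not in pat.labels.values()
            assert "CEI" not in pat.labels.values()
            assert pat.cells["E"]["SHR"] == 1  # the SHR anomaly reaches CEpI

    def test_shr_gain_splits_the_e_cell_fate(self, meta_grn):
        aset = simulate_spatial_mutant(meta_grn, "SHR", "gain", n_samples=2000, seed=6)
        from rootscn.models import reference_profiles

        prof = reference_profiles("B_prime").profiles
        e_states = {meta_grn.project(a.states[0], "E") for a in aset.attractors}
        cei_like = any(s[:9] == prof["CEI"][:9] for s in e_states)
        idx_shr = meta_grn.cell_nodes.index("SHR")
        cepi = prof["CEpI"]
        cepi_plus_shr = tuple(
            1 if i == idx_shr else v for i, v in enumerate(cepi)
        )
        assert cei_like
        assert cepi_plus_shr in e_states

    def test_mgp_loss_changes_nothing_under_the_convention(self, meta_grn):
        wt = find_global_attractors(meta_grn, n_samples=2000, seed=7)
        mut = simulate_spatial_mutant(
            meta_grn, "MGP", "loss", n_samples=2000, seed=7, scr_convention=True
        )
        assert len(wt) == len(mut) == 1
        drop = [
            i for i, n in enumerate(meta_grn.network.nodes) if not n.startswith("MGP@")
        ]
        wt_s, mut_s = wt.attractors[0].states[0], mut.attractors[0].states[0]
        assert tuple(wt_s[i] for i in drop) == tuple(mut_s[i] for i in drop)

    def test_unknown_node_and_kind_rejected(self, meta_grn):
        with pytest.raises(NetworkError):
            simulate_spatial_mutant(meta_grn, "FOO", "loss", n_samples=1, seed=0)
        with pytest.raises(NetworkError):
            simulate_spatial_mutant(meta_grn, "SHR", "up", n_samples=1, seed=0)


class TestContinuousSpatial:
    def test_continuous_version_recovers_the_discrete_pattern(self, meta_grn):
        from rootscn.spatial import continuous_spatial_attractors

        wt = find_global_attractors(meta_grn, n_samples=500, seed=13)
        target = wt.attractors[0].states[0]
        _, finals = continuous_spatial_attractors(meta_grn, n_starts=10, seed=13)
        assert set(finals) == {target}
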