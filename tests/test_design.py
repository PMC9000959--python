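"""Design search: enumeration, metrics, screening and gain optimization."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from yeastcons.design import (
    DesignCandidate,
    Topology,
    TruthTable,
    default_input_grids,
    enumerate_topologies,
    gate_score,
    nonmonotonicity_score,
    normalize_outputs,
    optimize_gains,
    screen,
    sensed_species,
    sensor_dynamic_range,
    simulate_response_tensor,
)
from yeastcons.kinetics import dose_response
from yeastcons.species import Signal


class TestEnumeration:
    def test_small_pool_count(self, small_pool, library):
        topos = enumerate_topologies(small_pool, 2, [library["IAA_rep_GFP"]])
        assert len(topos) == math.comb(4, 2)
        assert len({t.members for t in topos}) == 6

    @pytest.mark.parametrize("k, count", [(2, 120), (3, 560), (4, 1820)])
    def test_full_pool_reproduces_published_counts(self, library, k, count):
        topos = enumerate_topologies(library.pool_strains(), k,
                                     [library["IAA_rep_GFP"]])
        assert len(topos) == count

    def test_deterministic_order(self, small_pool, library):
        a = enumerate_topologies(small_pool, 2, library.sensors)
        b = enumerate_topologies(small_pool, 2, library.sensors)
        assert a == b

    def test_invalid_size_rejected(self, small_pool, library):
        for k in (1, 5):
            with pytest.raises(ValueError):
                enumerate_topologies(small_pool, k, library.sensors)

    def test_signal_graph_edges(self, library):
        topo = Topology(("aF_act_IAA", "IAA_act_BAR1"), "IAA_rep_GFP")
        g = topo.signal_graph(library)
        assert g.has_edge("alpha_factor", "aF_act_IAA")
        assert g.has_edge("aF_act_IAA", "auxin")
        assert g.has_edge("IAA_act_BAR1", "BAR1")
        assert g.has_edge("auxin", "IAA_rep_GFP")


class TestInputGrids:
    def test_published_grids(self):
        g = default_input_grids()
        assert g[Signal.ALPHA_FACTOR] == (0.0, 1.0, 5.0, 10.0, 50.0, 200.0, 1000.0)
        assert g[Signal.AUXIN] == (0.0, 100.0, 500.0, 1000.0, 5000.0)
        assert g[Signal.BETA_ESTRADIOL] == (0.0, 1.0, 5.0, 10.0, 100.0)
        for sp in Signal:
            assert g[sp][0] == 0.0


class TestResponseTensor:
    def test_single_species_circuit_has_linear_grid(self, library):
        topo = Topology(("aF_act_IAA", "aF_act_BAR1"), "IAA_rep_GFP")
        assert sensed_species(topo, library) == [Signal.ALPHA_FACTOR, Signal.AUXIN]
        topo2 = Topology((), "aF_rep_GFP")
        tensor = simulate_response_tensor(topo2, library)
        assert len(tensor.combos) == 7  # alpha grid only, not 7x5x5

    def test_zero_input_entry_is_unstimulated(self, library):
        topo = Topology((), "aF_rep_GFP")
        tensor = simulate_response_tensor(topo, library)
        flat = tensor.series[(0.0,)]
        np.testing.assert_allclose(flat, flat[0], rtol=1e-6)

    def test_bare_sensor_endpoint_matches_dose_response(self, library):
        sensor = library["IAA_rep_GFP"]
        tensor = simulate_response_tensor(Topology((), "IAA_rep_GFP"), library)
        doses = np.array([c[0] for c in tensor.combos])
        dr = dose_response(sensor.params, "repressing", doses, read_time=12.0)
        got = np.array([tensor.endpoint(c) for c in tensor.combos])
        np.testing.assert_allclose(np.sort(got)[::-1], dr.response, rtol=1e-4)


class TestNormalization:
    def test_affine_map_endpoints(self, library):
        s = library["IAA_rep_GFP"]
        lo, hi = sensor_dynamic_range(s)
        assert normalize_outputs(hi, s) == pytest.approx(1.0)
        assert normalize_outputs(lo, s) == pytest.approx(0.0)
        assert normalize_outputs((lo + hi) / 2, s) == pytest.approx(0.5)

    def test_clipping(self, library):
        s = library["IAA_rep_GFP"]
        lo, hi = sensor_dynamic_range(s)
        assert normalize_outputs(hi * 2, s) == 1.0
        assert normalize_outputs(0.0, s) == 0.0


class TestGateScore:
    TABLE = TruthTable("AND", (Signal.ALPHA_FACTOR, Signal.BETA_ESTRADIOL))

    def test_hand_computed_score(self):
        corners = {(False, False): 0.1, (False, True): 0.2,
                   (True, False): 0.2, (True, True): 0.8}
        # AND: ON = {0.8}; OFF = {0.1, 0.2, 0.2} -> 0.8 / 0.2 = 4.0
        assert gate_score(corners, self.TABLE) == pytest.approx(4.0)

    def test_boundary_is_one(self):
        corners = {(False, False): 0.3, (False, True): 0.3,
                   (True, False): 0.3, (True, True): 0.3}
        assert gate_score(corners, self.TABLE) == pytest.approx(1.0)

    def test_off_above_on_scores_below_one(self):
        corners = {(False, False): 0.9, (False, True): 0.1,
                   (True, False): 0.1, (True, True): 0.5}
        assert gate_score(corners, self.TABLE) < 1.0

    def test_missing_corner_rejected(self):
        with pytest.raises(ValueError, match="corner"):
            gate_score({(False, False): 0.1}, self.TABLE)

    @given(vals=st.lists(st.floats(1e-3, 1.0), min_size=4, max_size=4),
           scale=st.floats(0.01, 100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance_and_threshold_semantics(self, vals, scale):
        corners = dict(zip([(False, False), (False, True),
                            (True, False), (True, True)], vals))
        scaled = {k: v * scale for k, v in corners.items()}
        s1 = gate_score(corners, self.TABLE)
        s2 = gate_score(scaled, self.TABLE)
        assert s1 == pytest.approx(s2, rel=1e-9)
        on = [corners[(True, True)]]
        off = [v for k, v in corners.items() if k != (True, True)]
        assert (s1 <= 1.0) == (max(off) >= min(on))

    def test_truth_tables(self):
        rows = {g: TruthTable(g, self.TABLE.inputs).rows for g in
                ("AND", "OR", "NAND", "NOR")}
        assert [r[2] for r in rows["AND"]] == [False, False, False, True]
        assert [r[2] for r in rows["OR"]] == [False, True, True, True]
        assert [r[2] for r in rows["NAND"]] == [True, True, True, False]
        assert [r[2] for r in rows["NOR"]] == [True, False, False, False]


class TestNonmonotonicity:
    def test_hand_computed_peak(self):
        assert nonmonotonicity_score([0.0, 1.0, 0.1]) == pytest.approx(0.9)

    def test_hand_computed_dip(self):
        assert nonmonotonicity_score([1.0, 0.2, 0.9]) == pytest.approx(0.7)

    def test_constant_and_monotone_are_zero(self):
        assert nonmonotonicity_score([0.4, 0.4, 0.4, 0.4]) == 0.0
        assert nonmonotonicity_score([0.0, 0.2, 0.5, 1.0]) == 0.0
        assert nonmonotonicity_score([1.0, 0.5, 0.2, 0.0]) == 0.0

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=30))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_monotone_series_score_zero_and_reversal_invariance(self, vals):
        mono = sorted(vals)
        assert nonmonotonicity_score(mono) == 0.0
        assert nonmonotonicity_score(mono[::-1]) == 0.0
        assert nonmonotonicity_score(vals) == pytest.approx(
            nonmonotonicity_score(vals[::-1]), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            nonmonotonicity_score([0.0, 1.0])


@pytest.fixture(scope="module")
def and_screen(library, small_pool):
    return screen(library, "AND", sizes=(2,), pool=small_pool,
                  sensors=[library["IAA_rep_GFP"]])


class TestScreen:
    def test_exhaustive_and_deterministic(self, library, small_pool, and_screen):
        assert and_screen.n_topologies == math.comb(4, 2)
        again = screen(library, "AND", sizes=(2,), pool=small_pool,
                       sensors=[library["IAA_rep_GFP"]])
        for a, b in zip(and_screen.candidates, again.candidates):
            assert a.topology == b.topology and a.score == b.score

    def test_matches_per_topology_rescoring(self, library, small_pool, and_screen):
        """Small-instance oracle: re-score every topology independently."""
        from yeastcons.design import _score_candidate, default_input_grids
        for cand in and_screen.candidates:
            redo = _score_candidate(cand.topology, library, "AND",
                                    default_input_grids(),
                                    dict(cand.gains), 12.0, None)
            assert redo.score == pytest.approx(cand.score, rel=1e-9)

    def test_expected_and_architecture_wins(self, and_screen):
        """Repression of auxin synthesis by both inputs + negative auxin
        sensor is the textbook AND realization here."""
        best = and_screen.candidates[0]
        assert set(best.topology.members) == {"aF_rep_IAA", "bE_rep_IAA"}
        assert best.score > 1.0

    def test_selected_keeps_only_scores_above_one(self, and_screen):
        sel = and_screen.selected()
        assert all(c.score > 1.0 for c in sel)


class TestOptimizeGains:
    def test_finds_known_optimum_of_toy_network(self, library):
        """One auxin producer + repressing sensor, band-pass impossible: use
        the AND pair and compare against a 1-D gain grid search."""
        cand_topo = Topology(("aF_rep_IAA", "bE_rep_IAA"), "IAA_rep_GFP")
        from yeastcons.design import _score_candidate, default_input_grids
        grids = default_input_grids()

        def score_at(g1):
            return _score_candidate(cand_topo, library, "AND", grids,
                                    {"aF_rep_IAA": g1, "bE_rep_IAA": 1.0},
                                    12.0, None).score

        grid = np.geomspace(0.1, 10.0, 25)
        oracle_best = max(grid, key=score_at)
        base = _score_candidate(cand_topo, library, "AND", grids,
                                {"aF_rep_IAA": 1.0, "bE_rep_IAA": 1.0}, 12.0, None)
        out = optimize_gains(base, library, seed=0, n_restarts=2, max_evals=60)
        assert out.score >= base.score
        assert score_at(out.gains["aF_rep_IAA"]) >= 0.95 * score_at(oracle_best)

    def test_bounds_respected(self, library):
        topo = Topology(("aF_rep_IAA", "bE_rep_IAA"), "IAA_rep_GFP")
        base = DesignCandidate(topology=topo,
                               gains={"aF_rep_IAA": 1.0, "bE_rep_IAA": 1.0},
                               metric="AND", score=1.0)
        out = optimize_gains(base, library, bounds=(0.5, 2.0), seed=1,
                             n_restarts=2, max_evals=40)
        for v in out.gains.values():
            assert 0.5 <= v <= 2.0
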