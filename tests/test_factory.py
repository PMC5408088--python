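import dataclasses
import math

import numpy as np
import pytest

from vascufab.config import FactoryParams, FlowParams, SimulationConfig
from vascufab.core import Cell, CellKind
from vascufab.factory import (
    FactoryState,
    baseline_throughput,
    compute_throughput,
    nutrient_consumption_rate,
    nutrient_delivery_rate,
    product_uptake_rate,
    production_rate,
    run_factory,
)
from vascufab.flow import solve_network_flow
from vascufab.vesselgraph import SINK, SOURCE, GraphEdge, GraphNode, VesselGraph

P = FactoryParams()


class TestDeliveryRate:
    def test_no_flow_no_delivery(self):
        assert nutrient_delivery_rate(0.0, 3.0, 0.5, P) == 0.0

    def test_nutrient_rich_microenvironment_shuts_delivery_down(self):
        rich = nutrient_delivery_rate(1e6, 3.0, 1e9, P)
        poor = nutrient_delivery_rate(1e6, 3.0, 0.0, P)
        assert rich < 1e-6 * poor

    def test_double_saturation_limit(self):
        rate = nutrient_delivery_rate(1e15, 3.0, 0.0, P)
        assert rate == pytest.approx(P.rho_n * 2 * math.pi * 3.0, rel=1e-6)

    def test_direction_agnostic(self):
        assert nutrient_delivery_rate(-5e4, 3.0, 0.1, P) == \
            nutrient_delivery_rate(5e4, 3.0, 0.1, P)


class TestProductionRate:
    def test_no_nutrient_no_product(self):
        assert production_rate(0.0, 0.0, P) == 0.0

    def test_product_inhibition_limit(self):
        assert production_rate(1.0, 1e9, P) < 1e-6 * production_rate(1.0, 0.0, P)

    def test_saturation_limit(self):
        assert production_rate(1e9, 0.0, P) == pytest.approx(P.mu_p * P.M_p, rel=1e-6)

    def test_half_saturation(self):
        assert production_rate(P.k_p, 0.0, P) == pytest.approx(P.mu_p * P.M_p / 2)


class TestUptakeRate:
    def test_no_product_no_uptake(self):
        assert product_uptake_rate(1e5, 3.0, 0.0, P) == 0.0

    def test_stagnant_vessel_removes_nothing(self):
        assert product_uptake_rate(0.0, 3.0, 5.0, P) == 0.0

    def test_double_saturation_limit(self):
        rate = product_uptake_rate(1e15, 3.0, 1e9, P)
        assert rate == pytest.approx(P.rho_p * 2 * math.pi * 3.0, rel=1e-6)


class TestConsumptionRate:
    def test_no_nutrient_no_consumption(self):
        assert nutrient_consumption_rate(0.0, 1.0, P) == 0.0

    def test_ratio_to_production_is_rate_ratio(self):
        # shared Hill factors cancel at any operating point
        for N, X in [(0.1, 0.0), (1.0, 0.3), (5.0, 2.0)]:
            assert nutrient_consumption_rate(N, X, P) / production_rate(N, X, P) == \
                pytest.approx(P.mu_n / P.mu_p)

    def test_inhibition_limit(self):
        assert nutrient_consumption_rate(1.0, 1e9, P) < \
            1e-6 * nutrient_consumption_rate(1.0, 0.0, P)


def small_factory_config(**factory_overrides):
    fp = dict(production_window=5.0, max_sim_time=60.0)
    fp.update(factory_overrides)
    return SimulationConfig(
        domain_height=64.0, domain_width=64.0, n_circulatory=26,
        n_interior_cells=0, cell_radius=2.0,
        factory_params=FactoryParams(**fp),
    )


def straight_vessel_graph(cfg, radius=3.0):
    """One horizontal pipe through the domain middle, terminals attached."""
    W, H = cfg.domain_width, cfg.domain_height
    row = int(H / 2)
    path = [(row, j) for j in range(2, int(W) - 2)]
    nodes = [GraphNode(0, (2.5, H / 2)), GraphNode(1, (W - 2.5, H / 2)),
             GraphNode(2, (0.0, H / 2), SOURCE), GraphNode(3, (W, H / 2), SINK)]
    edges = [GraphEdge(0, 1, radius, float(len(path) - 1), path),
             GraphEdge(2, 0, radius, 1.0), GraphEdge(3, 1, radius, 1.0)]
    return VesselGraph(nodes, edges)


def ring_of_producers(cfg, n=40, offset=6.0):
    H = cfg.domain_height
    cells = []
    for i in range(n):
        x = 8.0 + (cfg.domain_width - 16.0) * (i % (n // 2)) / (n // 2 - 1)
        y = H / 2 + (offset if i < n // 2 else -offset)
        cells.append(Cell(i, CellKind.PRODUCER, (x, y), cfg.cell_radius, 1.0))
    return cells


class TestRunFactory:
    def test_no_producers_gives_zero_product(self):
        cfg = small_factory_config()
        g = straight_vessel_graph(cfg)
        sol = solve_network_flow(g, cfg.flow_params)
        state = run_factory([], g, sol, cfg)
        assert state.field_X.values.max() == 0.0
        assert compute_throughput(state) == 0.0
        # nutrient flows in even with nobody to eat it
        assert state.field_N.values.max() > 0.0

    def test_zero_pressure_head_means_dead_factory(self):
        cfg = small_factory_config()
        cfg = dataclasses.replace(cfg, flow_params=FlowParams(delta_P=1e-9))
        cells = ring_of_producers(cfg)
        state = run_factory(cells, None, None, cfg)
        assert compute_throughput(state) == pytest.approx(0.0, abs=1e-12)
        assert state.field_N.values.max() < 1e-9

    def test_steady_state_mass_budget_closes(self):
        # at steady state the product removal rate balances synthesis
        cfg = small_factory_config(production_window=30.0, max_sim_time=400.0,
                                   steady_tol=0.003)
        g = straight_vessel_graph(cfg)
        sol = solve_network_flow(g, cfg.flow_params)
        cells = ring_of_producers(cfg)
        state = run_factory(cells, g, sol, cfg)
        assert state.steady
        produced = state.produced_total
        removed = state.removed_per_edge.sum()
        leftover = state.field_X.total_mass()
        # global ledger: everything produced is either removed or in the field
        assert removed + leftover == pytest.approx(produced, rel=1e-6)
        # and at steady state the flux balance itself closes within 2%
        removal_rate = state.window_removed_per_edge.sum() / state.window_duration
        prod_rate = state.window_produced / state.window_duration
        assert removal_rate == pytest.approx(prod_rate, rel=0.02)

    def test_global_ledger_exact_for_both_fields(self):
        cfg = small_factory_config(production_window=5.0, max_sim_time=40.0)
        g = straight_vessel_graph(cfg)
        sol = solve_network_flow(g, cfg.flow_params)
        cells = ring_of_producers(cfg)
        state = run_factory(cells, g, sol, cfg)
        delivered = state.delivered_per_edge.sum()
        consumed = state.consumed_total
        assert state.field_N.total_mass() == pytest.approx(delivered - consumed,
                                                           rel=1e-6)
        produced = state.produced_total
        removed = state.removed_per_edge.sum()
        assert state.field_X.total_mass() == pytest.approx(produced - removed,
                                                           rel=1e-6)
        assert (state.field_N.values >= 0).all()
        assert (state.field_X.values >= 0).all()

    def test_throughput_monotone_in_synthesis_rate(self):
        cfg_lo = small_factory_config(mu_p=1.0)
        cfg_hi = small_factory_config(mu_p=3.0)
        tp = {}
        for name, cfg in [("lo", cfg_lo), ("hi", cfg_hi)]:
            g = straight_vessel_graph(cfg)
            sol = solve_network_flow(g, cfg.flow_params)
            state = run_factory(ring_of_producers(cfg), g, sol, cfg)
            tp[name] = compute_throughput(state)
        assert tp["hi"] >= tp["lo"]

    def test_disabling_product_inhibition_cannot_reduce_throughput(self):
        # the uninhibited factory approaches its asymptote from below, so a
        # tight steady tolerance and a small slack for finite detection
        kw = dict(production_window=20.0, max_sim_time=400.0, steady_tol=0.002)
        cfg_inh = small_factory_config(k_i=0.05, **kw)
        cfg_free = small_factory_config(k_i=1e9, **kw)
        tp = {}
        for name, cfg in [("inh", cfg_inh), ("free", cfg_free)]:
            g = straight_vessel_graph(cfg)
            sol = solve_network_flow(g, cfg.flow_params)
            state = run_factory(ring_of_producers(cfg), g, sol, cfg)
            tp[name] = compute_throughput(state)
        assert tp["free"] >= 0.98 * tp["inh"]

    def test_deterministic_rerun(self):
        cfg = small_factory_config()
        g = straight_vessel_graph(cfg)
        sol = solve_network_flow(g, cfg.flow_params)
        cells = ring_of_producers(cfg)
        a = run_factory(cells, g, sol, cfg)
        b = run_factory(cells, g, sol, cfg)
        np.testing.assert_array_equal(a.field_X.values, b.field_X.values)
        assert compute_throughput(a) == compute_throughput(b)


class TestThroughputAccounting:
    def test_error_before_steady_state(self):
        state = FactoryState(
            field_N=None, field_X=None, t=0.0,
            delivered_per_edge=np.zeros(1), removed_per_edge=np.zeros(1),
            producer_active=np.zeros(0, bool), throughput_rate=0.0,
            steady=False,
        )
        with pytest.raises(RuntimeError, match="steady"):
            compute_throughput(state)

    def test_baseline_starves_the_interior(self):
        cfg = SimulationConfig(
            domain_height=129.0, domain_width=129.0, n_circulatory=52,
            n_interior_cells=600, cell_radius=2.0,
            factory_params=FactoryParams(production_window=10.0, max_sim_time=120.0),
        )
        tp = baseline_throughput(cfg, seed=4)
        assert tp > 0.0
        # reconstruct the final state to inspect the nutrient field
        from vascufab.core import make_initial_state
        from vascufab.morphogenesis import relax_shoving

        cells = make_initial_state(
            dataclasses.replace(cfg, vascular_fraction=0.0),
            np.random.default_rng(4))
        cells, _ = relax_shoving(cells, 120, (cfg.domain_width, cfg.domain_height))
        state = run_factory(cells, None, None,
                            dataclasses.replace(cfg, vascular_fraction=0.0))
        rows, cols = state.field_N.values.shape
        centre = state.field_N.values[rows // 2, cols // 2]
        assert centre < cfg.factory_params.activation_threshold
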