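"""Cellular Potts engine: energies, acceptance law, division, removal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lobulesim import cpm, geometry as geo
from lobulesim.driver import RunConfig, Simulation
from lobulesim.params import CpmParams, ModelParams

from conftest import random_lattice


def brute_force_delta(grid, klass, params, area, target, src, tgt):
    """H(after) - H(before) with H recomputed from scratch."""
    h_before = cpm.hamiltonian(grid, klass, params, target)
    after = grid.copy()
    after[tgt] = grid[src]
    return cpm.hamiltonian(after, klass, params, target) - h_before


class TestDeltaHamiltonian:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_incremental_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        grid, klass, area, target = random_lattice(rng)
        p = CpmParams()
        # find a valid neighbouring pair with different ids
        for _ in range(200):
            i, j = rng.integers(1, 19, size=2)
            di, dj = rng.choice([-1, 0, 1], size=2)
            if (di, dj) == (0, 0):
                continue
            src = (i + di, j + dj)
            if grid[src] == grid[i, j]:
                continue
            dh = cpm.delta_hamiltonian(grid, klass, p, area, target, src, (i, j))
            ref = brute_force_delta(grid, klass, p, area, target, src, (i, j))
            assert dh == pytest.approx(ref, abs=1e-9)
            return

    def test_same_cell_pair_is_invalid(self, rng):
        grid, klass, area, target = random_lattice(rng)
        grid[5, 5] = grid[5, 6] = 3
        with pytest.raises(ValueError):
            cpm.delta_hamiltonian(grid, klass, CpmParams(), area, target,
                                  (5, 5), (5, 6))

    def test_macrophage_chemotaxis_context_strengths(self, rng):
        grid = np.zeros((10, 10), dtype=np.int32)
        grid[4, 4] = 1  # macrophage pixel
        klass = np.array([0, geo.CLASS_MACROPHAGE], dtype=np.int8)
        area = np.bincount(grid.ravel(), minlength=2).astype(np.int64)
        target = np.array([0.0, 17.5])
        chemo = np.zeros((10, 10))
        chemo[4, 5] = 1.0  # gradient toward the target pixel
        p = CpmParams()
        base = cpm.delta_hamiltonian(grid, klass, p, area, target,
                                     (4, 4), (4, 5))
        for ctx, mu in [(cpm.CTX_DEFAULT, p.mu_default),
                        (cpm.CTX_PERIPORTAL, p.mu_periportal),
                        (cpm.CTX_NEAR_NECROTIC, p.mu_near_necrotic)]:
            mu_ctx = np.array([0, ctx], dtype=np.uint8)
            dh = cpm.delta_hamiltonian(grid, klass, p, area, target,
                                       (4, 4), (4, 5), chemo=chemo,
                                       mu_ctx=mu_ctx)
            assert dh == pytest.approx(base - mu * 1.0)


class TestAcceptance:
    def test_negative_energy_always_accepted(self, rng):
        assert all(cpm.attempt_copy(-1.0, t, rng) for t in (0.5, 2, 50)
                   for _ in range(100))

    def test_zero_energy_always_accepted(self, rng):
        assert all(cpm.attempt_copy(0.0, 2.0, rng) for _ in range(100))

    def test_boltzmann_frequency_at_dh_equal_t(self, rng):
        n = 100_000
        hits = sum(cpm.attempt_copy(2.0, 2.0, rng) for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 4 * sigma

    def test_non_positive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            cpm.attempt_copy(1.0, 0.0, rng)


def _make_sim(dose=0.0, seed=0, horizon=1.0, **kw):
    cfg = RunConfig(dose=dose, horizon_h=horizon, seed=seed, miniature=True, **kw)
    return Simulation(cfg)


class TestMonteCarloStep:
    def test_single_cell_converges_to_target_area(self, rng):
        # with a stiff area constraint the cell settles within +-1 px
        layout = geo.LobuleLayout.miniature()
        grid, pop, hep, kc = geo.build_lobule(layout, 1, 0, rng=rng)
        stiff = CpmParams(temperature=2.0,
                          lambda_area=(0, 0, 50.0, 50.0, 50.0, 100.0, 50.0))
        lat = cpm.CpmLattice(grid, pop, stiff, layout.domain_mask,
                             layout.vein_mask)
        for _ in range(100):
            lat.monte_carlo_step(rng)
        assert abs(pop.area[hep[0]] - 35.0) <= 1.0
        lat.check_consistency()

    def test_frozen_lattice_unchanged(self, rng):
        layout = geo.LobuleLayout.miniature()
        grid, pop, hep, kc = geo.build_lobule(layout, 5, 0, rng=rng)
        pop.state[hep] = geo.NECROTIC  # necrotic cells are immotile
        lat = cpm.CpmLattice(grid, pop, CpmParams(), layout.domain_mask,
                             layout.vein_mask)
        before = grid.copy()
        for _ in range(20):
            lat.monte_carlo_step(rng)
        assert np.array_equal(before, lat.grid)

    def test_vein_pixels_immutable_over_simulation(self):
        sim = _make_sim(dose=450.0, horizon=2.0, seed=2)
        layout = sim.layout
        vein_before = sim.lattice.grid[layout.vein_mask].copy()
        sim.initialize()
        for _ in range(sim.config.n_mcs):
            sim.step()
        assert np.array_equal(vein_before, sim.lattice.grid[layout.vein_mask])

    def test_cache_consistency_detects_corruption(self, rng):
        layout = geo.LobuleLayout.miniature()
        grid, pop, hep, kc = geo.build_lobule(layout, 5, 2, rng=rng)
        lat = cpm.CpmLattice(grid, pop, CpmParams(), layout.domain_mask,
                             layout.vein_mask)
        lat.check_consistency()
        pop.area[hep[0]] += 1
        with pytest.raises(RuntimeError):
            lat.check_consistency()

    def test_no_cell_deaths_during_initialization(self):
        # Kupffer cells (target area 3.5 px) must essentially never reach
        # zero area by chance during the relaxation phase
        for seed in (0, 1):
            cfg = RunConfig(dose=0.0, horizon_h=1.0, seed=seed)
            sim = Simulation(cfg)
            sim.initialize()
            assert len(sim.pop.ids_of(geo.KUPFFER)) == 150
            # hepatocyte losses during packing are tolerated but rare
            assert len(sim.pop.ids_of(geo.HEPATOCYTE)) >= 597


class TestDivision:
    def _grown_cell(self, rng):
        layout = geo.LobuleLayout.miniature()
        grid, pop, hep, kc = geo.build_lobule(layout, 1, 0, rng=rng)
        lat = cpm.CpmLattice(grid, pop, CpmParams(), layout.domain_mask,
                             layout.vein_mask)
        for _ in range(60):
            lat.monte_carlo_step(rng)
        return lat, pop, hep[0]

    def test_daughters_partition_parent_pixels(self, rng):
        lat, pop, parent = self._grown_cell(rng)
        before = set(map(tuple, lat.pixels_of(parent)))
        daughter = lat.divide_cell(parent, rng)
        a = set(map(tuple, lat.pixels_of(parent)))
        b = set(map(tuple, lat.pixels_of(daughter)))
        assert a | b == before and not (a & b)
        assert len(a) > 0 and len(b) > 0
        assert pop.cell_type[daughter] == geo.HEPATOCYTE
        assert pop.state[daughter] == geo.HEALTHY
        lat.check_consistency()

    def test_single_pixel_cell_division_skipped(self, rng):
        layout = geo.LobuleLayout.miniature()
        grid, pop, hep, kc = geo.build_lobule(layout, 1, 0, rng=rng)
        lat = cpm.CpmLattice(grid, pop, CpmParams(), layout.domain_mask,
                             layout.vein_mask)
        assert lat.divide_cell(hep[0], rng) is None

    def test_lineage_bookkeeping(self):
        # total hepatocyte lineage = initial + cumulative proliferation
        sim = _make_sim(dose=450.0, horizon=30.0, seed=1)
        rec = sim.run()
        ts = rec.timeseries
        last = ts.iloc[-1]
        lineage = last.healthy + last.senescent + last.necrotic + last.cleared_cum
        assert lineage == sim.config.n_hepatocytes + last.prolif_cum


class TestRemoval:
    def test_removal_conserves_pixel_budget(self, rng):
        layout = geo.LobuleLayout.miniature()
        grid, pop, hep, kc = geo.build_lobule(layout, 5, 3, rng=rng)
        lat = cpm.CpmLattice(grid, pop, CpmParams(), layout.domain_mask,
                             layout.vein_mask)
        total = grid.size
        freed = lat.remove_cell(int(hep[0]))
        assert freed == 1
        counts = np.bincount(lat.grid.ravel(), minlength=pop.n_ids)
        assert counts.sum() + 0 == total  # all pixels still accounted for
        assert not pop.alive[hep[0]]

    def test_event_log_replay_matches_removals(self):
        sim = _make_sim(dose=500.0, horizon=60.0, seed=1)
        rec = sim.run()
        ev = rec.events
        removed = ev[ev.event.isin(["phagocytosis", "senescent_clearance"])]
        for _, row in removed.iterrows():
            assert not sim.pop.alive[int(row.cell_id)]
            assert sim.pop.area[int(row.cell_id)] == 0
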