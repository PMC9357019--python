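"""Run orchestration: initialization, the APAP exposure loop, recording.

A run proceeds in two phases.  During the 96-MCS initialization the lattice
relaxes from single-pixel seeds to packed cells (no APAP, no fields, all
intracellular variables at their basal steady state).  At exposure, the
plasma pool is loaded with the dose and every subsequent MCS (5 simulated
minutes) executes, in fixed order: (1) plasma decay and field
diffusion/production substeps, (2) vectorized per-hepatocyte ODE substeps
with locally sampled field inputs, (3) fate checks and immune rules in
ascending cell-id order, (4) one cellular Potts Monte Carlo step, and
(5) recording.  All stochastic decisions draw from a single per-run
generator in a fixed order, so identical (config, seed) pairs produce
identical records.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from . import cpm as cpm_mod
from . import geometry as geo
from . import immune as imm
from . import intracellular as intra
from .fields import DiffusionField, PlasmaPool, mean_over_cells
from .geometry import ConfigurationError
from .params import ModelParams
from .perturb import TherapyEvent, apply_fate_scale, apply_mdm2_feedback_scale


@dataclass
class RunConfig:
    """Everything that determines one run (together with the seed)."""

    dose: float = 450.0
    horizon_h: float = 168.0
    mcs_minutes: float = 5.0
    init_mcs: int = 96
    replicates: int = 10
    seed: int = 0
    miniature: bool = False
    n_hepatocytes: int = 600
    n_kupffer: int = 150
    zonation_mode: str = "both"
    ode_substeps: int = 20
    field_substeps: int = 3
    no_macrophages: bool = False
    mdm2_feedback_scale: float = 1.0
    fate_scale_which: str | None = None
    fate_scale_factor: float = 1.0
    therapies: list = dfield(default_factory=list)

    def __post_init__(self):
        n_mcs = self.horizon_h * 60.0 / self.mcs_minutes
        if abs(n_mcs - round(n_mcs)) > 1e-9:
            raise ConfigurationError("horizon must divide into whole MCS")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.miniature and self.n_hepatocytes == 600:
            self.n_hepatocytes = 54
            self.n_kupffer = 14

    @property
    def n_mcs(self) -> int:
        return int(round(self.horizon_h * 60.0 / self.mcs_minutes))

    @property
    def dt_h(self) -> float:
        return self.mcs_minutes / 60.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["therapies"] = [
            {"drug": t.drug, "time_h": t.time_h} for t in self.therapies
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["therapies"] = [TherapyEvent(**t) for t in d.get("therapies", [])]
        return cls(**d)


@dataclass
class SimulationRecord:
    """Per-MCS time series, the event log and final state tables."""

    timeseries: pd.DataFrame
    events: pd.DataFrame
    config: dict
    seed: int
    final_grid: np.ndarray | None = None
    final_types: np.ndarray | None = None
    cell_table: pd.DataFrame | None = None


class Simulation:
    """One lobule run; see the module docstring for the update order."""

    def __init__(self, config: RunConfig, seed: int | None = None,
                 params: ModelParams | None = None):
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed)
        self.params = (params or ModelParams()).copy()
        if config.mdm2_feedback_scale != 1.0:
            self.params.ddr = apply_mdm2_feedback_scale(
                self.params.ddr, config.mdm2_feedback_scale)
        if config.fate_scale_which is not None:
            self.params = apply_fate_scale(
                self.params, config.fate_scale_which, config.fate_scale_factor)
        self.p_necrosis = self.params.fate.p_necrosis
        self.p_recruit = 0.0 if config.no_macrophages else self.params.immune.p_recruit

        # the plasma pool represents whole-body plasma per lobule equivalent:
        # per-hepatocyte uptake scales inversely with the hepatocyte count so
        # the elimination split, half-life and per-cell exposure profile are
        # invariant under lobule size (miniature fixture = scale replica)
        from .params import REFERENCE_N_HEPATOCYTES
        n0 = max(config.n_hepatocytes, 1)
        if n0 != REFERENCE_N_HEPATOCYTES:
            scale = REFERENCE_N_HEPATOCYTES / n0
            self.params.plasma = dataclasses.replace(
                self.params.plasma,
                k_u=self.params.plasma.k_u * scale,
                partition=self.params.plasma.partition / scale,
            )

        self.layout = (geo.LobuleLayout.miniature() if config.miniature
                       else geo.LobuleLayout())
        self.scenario = geo.ZonationScenario(
            mode=config.zonation_mode, axis_length_um=self.layout.axis_length_um)
        grid, pop, hep_ids, kc_ids = geo.build_lobule(
            self.layout, config.n_hepatocytes, config.n_kupffer, self.rng,
            self.scenario)
        self.pop = pop
        self.hep_ids = hep_ids  # grows with divisions; row k <-> cohort row k
        self.kc_ids = kc_ids
        self.lattice = cpm_mod.CpmLattice(grid, pop, self.params.cpm,
                                          self.layout.domain_mask,
                                          self.layout.vein_mask)
        gsh0 = np.zeros(len(hep_ids))
        p450 = np.zeros(len(hep_ids))
        for k, cid in enumerate(hep_ids):
            gsh0[k], p450[k] = geo.initial_zonation(
                pop.distance_um[cid], self.scenario)
        self.cohort = intra.HepatocyteCohort(gsh0, p450, self.params)

        shape = self.layout.grid_shape
        fp = self.params.fields
        px = self.layout.pixel_size
        self.fields = {
            "DAMP": DiffusionField("DAMP", shape, fp.D_damp, fp.d_damp, px),
            "MCP1": DiffusionField("MCP1", shape, fp.D_mcp1, fp.d_mcp1, px),
            "MIT": DiffusionField("MIT", shape, fp.D_mit, fp.d_mit, px),
            "TGFB": DiffusionField("TGFB", shape, fp.D_tgfb, fp.d_tgfb, px),
        }
        self.plasma: PlasmaPool | None = None
        self.timers = imm.ContactTimers(pop.capacity)
        self.recruit_state = imm.RecruitmentState()
        self.pre_exposure_max_gsh = float(gsh0.max()) if len(hep_ids) else 0.0
        self.cumulative_proliferation = 0
        self.cumulative_cleared = 0
        self._mcp1_history: list[float] = []
        self.mcs = 0
        self._rows: list = []
        self._events: list = []
        self.proliferated = np.zeros(pop.capacity, dtype=bool)
        self._therapies = [TherapyEvent(t.drug, t.time_h)
                           for t in config.therapies]

    # -- helpers ----------------------------------------------------------

    @property
    def time_h(self) -> float:
        """Hours since APAP exposure (negative during initialization)."""
        return (self.mcs - self.config.init_mcs) * self.config.dt_h

    def alive_hepatocyte_mask(self) -> np.ndarray:
        """Cohort-row mask of alive hepatocytes (healthy or senescent)."""
        st = self.pop.state[self.hep_ids]
        return self.pop.alive[self.hep_ids] & (st != geo.NECROTIC)

    def _hep_state_counts(self) -> tuple[int, int, int]:
        ids = self.hep_ids[self.pop.alive[self.hep_ids]]
        st = self.pop.state[ids]
        return (int((st == geo.HEALTHY).sum()), int((st == geo.SENESCENT).sum()),
                int((st == geo.NECROTIC).sum()))

    def _log(self, event: str, cell_id: int, cause: str = "") -> None:
        pos = (-1, -1)
        if cell_id > 0 and self.pop.area[cell_id] > 0:
            pix = np.argwhere(self.lattice.grid == cell_id)
            if len(pix):
                pos = tuple(int(v) for v in pix[0])
        self._events.append(
            {"mcs": self.mcs, "time_h": round(self.time_h, 6), "event": event,
             "cell_id": int(cell_id), "i": pos[0], "j": pos[1], "cause": cause})

    def deplete_kupffer_cells(self) -> None:
        for cid in self.pop.ids_of(geo.KUPFFER):
            self.lattice.remove_cell(int(cid))
            self._log("kc_depletion", int(cid), "clodronate")

    def _remove(self, cell_id: int, event: str, cause: str = "") -> None:
        self._log(event, cell_id, cause)
        self.lattice.remove_cell(cell_id)
        if self.pop.cell_type[cell_id] == geo.HEPATOCYTE:
            self.cumulative_cleared += 1

    # -- phases -----------------------------------------------------------

    def initialize(self) -> None:
        """Relax the lattice for ``init_mcs`` steps before APAP exposure."""
        for _ in range(self.config.init_mcs):
            zeroed = self.lattice.monte_carlo_step(self.rng)
            self._handle_zero_area(zeroed)
            self.mcs += 1
            self._record_row()
        self.plasma = PlasmaPool(self.config.dose, self.params.plasma.k_u,
                                 self.params.plasma.k_e)

    def _handle_zero_area(self, zeroed: list[int]) -> None:
        for cid in zeroed:
            self.pop.alive[cid] = False
            if self.pop.cell_type[cid] == geo.HEPATOCYTE:
                self.cumulative_cleared += 1
            self._log("zero_area", cid)

    def _field_step(self, klass: np.ndarray) -> None:
        dt = self.config.dt_h
        fp = self.params.fields
        g = self.lattice.grid
        necrotic = klass[g] == geo.CLASS_HEP_NECROTIC
        senescent = klass[g] == geo.CLASS_HEP_SENESCENT
        mphi = klass[g] == geo.CLASS_MACROPHAGE

        # secreting KCs: mean footprint DAMP above threshold
        kc_ids = self.pop.ids_of(geo.KUPFFER)
        mcp1_prod = np.zeros(g.shape)
        if len(kc_ids):
            damp_loc = mean_over_cells(self.fields["DAMP"].grid, g, kc_ids)
            secreting = kc_ids[np.nan_to_num(damp_loc) >
                               self.params.immune.damp_activation_threshold]
            if len(secreting):
                mcp1_prod[np.isin(g, secreting)] = fp.r_mcp1

        mphi_ids = self.pop.ids_of(geo.MACROPHAGE)
        tgfb_prod = np.zeros(g.shape)
        if len(mphi_ids):
            near_nec = imm.macrophage_secretion_context(g, klass, mphi_ids)
            producers = mphi_ids[near_nec]
            if len(producers):
                tgfb_prod[np.isin(g, producers)] = fp.t_macrophage
        tgfb_prod[senescent] += fp.t_senescent

        sub = self.config.field_substeps
        self.fields["DAMP"].step(dt, necrotic * fp.r_damp, substeps=sub)
        self.fields["MCP1"].step(dt, mcp1_prod, substeps=sub)
        self.fields["MIT"].step(dt, mphi * fp.r_mit, substeps=sub)
        self.fields["TGFB"].step(dt, tgfb_prod, substeps=sub)

        # receptor exchange: remove/add the net per-hepatocyte binding flux
        alive = self.alive_hepatocyte_mask()
        ids = self.hep_ids[alive]
        if len(ids):
            t_loc = np.nan_to_num(mean_over_cells(self.fields["TGFB"].grid, g, ids))
            rp = self.params.receptor
            flux = (rp.k_on * t_loc * self.cohort["R"][alive]
                    - rp.k_off * self.cohort["RT"][alive]) * dt
            areas = self.pop.area[ids].astype(float)
            delta = np.zeros(g.shape)
            per_pix = -flux / np.maximum(areas, 1.0)
            lut = np.zeros(self.pop.n_ids)
            lut[ids] = per_pix
            member = np.isin(g, ids)
            delta[member] = lut[g[member]]
            self.fields["TGFB"].add(delta)

    def _ode_step(self, klass: np.ndarray) -> None:
        g = self.lattice.grid
        ids = self.hep_ids
        t_loc = np.nan_to_num(mean_over_cells(self.fields["TGFB"].grid, g, ids))
        mit_loc = np.nan_to_num(mean_over_cells(self.fields["MIT"].grid, g, ids))
        active = self.alive_hepatocyte_mask()
        frozen = ~active
        y_before = self.cohort.y[:, frozen].copy()
        r_before = self.cohort.routes[:, frozen].copy()
        intra.step_cohort(self.cohort, self.config.dt_h, self.plasma.P_ex,
                          t_loc, mit_loc, active=active.astype(float),
                          substeps=self.config.ode_substeps)
        self.cohort.y[:, frozen] = y_before
        self.cohort.routes[:, frozen] = r_before

    def _fate_and_rules(self, klass: np.ndarray) -> None:
        pop = self.pop
        g = self.lattice.grid
        dtmin = self.config.mcs_minutes

        # fate checks for healthy hepatocytes, ascending id order
        healthy = (pop.alive[self.hep_ids]
                   & (pop.state[self.hep_ids] == geo.HEALTHY))
        rows = np.flatnonzero(healthy)
        if len(rows):
            events = intra.check_fate(self.cohort["C"][rows],
                                      self.cohort["K"][rows], self.rng,
                                      self.params.fate, self.p_necrosis)
            for r, ev in zip(rows, events):
                cid = int(self.hep_ids[r])
                if ev == intra.EVENT_NECROSIS:
                    pop.state[cid] = geo.NECROTIC
                    self._log("necrosis", cid)
                elif ev == intra.EVENT_SENESCENCE:
                    pop.state[cid] = geo.SENESCENT
                    self._log("senescence", cid)
                elif ev == intra.EVENT_PROLIFERATION:
                    daughter = self.lattice.divide_cell(cid, self.rng)
                    if daughter is not None:
                        self.hep_ids = np.append(self.hep_ids, daughter)
                        ycopy = self.cohort.y[:, r].copy()
                        rcopy = self.cohort.routes[:, r].copy()
                        self.cohort.y = np.column_stack([self.cohort.y, ycopy])
                        self.cohort.routes = np.column_stack(
                            [self.cohort.routes, rcopy])
                        self.cohort.P450 = np.append(self.cohort.P450,
                                                     self.cohort.P450[r])
                        self.cohort.b_GSH = np.append(self.cohort.b_GSH,
                                                      self.cohort.b_GSH[r])
                        self.cohort.n += 1
                        self.cumulative_proliferation += 1
                        self.proliferated[daughter] = True
                        self.proliferated[cid] = True
                        self._log("proliferation", cid)

        # contact timers
        klass = pop.contact_class()
        nec_ids = pop.ids_of(geo.HEPATOCYTE, geo.NECROTIC)
        sen_ids = pop.ids_of(geo.HEPATOCYTE, geo.SENESCENT)
        mphi_ids = pop.ids_of(geo.MACROPHAGE)
        nec_adj = imm.cells_adjacent_to(g, klass, nec_ids, geo.CLASS_MACROPHAGE)
        sen_adj = imm.cells_adjacent_to(g, klass, sen_ids, geo.CLASS_MACROPHAGE)
        in_contact = np.concatenate([nec_ids[nec_adj], sen_ids[sen_adj]])
        self.timers.tick(in_contact.astype(int), mphi_ids.astype(int), dtmin)

        ip = self.params.immune
        for cid, adj in zip(nec_ids, nec_adj):
            if imm.phagocytose(self.timers.contact_min[cid], bool(adj), ip,
                               self.rng):
                self._remove(int(cid), "phagocytosis")
        for cid, adj in zip(sen_ids, sen_adj):
            if imm.clear_senescent(self.timers.contact_min[cid], bool(adj), ip,
                                   self.rng):
                self._remove(int(cid), "senescent_clearance")

        # the recruitment / retreat rules read a 1 h running mean of the
        # periportal MCP-1 so single-MCS producer flicker cannot trip the
        # 10%-below-maximum stop rule during the build-up phase
        raw = float(self.fields["MCP1"].grid[self.layout.periportal_mask].mean())
        self._mcp1_history.append(raw)
        if len(self._mcp1_history) > 12:
            self._mcp1_history.pop(0)
        pp_mcp1 = float(np.mean(self._mcp1_history))
        new_mphi = imm.recruit_macrophages(
            g, pop, self.layout, self.recruit_state, pp_mcp1, ip, self.rng,
            p_recruit=self.p_recruit)
        for cid in new_mphi:
            self._log("recruit", cid)
        for cid in pop.ids_of(geo.MACROPHAGE):
            if imm.retreat_macrophage(self.timers.age_min[cid], pp_mcp1, ip,
                                      self.rng):
                self._log("retreat", int(cid))
                self.lattice.remove_cell(int(cid))

    def _cpm_step(self) -> None:
        klass = self.pop.contact_class()
        ctx = cpm_mod.chemotaxis_context(self.lattice.grid, klass,
                                         self.pop.n_ids,
                                         self.layout.periportal_mask)
        zeroed = self.lattice.monte_carlo_step(
            self.rng, chemo=self.fields["MCP1"].grid, mu_ctx=ctx)
        self._handle_zero_area(zeroed)

    def _record_row(self) -> None:
        h, s, n = self._hep_state_counts()
        row = {
            "mcs": self.mcs,
            "time_h": round(self.time_h, 6),
            "healthy": h,
            "senescent": s,
            "necrotic": n,
            "macrophages": len(self.pop.ids_of(geo.MACROPHAGE)),
            "kupffer": len(self.pop.ids_of(geo.KUPFFER)),
            "prolif_cum": self.cumulative_proliferation,
            "cleared_cum": self.cumulative_cleared,
            "P_ex": self.plasma.P_ex if self.plasma else np.nan,
            "excreted_cum": self.plasma.cumulative_excreted if self.plasma else 0.0,
            "uptaken_cum": self.plasma.cumulative_taken_up if self.plasma else 0.0,
            "periportal_mcp1": float(
                self.fields["MCP1"].grid[self.layout.periportal_mask].mean()),
            "damp_max": float(self.fields["DAMP"].grid.max()),
            "tgfb_max": float(self.fields["TGFB"].grid.max()),
            "mit_mean": float(self.fields["MIT"].grid.mean()),
        }
        self._rows.append(row)

    def step(self) -> None:
        """One post-exposure MCS in the documented order."""
        for ev in self._therapies:
            if not ev.applied and self.time_h >= ev.time_h:
                from .perturb import apply_therapy
                apply_therapy(self, ev)
                self._log("therapy", 0, ev.drug)
        klass = self.pop.contact_class()
        n_alive = int(self.alive_hepatocyte_mask().sum())
        self.plasma.step(n_alive, self.config.dt_h)
        self._field_step(klass)
        self._ode_step(klass)
        self._fate_and_rules(klass)
        self._cpm_step()
        self.mcs += 1
        self._record_row()
        if not np.all(np.isfinite(self.cohort.y)):
            raise RuntimeError(
                f"non-finite intracellular state at MCS {self.mcs}")

    def run(self) -> SimulationRecord:
        self.initialize()
        for _ in range(self.config.n_mcs):
            self.step()
        return self.record()

    def record(self) -> SimulationRecord:
        ts = pd.DataFrame(self._rows)
        ev = pd.DataFrame(self._events, columns=[
            "mcs", "time_h", "event", "cell_id", "i", "j", "cause"])
        n = self.pop.n_ids
        cells = pd.DataFrame({
            "cell_id": np.arange(n),
            "cell_type": self.pop.cell_type[:n],
            "state": self.pop.state[:n],
            "alive": self.pop.alive[:n],
            "area": self.pop.area[:n],
            "distance_um": self.pop.distance_um[:n],
            "proliferated": self.proliferated[:n],
        })
        types = self.pop.contact_class()[self.lattice.grid]
        return SimulationRecord(ts, ev, self.config.to_dict(), self.seed,
                                final_grid=self.lattice.grid.copy(),
                                final_types=types, cell_table=cells)

    def cell_state_table(self) -> pd.DataFrame:
        """Tidy per-hepatocyte intracellular state at the current time."""
        ids = self.hep_ids
        d = {"time_h": self.time_h, "cell_id": ids,
             "distance_um": self.pop.distance_um[ids]}
        for k, v in enumerate(intra.STATE_VARS):
            d[v] = self.cohort.y[k]
        d["P450"] = self.cohort.P450
        d["state"] = self.pop.state[ids]
        return pd.DataFrame(d)


def run_simulation(config: RunConfig, seed: int | None = None,
                   params: ModelParams | None = None) -> SimulationRecord:
    """Execute one full run and return its record."""
    return Simulation(config, seed=seed, params=params).run()


def run_metabolism_cohort(dose: float, hours: float, seed: int = 0,
                          n_hepatocytes: int = 600,
                          zonation_mode: str = "both",
                          params: ModelParams | None = None):
    """Desk-scale run of the zonated metabolism for a full hepatocyte cohort.

    Builds the lobule geometry (for realistic porto-central positions),
    couples every hepatocyte to the shared plasma pool and integrates the
    intracellular system without the lattice dynamics.  Returns
    ``(cohort, pool)`` after ``hours`` of APAP exposure.
    """
    from .fields import PlasmaPool

    params = (params or ModelParams()).copy()
    layout = geo.LobuleLayout()
    scenario = geo.ZonationScenario(mode=zonation_mode,
                                    axis_length_um=layout.axis_length_um)
    rng = np.random.default_rng(seed)
    grid, pop, hep_ids, _ = geo.build_lobule(layout, n_hepatocytes, 0, rng,
                                             scenario)
    gsh0 = np.zeros(len(hep_ids))
    p450 = np.zeros(len(hep_ids))
    for k, cid in enumerate(hep_ids):
        gsh0[k], p450[k] = geo.initial_zonation(pop.distance_um[cid], scenario)
    cohort = intra.HepatocyteCohort(gsh0, p450, params)
    pool = PlasmaPool(dose, params.plasma.k_u, params.plasma.k_e)
    dt = 5 / 60
    for _ in range(int(round(hours / dt))):
        p_local = pool.P_ex
        pool.step(n_hepatocytes, dt)
        intra.step_cohort(cohort, dt, p_local, 0.0, 0.0, substeps=10)
    return cohort, pool


def elimination_route_fractions(cohort) -> dict[str, float]:
    """Percentage of eliminated APAP per route, summed over the cohort.

    The oxidation route counts everything that passed through NAPQI
    (GSH conjugates, protein adducts and the current NAPQI pool).
    """
    gluc = cohort.route("glucuronidated").sum()
    sulf = cohort.route("sulfated").sum()
    ox = cohort.route("oxidized").sum()
    total = gluc + sulf + ox
    return {"glucuronidation": 100 * gluc / total,
            "sulfation": 100 * sulf / total,
            "oxidation": 100 * ox / total}


def summarize(records: list[SimulationRecord]) -> pd.DataFrame:
    """Per-condition summary statistics across replicate records.

    Onset is the first post-exposure time with a positive necrotic count;
    clearance the first later time at which it returns to zero.  Undefined
    statistics (e.g. onset without necrosis) are reported as NaN, never 0.
    """
    if not records:
        raise ValueError("need at least one record")
    rows = []
    for rec in records:
        ts = rec.timeseries
        post = ts[ts.time_h >= 0]
        nec = post[post.necrotic > 0]
        onset = nec.time_h.iloc[0] if len(nec) else np.nan
        clearance = np.nan
        if len(nec):
            after = post[(post.time_h > onset) & (post.necrotic == 0)]
            clearance = after.time_h.iloc[0] if len(after) else np.nan

        def at(col, t):
            sub = post[post.time_h >= t]
            return sub[col].iloc[0] if len(sub) else np.nan

        total_end = at("healthy", 168.0) + at("senescent", 168.0)
        rows.append({
            "seed": rec.seed,
            "onset_h": onset,
            "clearance_h": clearance,
            "necrotic_14h": at("necrotic", 14.0),
            "senescent_48h": at("senescent", 48.0),
            "healthy_168h": at("healthy", 168.0),
            "senescent_168h": at("senescent", 168.0),
            "healthy_prop_168h": (at("healthy", 168.0)
                                  / rec.config["n_hepatocytes"]),
            "alive_168h": total_end,
            "prolif_cum": post.prolif_cum.iloc[-1] if len(post) else np.nan,
        })
    return pd.DataFrame(rows)
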