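"""Immunosurveillance rules: Kupffer-cell activation, macrophage
recruitment, secretion contexts, phagocytosis of necrotic cells and
clearance of senescent cells.

Kupffer cells sensing DAMPs above threshold secrete MCP-1; once the mean
periportal MCP-1 exceeds the recruitment threshold, macrophages enter as
single pixels next to the portal veins (one Bernoulli(0.5) attempt per PV
per MCS) until the periportal MCP-1 has dropped 10% below its running
maximum, after which recruitment is permanently disarmed.  Contact timers
accumulate cumulative (possibly non-contiguous) minutes of macrophage
adjacency per target cell and never reset; the printed clearance rules
additionally require current adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .params import ImmuneParams


class ContactTimers:
    """Cumulative contact minutes per cell id plus per-macrophage ages."""

    def __init__(self, capacity: int = 2048):
        self.contact_min = np.zeros(capacity, dtype=np.float64)
        self.age_min = np.zeros(capacity, dtype=np.float64)

    def _ensure(self, n: int) -> None:
        if n > len(self.contact_min):
            grow = max(n, 2 * len(self.contact_min))
            for name in ("contact_min", "age_min"):
                arr = getattr(self, name)
                new = np.zeros(grow, dtype=np.float64)
                new[: len(arr)] = arr
                setattr(self, name, new)

    def tick(self, in_contact_ids: np.ndarray, macrophage_ids: np.ndarray,
             minutes: float) -> None:
        n = 1 + max(
            int(in_contact_ids.max()) if len(in_contact_ids) else 0,
            int(macrophage_ids.max()) if len(macrophage_ids) else 0,
        )
        self._ensure(n)
        if len(in_contact_ids):
            self.contact_min[in_contact_ids] += minutes
        if len(macrophage_ids):
            self.age_min[macrophage_ids] += minutes


@dataclass
class RecruitmentState:
    """Running bookkeeping for the macrophage recruitment stop rule."""

    m_max: float = 0.0
    armed: bool = False
    stopped: bool = False

    def update(self, periportal_mcp1: float, params: ImmuneParams) -> bool:
        """Returns whether recruitment is currently allowed."""
        if self.stopped:
            return False
        if periportal_mcp1 > params.mcp1_recruit_threshold:
            self.armed = True
        if self.armed:
            self.m_max = max(self.m_max, periportal_mcp1)
            if periportal_mcp1 < params.recruit_stop_fraction * self.m_max:
                self.stopped = True
                return False
        return self.armed and periportal_mcp1 > params.mcp1_recruit_threshold


def update_kupffer(damp_local: float, params: ImmuneParams) -> bool:
    """A KC secretes MCP-1 iff its mean footprint DAMP exceeds 0.5 a.u."""
    return damp_local > params.damp_activation_threshold


def recruit_macrophages(grid, pop: geo.CellPopulation, layout,
                        recruit_state: RecruitmentState,
                        periportal_mcp1: float, params: ImmuneParams,
                        rng: np.random.Generator,
                        p_recruit: float | None = None) -> list[int]:
    """Seed new single-pixel macrophages next to the portal veins.

    One attempt per PV region per MCS, each succeeding with probability
    0.5, while the mean periportal MCP-1 exceeds 1e-4 a.u. and the stop
    rule has not disarmed recruitment.  Attempts without a free periportal
    pixel are skipped.
    """
    p = params.p_recruit if p_recruit is None else p_recruit
    if not recruit_state.update(periportal_mcp1, params):
        return []
    new_ids = []
    for submask in layout.periportal_submasks:
        if rng.random() >= p:
            continue
        free = np.argwhere(submask & (grid == 0))
        if len(free) == 0:
            continue
        i, j = free[rng.integers(0, len(free))]
        cid = pop.new_cell(geo.MACROPHAGE, geo.MACROPHAGE_TARGET_AREA)
        grid[i, j] = cid
        pop.area[cid] = 1
        new_ids.append(cid)
    return new_ids


def adjacency_to_type(grid: np.ndarray, klass: np.ndarray,
                      contact_class: int) -> np.ndarray:
    """Boolean grid: pixels within the Moore neighbourhood of the class."""
    sel = klass[grid] == contact_class
    return geo._dilate(sel)


def cells_adjacent_to(grid: np.ndarray, klass: np.ndarray, cell_ids,
                      contact_class: int) -> np.ndarray:
    """Which of ``cell_ids`` have >= 1 pixel Moore-adjacent to the class."""
    cell_ids = np.asarray(cell_ids, dtype=int)
    if len(cell_ids) == 0:
        return np.zeros(0, dtype=bool)
    near = adjacency_to_type(grid, klass, contact_class)
    hits = np.bincount(grid[near].ravel(), minlength=int(grid.max()) + 1)
    sel = cell_ids < len(hits)
    out = np.zeros(len(cell_ids), dtype=bool)
    out[sel] = hits[cell_ids[sel]] > 0
    return out


def macrophage_secretion_context(grid, klass, macrophage_ids) -> np.ndarray:
    """TGF-beta producer flags: macrophages touching a necrotic neighbourhood.

    Every macrophage is a mitogen producer; it additionally produces
    TGF-beta iff any of its pixels lies in the Moore neighbourhood of a
    necrotic cell's pixel.
    """
    return cells_adjacent_to(grid, klass, macrophage_ids,
                             geo.CLASS_HEP_NECROTIC)


def phagocytose(contact_min: float, currently_adjacent: bool,
                params: ImmuneParams, rng: np.random.Generator) -> bool:
    """Clearance decision for one necrotic cell at one MCS."""
    if contact_min <= params.phagocytosis_contact_min or not currently_adjacent:
        return False
    return rng.random() < params.p_phagocytosis


def clear_senescent(contact_min: float, currently_adjacent: bool,
                    params: ImmuneParams, rng: np.random.Generator) -> bool:
    """Clearance decision for one senescent cell at one MCS."""
    if contact_min <= params.senescent_contact_min or not currently_adjacent:
        return False
    return rng.random() < params.p_senescent_clear


def retreat_macrophage(age_min: float, periportal_mcp1: float,
                       params: ImmuneParams, rng: np.random.Generator) -> bool:
    """Stochastic disappearance of an aged macrophage once MCP-1 is low."""
    if age_min <= params.retreat_age_min:
        return False
    if periportal_mcp1 >= params.retreat_mcp1_threshold:
        return False
    return rng.random() < params.p_retreat
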