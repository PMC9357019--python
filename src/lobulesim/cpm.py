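"""Cellular Potts dynamics: Metropolis pixel-copy attempts on the cell-id
lattice, with adhesion + area-constraint energies and context-dependent
chemotaxis for macrophages.

One Monte Carlo step (MCS, 5 simulated minutes) performs as many elementary
copy attempts as there are non-vein lattice sites inside the lobule.  An
attempt copies the id of a random Moore neighbour onto a random site and is
accepted with probability 1 if the energy change is negative, else
exp(-dH/T).  Vein pixels (and the exterior wall) are immutable; necrotic
cells are immotile (they neither extend nor get displaced).  The Moore
(8-neighbour) order is used both for contact energies and copy attempts.

The hot loop is compiled with numba; all randomness is drawn from the
run's numpy Generator outside the kernel so runs are bitwise reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import geometry as geo
from .params import CpmParams

# Moore neighbourhood offsets
_OFFS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

# context codes for the macrophage chemotaxis strength
CTX_DEFAULT = 0
CTX_PERIPORTAL = 1
CTX_NEAR_NECROTIC = 2


@njit(cache=True)
def _delta_h(grid, klass, J, lam, area, target_area, i, j, ni, nj):
    """Energy change of copying grid[ni, nj] onto grid[i, j] (no chemotaxis)."""
    old = grid[i, j]
    src = grid[ni, nj]
    ko = klass[old]
    ks = klass[src]
    dh = 0.0
    h, w = grid.shape
    for k in range(8):
        mi = i + _OFFS[k, 0]
        mj = j + _OFFS[k, 1]
        if mi < 0 or mj < 0 or mi >= h or mj >= w:
            continue
        m = grid[mi, mj]
        km = klass[m]
        if m != src:
            dh += J[ks, km]
        if m != old:
            dh -= J[ko, km]
    if src != 0:
        a = area[src]
        A = target_area[src]
        dh += lam[ks] * ((a + 1.0 - A) ** 2 - (a - A) ** 2)
    if old != 0:
        a = area[old]
        A = target_area[old]
        dh += lam[ko] * ((a - 1.0 - A) ** 2 - (a - A) ** 2)
    return dh


@njit(cache=True)
def _run_mcs(grid, klass, J, lam, area, target_area, T,
             sites_i, sites_j, site_pick, neigh_pick, urand,
             chemo, mu_ctx, mu_default, mu_periportal, mu_near_necrotic,
             zero_buf):
    """One MCS; returns the number of cells driven to zero area."""
    nzero = 0
    h, w = grid.shape
    for t in range(site_pick.shape[0]):
        s = site_pick[t]
        i = sites_i[s]
        j = sites_j[s]
        old = grid[i, j]
        ko = klass[old]
        if ko == geo.CLASS_VEIN or ko == geo.CLASS_HEP_NECROTIC:
            continue
        ni = i + _OFFS[neigh_pick[t], 0]
        nj = j + _OFFS[neigh_pick[t], 1]
        if ni < 0 or nj < 0 or ni >= h or nj >= w:
            continue
        src = grid[ni, nj]
        if src == old:
            continue
        ks = klass[src]
        if ks == geo.CLASS_VEIN or ks == geo.CLASS_HEP_NECROTIC:
            continue
        dh = _delta_h(grid, klass, J, lam, area, target_area, i, j, ni, nj)
        if ks == geo.CLASS_MACROPHAGE:
            ctx = mu_ctx[src]
            if ctx == CTX_NEAR_NECROTIC:
                mu = mu_near_necrotic
            elif ctx == CTX_PERIPORTAL:
                mu = mu_periportal
            else:
                mu = mu_default
            dh -= mu * (chemo[i, j] - chemo[ni, nj])
        if dh < 0.0 or urand[t] < np.exp(-dh / T):
            grid[i, j] = src
            if src != 0:
                area[src] += 1
            if old != 0:
                area[old] -= 1
                if area[old] == 0:
                    zero_buf[nzero] = old
                    nzero += 1
    return nzero


def attempt_copy(delta_h: float, temperature: float,
                 rng: np.random.Generator) -> bool:
    """Metropolis acceptance: certain for dH < 0, else exp(-dH/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_h < 0:
        return True
    return rng.random() < np.exp(-delta_h / temperature)


def delta_hamiltonian(grid, klass, params: CpmParams, area, target_area,
                      source_site, target_site, chemo=None, mu_ctx=None):
    """Energy change of copying the source pixel's id onto the target site.

    Mirrors the kernel exactly (it calls the same compiled routine) and adds
    the macrophage chemotaxis term when a concentration grid is supplied.
    """
    si, sj = source_site
    ti, tj = target_site
    if grid[si, sj] == grid[ti, tj]:
        raise ValueError("source and target belong to the same cell")
    lam = np.asarray(params.lambda_area, dtype=np.float64)
    dh = _delta_h(grid, klass, params.J, lam, area, target_area, ti, tj, si, sj)
    if chemo is not None and klass[grid[si, sj]] == geo.CLASS_MACROPHAGE:
        ctx = CTX_DEFAULT if mu_ctx is None else mu_ctx[grid[si, sj]]
        mu = {CTX_DEFAULT: params.mu_default,
              CTX_PERIPORTAL: params.mu_periportal,
              CTX_NEAR_NECROTIC: params.mu_near_necrotic}[int(ctx)]
        dh -= mu * (chemo[ti, tj] - chemo[si, sj])
    return dh


def hamiltonian(grid, klass, params: CpmParams, target_area) -> float:
    """Full lattice energy (adhesion + area constraint), brute force.

    Each unordered Moore-neighbour pair contributes once.  Used as the
    independent oracle for the incremental energy computation.
    """
    J = params.J
    lam = np.asarray(params.lambda_area, dtype=np.float64)
    h_adh = 0.0
    g = grid
    kg = klass[g]
    # pairs counted once: right, down, down-right, down-left
    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = g[max(0, -di): g.shape[0] - max(0, di) or None,
              max(0, -dj): g.shape[1] - max(0, dj) or None]
        b = g[max(0, di): g.shape[0] - max(0, -di) or None,
              max(0, dj): g.shape[1] - max(0, -dj) or None]
        ka = klass[a]
        kb = klass[b]
        h_adh += (J[ka, kb] * (a != b)).sum()
    ids, counts = np.unique(g, return_counts=True)
    h_area = 0.0
    for cid, a in zip(ids, counts):
        if cid == 0:
            continue
        h_area += lam[klass[cid]] * (a - target_area[cid]) ** 2
    return float(h_adh + h_area)


class CpmLattice:
    """Cell-id grid plus cached per-cell areas and the eligible-site list."""

    def __init__(self, grid: np.ndarray, population: geo.CellPopulation,
                 params: CpmParams, domain_mask: np.ndarray,
                 vein_mask: np.ndarray):
        self.grid = grid
        self.pop = population
        self.params = params
        sites = np.argwhere(domain_mask & ~vein_mask)
        self.sites_i = np.ascontiguousarray(sites[:, 0])
        self.sites_j = np.ascontiguousarray(sites[:, 1])
        self.n_attempts = len(sites)
        self._lam = np.asarray(params.lambda_area, dtype=np.float64)
        self._zero_buf = np.zeros(4096, dtype=np.int64)

    def check_consistency(self) -> None:
        """Raise if the cached areas and the grid disagree (tested contract)."""
        counts = np.bincount(self.grid.ravel(), minlength=self.pop.n_ids)
        cached = self.pop.area[: self.pop.n_ids]
        # id 0 is medium and carries no cached area
        if not np.array_equal(counts[1: self.pop.n_ids], cached[1:]):
            raise RuntimeError("area cache desynchronized from the lattice")

    def monte_carlo_step(self, rng: np.random.Generator,
                         chemo: np.ndarray | None = None,
                         mu_ctx: np.ndarray | None = None) -> list[int]:
        """One MCS of ``n_attempts`` random copy attempts.

        Returns ids of cells that reached zero area (to be removed by the
        caller).  ``chemo`` is the MCP-1 grid sensed by macrophages and
        ``mu_ctx`` the per-pixel chemotaxis-context code grid.
        """
        n = self.n_attempts
        site_pick = rng.integers(0, n, size=n)
        neigh_pick = rng.integers(0, 8, size=n)
        urand = rng.random(n)
        if chemo is None:
            chemo = np.zeros(self.grid.shape)
        if mu_ctx is None:
            mu_ctx = np.zeros(self.pop.n_ids, dtype=np.uint8)
        klass = self.pop.contact_class()
        p = self.params
        nzero = _run_mcs(
            self.grid, klass, p.J, self._lam,
            self.pop.area, self.pop.target_area, p.temperature,
            self.sites_i, self.sites_j, site_pick, neigh_pick, urand,
            np.asarray(chemo, dtype=np.float64), mu_ctx,
            p.mu_default, p.mu_periportal, p.mu_near_necrotic,
            self._zero_buf,
        )
        return [int(c) for c in self._zero_buf[:nzero]]

    def pixels_of(self, cell_id: int) -> np.ndarray:
        return np.argwhere(self.grid == cell_id)

    def remove_cell(self, cell_id: int) -> int:
        """Empty the cell's pixels to medium; returns the freed pixel count."""
        pix = self.grid == cell_id
        n = int(pix.sum())
        self.grid[pix] = 0
        self.pop.area[cell_id] = 0
        self.pop.alive[cell_id] = False
        return n

    def divide_cell(self, cell_id: int, rng: np.random.Generator) -> int | None:
        """Split a cell along a random line through its centroid.

        Both daughters keep the parent's type and a healthy state; the new
        daughter gets a fresh id.  Returns the daughter id, or None when the
        cell has fewer than 2 pixels (division skipped).
        """
        pix = self.pixels_of(cell_id)
        if len(pix) < 2:
            return None
        centroid = pix.mean(axis=0)
        theta = rng.uniform(0.0, np.pi)
        normal = np.array([np.sin(theta), np.cos(theta)])
        side = (pix - centroid) @ normal
        first = side <= 0.0  # ties go to the first daughter (the parent)
        if first.all() or not first.any():
            order = np.argsort(side, kind="stable")
            first = np.zeros(len(pix), dtype=bool)
            first[order[: len(pix) // 2]] = True
        pop = self.pop
        daughter = pop.new_cell(
            pop.cell_type[cell_id],
            pop.target_area[cell_id],
            state=geo.HEALTHY,
            distance_um=pop.distance_um[cell_id],
        )
        dpix = pix[~first]
        self.grid[dpix[:, 0], dpix[:, 1]] = daughter
        pop.area[daughter] = len(dpix)
        pop.area[cell_id] = int(first.sum())
        pop.state[cell_id] = geo.HEALTHY
        return daughter


def necrotic_neighbourhood_mask(grid: np.ndarray,
                                klass: np.ndarray) -> np.ndarray:
    """Pixels lying in the Moore neighbourhood of any necrotic-cell pixel."""
    nec = klass[grid] == geo.CLASS_HEP_NECROTIC
    return geo._dilate(nec)


def chemotaxis_context(grid: np.ndarray, klass: np.ndarray, n_ids: int,
                       periportal_mask: np.ndarray) -> np.ndarray:
    """Per-cell chemotaxis context, re-evaluated once per MCS.

    A macrophage in the Moore neighbourhood of a necrotic cell uses the
    weak 'parked' strength; one still touching the periportal entry zone
    uses the strong exit strength; all others the default.  Near-necrotic
    context takes precedence.
    """
    ctx = np.zeros(n_ids, dtype=np.uint8)
    mphi = klass[grid] == geo.CLASS_MACROPHAGE
    pp_ids = np.unique(grid[mphi & periportal_mask])
    ctx[pp_ids] = CTX_PERIPORTAL
    near = necrotic_neighbourhood_mask(grid, klass)
    nn_ids = np.unique(grid[mphi & near])
    ctx[nn_ids] = CTX_NEAR_NECROTIC
    return ctx
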