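"""Extracellular species: the well-mixed plasma APAP pool and diffusing fields.

APAP in blood is treated as a single homogeneous pool (blood-flow mixing is
fast relative to the 5-min lattice step), drained by per-hepatocyte uptake
and renal excretion.  DAMPs, MCP-1, mitogens and TGF-beta are scalar
concentration grids obeying diffusion + production - first-order decay with
no-flux boundaries, advanced with an exact spectral (DCT) propagator of the
5-point discrete Laplacian, so the solver is unconditionally stable and
conserves mass exactly when decay is off.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.fft import dctn, idctn


@dataclass
class PlasmaPool:
    """Well-mixed extracellular APAP concentration P_ex (a.u.).

    ``k_u`` is the per-hepatocyte uptake rate constant and ``k_e`` renal
    excretion (both h^-1).  Mass balance dose = P_ex + excreted + taken_up
    holds to floating-point accuracy because each step uses the exact
    solution of the linear pool ODE.
    """

    dose: float
    k_u: float
    k_e: float
    P_ex: float = dfield(init=False)
    cumulative_excreted: float = 0.0
    cumulative_taken_up: float = 0.0

    def __post_init__(self):
        self.P_ex = float(self.dose)

    def step(self, n_hepatocytes_alive: int, dt: float) -> None:
        """Advance the pool by ``dt`` hours with the given uptake population."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        ktot = self.k_e + n_hepatocytes_alive * self.k_u
        if ktot <= 0:
            return
        removed = self.P_ex * (1.0 - np.exp(-ktot * dt))
        self.cumulative_excreted += removed * self.k_e / ktot
        self.cumulative_taken_up += removed * (n_hepatocytes_alive * self.k_u) / ktot
        self.P_ex -= removed

    @property
    def excreted_fraction(self) -> float:
        tot = self.cumulative_excreted + self.cumulative_taken_up
        return self.cumulative_excreted / tot if tot > 0 else float("nan")


class DiffusionField:
    """One scalar concentration grid with diffusion, decay and production.

    The semi-discrete system du/dt = D L u - d u (L the 5-point Neumann
    Laplacian) is diagonal in the DCT-II basis, so each substep applies the
    exact matrix exponential; production is added explicitly before the
    propagator (first-order splitting in the production term only).
    """

    def __init__(self, name: str, shape: tuple[int, int], diffusion: float,
                 decay: float, pixel_size: float):
        self.name = name
        self.diffusion = float(diffusion)  # um^2/h
        self.decay = float(decay)  # 1/h
        self.pixel_size = float(pixel_size)  # um
        self.grid = np.zeros(shape, dtype=np.float64)
        ny, nx = shape
        dx2 = self.pixel_size**2
        ey = (2.0 * np.cos(np.pi * np.arange(ny) / ny) - 2.0) / dx2
        ex = (2.0 * np.cos(np.pi * np.arange(nx) / nx) - 2.0) / dx2
        self._lap_eig = ey[:, None] + ex[None, :]  # eigenvalues of L (<= 0)

    def step(self, dt: float, production: np.ndarray | None = None,
             substeps: int = 1) -> None:
        """Advance by ``dt`` hours.  ``production`` is an a.u./h rate grid."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        dtn = dt / substeps
        lam = self.decay - self.diffusion * self._lap_eig  # >= 0
        prop = np.exp(-lam * dtn)
        if production is not None:
            # exact update for a source held constant over the substep:
            # u_hat <- u_hat*e^(-lam dt) + p_hat*(1-e^(-lam dt))/lam
            with np.errstate(divide="ignore", invalid="ignore"):
                gain = np.where(lam > 0, (1.0 - prop) / np.where(lam > 0, lam, 1.0), dtn)
            p_hat = dctn(np.asarray(production, dtype=np.float64),
                         type=2, norm="ortho")
        u = self.grid
        for _ in range(substeps):
            u_hat = dctn(u, type=2, norm="ortho")
            u_hat *= prop
            if production is not None:
                u_hat += p_hat * gain
            u = idctn(u_hat, type=2, norm="ortho")
        # spectral ringing can produce O(1e-16 * max) negatives; clip them
        np.maximum(u, 0.0, out=u)
        self.grid = u

    def add(self, amount: np.ndarray) -> None:
        """Instantaneous addition/removal (e.g., receptor exchange)."""
        self.grid += amount
        np.maximum(self.grid, 0.0, out=self.grid)

    @property
    def total_mass(self) -> float:
        return float(self.grid.sum())


def sample_local(field_grid: np.ndarray, pixels: np.ndarray) -> float:
    """Mean concentration over a cell's pixel footprint.

    ``pixels`` is an (n, 2) array of (i, j) coordinates; raises on empty
    footprints (cells are removed from the lattice before reaching 0 px).
    """
    if len(pixels) == 0:
        raise ValueError("cell has no pixels")
    return float(field_grid[pixels[:, 0], pixels[:, 1]].mean())


def mean_over_cells(field_grid: np.ndarray, grid: np.ndarray,
                    ids: np.ndarray) -> np.ndarray:
    """Vectorized per-cell footprint means for every id in ``ids``.

    Cells absent from the lattice yield NaN.
    """
    if len(ids) == 0:
        return np.zeros(0)
    flat_ids = grid.ravel()
    sums = np.bincount(flat_ids, weights=field_grid.ravel(),
                       minlength=int(flat_ids.max()) + 1)
    counts = np.bincount(flat_ids, minlength=int(flat_ids.max()) + 1)
    out = np.full(len(ids), np.nan)
    sel = ids < len(counts)
    nz = np.zeros(len(ids), dtype=bool)
    nz[sel] = counts[ids[sel]] > 0
    out[nz] = sums[ids[nz]] / counts[ids[nz]]
    return out
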