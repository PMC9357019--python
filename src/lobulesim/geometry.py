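"""Hexagonal liver-lobule geometry, vein placement, cell seeding and zonation.

The simulated domain is one hexagonal lobule on a square pixel lattice: a
central vein (CV) in the middle, six portal veins (PVs) at the hexagon
vertices, hepatocytes and Kupffer cells seeded in between.  Metabolic
zonation (glutathione rising, cytochrome P450 falling from the CV towards
the portal field) is expressed as a profile over the porto-central distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

# cell type codes
MEDIUM = 0
HEPATOCYTE = 1
KUPFFER = 2
MACROPHAGE = 3
VEIN = 4

# cell state codes (hepatocytes)
HEALTHY = 0
SENESCENT = 1
NECROTIC = 2

# contact classes used by the CPM energy (index into the J matrix)
CLASS_MEDIUM = 0
CLASS_VEIN = 1
CLASS_HEP_HEALTHY = 2
CLASS_HEP_SENESCENT = 3
CLASS_HEP_NECROTIC = 4
CLASS_KUPFFER = 5
CLASS_MACROPHAGE = 6
N_CLASSES = 7


class ConfigurationError(ValueError):
    """Raised when a run configuration is geometrically or logically invalid."""


def _disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _hexagon_mask(shape, center, circumradius):
    """Regular hexagon (flat axis along x) inscribed by its 6 vertices."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    # a point is inside iff it is on the inner side of all 6 edges
    verts = [
        (circumradius * math.sin(math.radians(60 * k)),
         circumradius * math.cos(math.radians(60 * k)))
        for k in range(6)
    ]
    inside = np.ones(shape, dtype=bool)
    for k in range(6):
        y0, x0 = verts[k]
        y1, x1 = verts[(k + 1) % 6]
        # edge normal pointing outward; keep points with non-positive projection
        ey, ex = y1 - y0, x1 - x0
        ny, nx = ex, -ey
        # orient normal outward (away from center)
        if ny * y0 + nx * x0 < 0:
            ny, nx = -ny, -nx
        proj = ny * (dy - y0) + nx * (dx - x0)
        inside &= proj <= 0
    return inside


@dataclass
class LobuleLayout:
    """Static geometry of one hexagonal lobule on a square pixel grid.

    Defaults give a 200 x 200 grid at 3 um/pixel with a hexagon of
    circumradius 95 px centered at (100, 100), a 14 px central vein and six
    5 px portal veins at the vertices, so that the rim-to-rim porto-central
    distance is (95 - 14 - 5) * 3 = 228 um.
    """

    grid_shape: tuple[int, int] = (200, 200)
    center: tuple[int, int] = (100, 100)
    hex_radius: float = 95.0
    cv_radius: float = 14.0
    pv_radius: float = 5.0
    pixel_size: float = 3.0  # um per pixel
    seed_radius: float = 80.0  # hepatocyte/KC seeding disc, px

    hexagon_vertices: np.ndarray = field(init=False, repr=False)
    cv_center: tuple[int, int] = field(init=False)
    pv_centers: np.ndarray = field(init=False, repr=False)
    domain_mask: np.ndarray = field(init=False, repr=False)
    cv_mask: np.ndarray = field(init=False, repr=False)
    pv_masks: list = field(init=False, repr=False)
    vein_mask: np.ndarray = field(init=False, repr=False)
    periportal_mask: np.ndarray = field(init=False, repr=False)
    periportal_submasks: list = field(init=False, repr=False)

    def __post_init__(self):
        cy, cx = self.center
        self.cv_center = (cy, cx)
        verts = np.array(
            [
                (
                    round(cy + self.hex_radius * math.sin(math.radians(60 * k))),
                    round(cx + self.hex_radius * math.cos(math.radians(60 * k))),
                )
                for k in range(6)
            ],
            dtype=int,
        )
        self.hexagon_vertices = verts
        self.pv_centers = verts.copy()
        hexmask = _hexagon_mask(self.grid_shape, self.center, self.hex_radius)
        self.cv_mask = _disc_mask(self.grid_shape, self.center, self.cv_radius)
        self.pv_masks = [
            _disc_mask(self.grid_shape, tuple(v), self.pv_radius) & hexmask
            for v in verts
        ]
        self.vein_mask = self.cv_mask.copy()
        for m in self.pv_masks:
            self.vein_mask |= m
        self.domain_mask = hexmask
        # periportal area: pixels directly (Moore-)adjacent to any PV
        self.periportal_submasks = []
        for m in self.pv_masks:
            grown = _dilate(m) & ~self.vein_mask & self.domain_mask
            self.periportal_submasks.append(grown)
        pp = np.zeros(self.grid_shape, dtype=bool)
        for m in self.periportal_submasks:
            pp |= m
        self.periportal_mask = pp

    @property
    def axis_length_um(self) -> float:
        """Rim-to-rim porto-central distance along the CV-vertex axis."""
        return (self.hex_radius - self.cv_radius - self.pv_radius) * self.pixel_size

    @classmethod
    def miniature(cls) -> "LobuleLayout":
        """A 60 x 60 fixture lobule used by the fast test suite."""
        return cls(
            grid_shape=(60, 60),
            center=(30, 30),
            hex_radius=28.0,
            cv_radius=4.0,
            pv_radius=2.0,
            pixel_size=3.0,
            seed_radius=24.0,
        )


def _dilate(mask: np.ndarray) -> np.ndarray:
    """Moore (8-neighbour) binary dilation."""
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    out[1:, 1:] |= mask[:-1, :-1]
    out[1:, :-1] |= mask[:-1, 1:]
    out[:-1, 1:] |= mask[1:, :-1]
    out[:-1, :-1] |= mask[1:, 1:]
    return out


def porto_central_distance(pixel: tuple[int, int], layout: LobuleLayout) -> float:
    """Distance (um) from the CV *rim* to a pixel, floored at zero.

    Raises ``ConfigurationError`` for pixels outside the lobule domain.
    """
    i, j = pixel
    if not (0 <= i < layout.grid_shape[0] and 0 <= j < layout.grid_shape[1]):
        raise ConfigurationError(f"pixel {pixel} outside the grid")
    if not layout.domain_mask[i, j]:
        raise ConfigurationError(f"pixel {pixel} outside the lobule domain")
    d_px = math.hypot(i - layout.cv_center[0], j - layout.cv_center[1]) - layout.cv_radius
    return max(d_px, 0.0) * layout.pixel_size


@dataclass
class ZonationScenario:
    """Initial GSH / P450 assignment along the porto-central axis.

    ``mode`` selects which gradients are active; inactive species take the
    flat mid-axis value (the printed intermediate levels 20.61 a.u. GSH and
    1.15 a.u. P450).  Default profiles are linear in normalized porto-central
    position and anchored so the mid-axis value equals the flat value; the
    GSH gradient has a larger relative span than the P450 gradient.
    Custom callables (distance_um -> value) may be injected instead.
    """

    mode: str = "both"  # both | gsh_only | p450_only | none
    flat_gsh: float = 20.61
    flat_p450: float = 1.15
    gsh_cv: float = 4.0     # GSH at the CV rim (a.u.)
    p450_cv: float = 1.65   # P450 at the CV rim (a.u.)
    axis_length_um: float = 228.0
    gsh_profile: Optional[Callable[[float], float]] = None
    p450_profile: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if self.mode not in ("both", "gsh_only", "p450_only", "none"):
            raise ConfigurationError(f"unknown zonation mode {self.mode!r}")

    # linear profiles anchored at the mid-axis flat value
    def _gsh(self, d: float) -> float:
        if self.gsh_profile is not None:
            return self.gsh_profile(d)
        x = min(max(d / self.axis_length_um, 0.0), 1.0)
        return self.gsh_cv + 2.0 * (self.flat_gsh - self.gsh_cv) * x

    def _p450(self, d: float) -> float:
        if self.p450_profile is not None:
            return self.p450_profile(d)
        x = min(max(d / self.axis_length_um, 0.0), 1.0)
        return self.p450_cv + 2.0 * (self.flat_p450 - self.p450_cv) * x


def initial_zonation(distance_um: float, scenario: ZonationScenario) -> tuple[float, float]:
    """Initial (GSH0, P4500) for a hepatocyte at the given porto-central distance."""
    if distance_um < 0:
        raise ConfigurationError("distance must be non-negative")
    gsh = scenario._gsh(distance_um) if scenario.mode in ("both", "gsh_only") else scenario.flat_gsh
    p450 = scenario._p450(distance_um) if scenario.mode in ("both", "p450_only") else scenario.flat_p450
    return gsh, p450


class CellPopulation:
    """Array-backed registry of all lattice entities (veins included).

    Cell ids are row indices; id 0 is reserved for medium (empty space).
    """

    def __init__(self, capacity: int = 2048):
        self.capacity = capacity
        self.cell_type = np.zeros(capacity, dtype=np.int8)
        self.state = np.zeros(capacity, dtype=np.int8)
        self.alive = np.zeros(capacity, dtype=bool)
        self.target_area = np.zeros(capacity, dtype=np.float64)
        self.area = np.zeros(capacity, dtype=np.int64)
        self.distance_um = np.full(capacity, np.nan)
        self.n_ids = 1  # id 0 = medium

    def _grow(self):
        cap = self.capacity * 2
        for name in ("cell_type", "state", "alive", "target_area", "area", "distance_um"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            if name == "distance_um":
                new[:] = np.nan
            new[: self.capacity] = arr
            setattr(self, name, new)
        self.capacity = cap

    def new_cell(self, cell_type: int, target_area: float, state: int = HEALTHY,
                 distance_um: float = np.nan) -> int:
        if self.n_ids >= self.capacity:
            self._grow()
        cid = self.n_ids
        self.n_ids += 1
        self.cell_type[cid] = cell_type
        self.state[cid] = state
        self.alive[cid] = True
        self.target_area[cid] = target_area
        self.area[cid] = 0
        self.distance_um[cid] = distance_um
        return cid

    def ids_of(self, cell_type: int, state: Optional[int] = None) -> np.ndarray:
        sel = self.alive[: self.n_ids] & (self.cell_type[: self.n_ids] == cell_type)
        if state is not None:
            sel &= self.state[: self.n_ids] == state
        return np.nonzero(sel)[0]

    def contact_class(self) -> np.ndarray:
        """Per-id contact class for the CPM J matrix (id 0 -> medium)."""
        n = self.n_ids
        cls = np.zeros(n, dtype=np.int8)
        t = self.cell_type[:n]
        s = self.state[:n]
        cls[t == VEIN] = CLASS_VEIN
        cls[(t == HEPATOCYTE) & (s == HEALTHY)] = CLASS_HEP_HEALTHY
        cls[(t == HEPATOCYTE) & (s == SENESCENT)] = CLASS_HEP_SENESCENT
        cls[(t == HEPATOCYTE) & (s == NECROTIC)] = CLASS_HEP_NECROTIC
        cls[t == KUPFFER] = CLASS_KUPFFER
        cls[t == MACROPHAGE] = CLASS_MACROPHAGE
        cls[0] = CLASS_MEDIUM
        return cls


# target areas (px), printed lobule composition
HEPATOCYTE_TARGET_AREA = 35.0
KUPFFER_TARGET_AREA = 3.5
MACROPHAGE_TARGET_AREA = 17.5


def build_lobule(
    layout: LobuleLayout,
    n_hepatocytes: int = 600,
    n_kupffer: int = 150,
    rng: np.random.Generator | int | None = None,
    scenario: ZonationScenario | None = None,
):
    """Seed the initial lobule: veins plus single-pixel hepatocytes and KCs.

    Cells are placed by rejection sampling of free non-vein pixels inside a
    disc of ``layout.seed_radius`` around the lattice center.  Returns
    ``(grid, population, hepatocyte_ids, kupffer_ids)`` where ``grid`` is the
    int32 cell-id lattice (exterior pixels carry the immobile wall cell id).
    """
    if n_hepatocytes < 0 or n_kupffer < 0:
        raise ConfigurationError("cell counts must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    pop = CellPopulation()
    grid = np.zeros(layout.grid_shape, dtype=np.int32)

    # wall: everything outside the hexagon (frozen, vein class)
    wall_id = pop.new_cell(VEIN, 0.0)
    grid[~layout.domain_mask] = wall_id
    pop.area[wall_id] = int((~layout.domain_mask).sum())
    cv_id = pop.new_cell(VEIN, 0.0)
    grid[layout.cv_mask] = cv_id
    pop.area[cv_id] = int(layout.cv_mask.sum())
    for m in layout.pv_masks:
        pv_id = pop.new_cell(VEIN, 0.0)
        grid[m] = pv_id
        pop.area[pv_id] = int(m.sum())

    seed_disc = _disc_mask(layout.grid_shape, layout.center, layout.seed_radius)
    candidates = seed_disc & layout.domain_mask & (grid == 0)
    coords = np.argwhere(candidates)
    n_total = n_hepatocytes + n_kupffer
    if n_total > len(coords):
        raise ConfigurationError(
            f"requested {n_total} cells but only {len(coords)} free seeding pixels"
        )
    # rejection sampling with Moore-neighbourhood exclusion: single-pixel
    # seeds never start adjacent, so no seed can be engulfed before growing
    order = rng.permutation(len(coords))
    taken = np.zeros(layout.grid_shape, dtype=bool)
    chosen = []
    for idx in order if n_total > 0 else []:
        i, j = coords[idx]
        if taken[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2].any():
            continue
        taken[i, j] = True
        chosen.append((i, j))
        if len(chosen) == n_total:
            break
    if len(chosen) < n_total:
        # fall back to plain sampling for the remainder (dense configs)
        free = [tuple(c) for c in coords if not taken[c[0], c[1]]]
        extra = rng.choice(len(free), size=n_total - len(chosen), replace=False)
        chosen.extend(free[e] for e in extra)
    chosen = np.array(chosen, dtype=int)

    scenario = scenario or ZonationScenario(axis_length_um=layout.axis_length_um)
    hep_ids, kc_ids = [], []
    for k, (i, j) in enumerate(chosen):
        if k < n_hepatocytes:
            d = porto_central_distance((i, j), layout)
            cid = pop.new_cell(HEPATOCYTE, HEPATOCYTE_TARGET_AREA, distance_um=d)
            hep_ids.append(cid)
        else:
            cid = pop.new_cell(KUPFFER, KUPFFER_TARGET_AREA)
            kc_ids.append(cid)
        grid[i, j] = cid
        pop.area[cid] = 1

    return grid, pop, np.array(hep_ids, dtype=int), np.array(kc_ids, dtype=int)
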