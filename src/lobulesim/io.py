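"""Record persistence and snapshot rendering.

Time series and event logs round-trip through CSV at full float precision;
lattice snapshots are exported as integer-labelled arrays (cell id and
type/state channels) and can be rendered to PNG with the standard colour
code: brown healthy hepatocytes, black necrotic, gray senescent, green
macrophages, blue Kupffer cells, red veins, orange proliferated cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from .driver import RunConfig, SimulationRecord

TIMESERIES_COLUMNS = [
    "mcs", "time_h", "healthy", "senescent", "necrotic", "macrophages",
    "kupffer", "prolif_cum", "cleared_cum", "P_ex", "excreted_cum",
    "uptaken_cum", "periportal_mcp1", "damp_max", "tgfb_max", "mit_mean",
]

STATE_COLORS = {
    "medium": (1.0, 1.0, 1.0),
    "vein": (0.80, 0.10, 0.10),
    "healthy": (0.55, 0.35, 0.17),
    "senescent": (0.60, 0.60, 0.60),
    "necrotic": (0.05, 0.05, 0.05),
    "kupffer": (0.25, 0.45, 0.85),
    "macrophage": (0.20, 0.65, 0.25),
    "proliferated": (0.95, 0.55, 0.10),
}

_CLASS_TO_NAME = {
    geo.CLASS_MEDIUM: "medium",
    geo.CLASS_VEIN: "vein",
    geo.CLASS_HEP_HEALTHY: "healthy",
    geo.CLASS_HEP_SENESCENT: "senescent",
    geo.CLASS_HEP_NECROTIC: "necrotic",
    geo.CLASS_KUPFFER: "kupffer",
    geo.CLASS_MACROPHAGE: "macrophage",
}


def write_outputs(record: SimulationRecord, outdir: str | Path,
                  snapshots: bool = False) -> Path:
    """Write timeseries.csv, events.csv, config.json (+ optional arrays)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record.timeseries.to_csv(outdir / "timeseries.csv", index=False,
                             float_format="%.17g")
    record.events.to_csv(outdir / "events.csv", index=False,
                         float_format="%.17g")
    meta = {"config": record.config, "seed": record.seed}
    (outdir / "config.json").write_text(json.dumps(meta, indent=2))
    if record.cell_table is not None:
        record.cell_table.to_csv(outdir / "cells.csv", index=False,
                                 float_format="%.17g")
    if snapshots and record.final_grid is not None:
        np.savez_compressed(outdir / "snapshot.npz",
                            cell_id=record.final_grid,
                            type_state=record.final_types)
    return outdir


def read_record(outdir: str | Path) -> SimulationRecord:
    """Inverse of :func:`write_outputs` (numeric fields to full precision)."""
    outdir = Path(outdir)
    _float_cols = ["time_h", "P_ex", "excreted_cum", "uptaken_cum",
                   "periportal_mcp1", "damp_max", "tgfb_max", "mit_mean"]
    ts = pd.read_csv(outdir / "timeseries.csv",
                     dtype={c: np.float64 for c in _float_cols})
    ev = pd.read_csv(outdir / "events.csv")
    if "cause" in ev.columns:
        ev["cause"] = ev["cause"].fillna("")
    meta = json.loads((outdir / "config.json").read_text())
    cells = None
    if (outdir / "cells.csv").exists():
        cells = pd.read_csv(outdir / "cells.csv")
    grid = types = None
    snap = outdir / "snapshot.npz"
    if snap.exists():
        with np.load(snap) as z:
            grid = z["cell_id"]
            types = z["type_state"]
    return SimulationRecord(ts, ev, meta["config"], meta["seed"],
                            final_grid=grid, final_types=types,
                            cell_table=cells)


def render_snapshot(type_state: np.ndarray,
                    proliferated_mask: np.ndarray | None = None) -> np.ndarray:
    """RGB image (H, W, 3 floats) from a type/state class grid."""
    img = np.ones(type_state.shape + (3,))
    for cls, name in _CLASS_TO_NAME.items():
        img[type_state == cls] = STATE_COLORS[name]
    if proliferated_mask is not None:
        sel = proliferated_mask & (type_state == geo.CLASS_HEP_HEALTHY)
        img[sel] = STATE_COLORS["proliferated"]
    return img


def save_png(img: np.ndarray, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), img)


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
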