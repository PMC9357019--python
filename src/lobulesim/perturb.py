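"""Model perturbations, timed in-silico therapies and parameter calibration.

Perturbations are pure parameter transforms applied at simulation start
(zonation scenario switches, MDM2-p53 feedback scaling, cyclin/CDK
regulation scaling, macrophage removal).  Therapies are instantaneous
events at a scheduled hour after APAP exposure: an NAC glutathione bolus,
4MP (P450 and p53-phosphorylation inhibition plus direct necrosis
suppression), pifithrin-alpha (p53 transcriptional inhibition with
amplified necrosis) and clodronate (Kupffer-cell depletion).

The calibration utility fits free rate constants to observable targets by
Latin-hypercube multistart followed by derivative-based least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .geometry import ConfigurationError
from .params import DdrParams, FateParams, ModelParams

#: printed multiplier sets used in the perturbation scans
MDM2_FEEDBACK_FACTORS = (0.01, 0.1, 1.0, 10.0, 100.0)
FATE_SCALE_FACTORS = (0.1, 0.125, 0.167, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

THERAPY_DEFAULT_TIMES_H = (3.0, 6.0, 12.0, 18.0, 24.0, 48.0)

# drug-specific effect constants
K_4MP_JNK = 0.2
K_4MP_P450 = 0.1
P_NECROSIS_4MP = 5e-5
K_PFT = 0.5
K_PFT_PHOS = 0.67
P_NECROSIS_PFT = 1.0
NAC_GSH_MULTIPLE = 2.0


@dataclass
class Perturbation:
    """A start-of-run model variation."""

    kind: str  # zonation_scenario | mdm2_feedback_scale | fate_param_scale | no_macrophages
    value: object = None
    which: str | None = None  # for fate_param_scale: k_inhib | k_mit | k_stim


@dataclass
class TherapyEvent:
    """One timed drug administration (hours after APAP exposure)."""

    drug: str  # NAC | 4MP | PFT | clodronate
    time_h: float
    applied: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.drug not in ("NAC", "4MP", "PFT", "clodronate"):
            raise ConfigurationError(f"unknown drug {self.drug!r}")


def apply_mdm2_feedback_scale(ddr: DdrParams, r: float) -> DdrParams:
    """Scale the MDM2-mediated degradation of p53 and phospho-p53 by ``r``."""
    if r <= 0:
        raise ValueError("feedback multiplier must be positive")
    from dataclasses import replace

    return replace(ddr, kd_p53_mdm2=ddr.kd_p53_mdm2 * r,
                   kd_p53p_mdm2=ddr.kd_p53p_mdm2 * r)


def apply_fate_scale(params: ModelParams, which: str, factor: float) -> ModelParams:
    """Scale one of the cyclin/CDK-regulating constants by ``factor``.

    The basal production b_K is defined by the steady-state constraint
    b_K = d_K*K_init + k_inhib*P21_init*K_init and is therefore re-derived
    with the scaled k_inhib: the unperturbed basal state must remain a
    fixed point, the perturbation changes the response to deviations.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    out = params.copy()
    if which == "k_inhib":
        out.fate.k_inhib *= factor
    elif which == "k_mit":
        out.fate.k_mit *= factor
    elif which == "k_stim":
        out.ddr.k_stim *= factor
    else:
        raise ConfigurationError(f"unknown fate constant {which!r}")
    return out


class TherapyError(ConfigurationError):
    pass


def apply_therapy(sim, event: TherapyEvent) -> None:
    """Apply one therapy to a running simulation, exactly once.

    ``sim`` is the simulation driver object; effects modify its parameter
    blocks and per-cell state in place and persist for the rest of the run.
    """
    if event.applied:
        raise TherapyError(f"{event.drug} at {event.time_h} h applied twice")
    cohort = sim.cohort
    alive = sim.alive_hepatocyte_mask()
    if event.drug == "NAC":
        bolus = NAC_GSH_MULTIPLE * sim.pre_exposure_max_gsh
        g = cohort["G"]
        g[alive] += bolus
        cohort["G"] = g
    elif event.drug == "4MP":
        sim.params.ddr.k_p *= K_4MP_JNK
        cohort.P450 *= K_4MP_P450
        sim.p_necrosis = P_NECROSIS_4MP
    elif event.drug == "PFT":
        sim.params.ddr.ks_mdm2_p53p *= K_PFT
        sim.params.ddr.ks_p21_p53p *= K_PFT
        sim.params.ddr.k_p *= K_PFT_PHOS
        cohort["P53p"] = cohort["P53p"] * K_PFT_PHOS
        sim.p_necrosis = P_NECROSIS_PFT
    elif event.drug == "clodronate":
        sim.deplete_kupffer_cells()
    event.applied = True


# ---------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationResult:
    best_params: np.ndarray
    residuals: np.ndarray
    cost: float
    starts: list = field(default_factory=list)


def calibrate(residual_fn: Callable[[np.ndarray], np.ndarray],
              bounds: Sequence[tuple[float, float]],
              rng: np.random.Generator | int | None = None,
              n_starts: int = 10) -> CalibrationResult:
    """Latin-hypercube multistart least-squares fit.

    ``residual_fn`` maps a parameter vector to weighted residuals against
    the observable targets; ``bounds`` are per-parameter (lo, hi).  Starts
    whose objective is non-finite are discarded.  All starts are returned
    for reproducibility.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    sampler = qmc.LatinHypercube(d=len(bounds),
                                 seed=int(rng.integers(0, 2**31 - 1)))
    starts = lo + sampler.random(n_starts) * (hi - lo)
    best = None
    log = []
    for x0 in starts:
        r0 = np.asarray(residual_fn(x0), dtype=float)
        if not np.all(np.isfinite(r0)):
            log.append((x0, None, np.inf))
            continue
        if np.allclose(r0, 0.0):
            # already a zero-residual point: the optimizer must not move it
            log.append((x0, x0, 0.0))
            if best is None or best.cost > 0:
                best = CalibrationResult(x0.copy(), r0, 0.0)
            continue
        try:
            sol = least_squares(residual_fn, x0, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            log.append((x0, None, np.inf))
            continue
        log.append((x0, sol.x, float(sol.cost)))
        if best is None or sol.cost < best.cost:
            best = CalibrationResult(sol.x, sol.fun, float(sol.cost))
    if best is None:
        raise RuntimeError("all calibration starts failed")
    best.starts = log
    return best
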