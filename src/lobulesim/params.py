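"""Parameter blocks for the lobule model, with calibrated defaults.

Printed constants (field parameters, fate thresholds, immune rules, therapy
effect sizes) are taken at face value.  Rate constants that are not printed
(APAP metabolism, the reduced p53/p21 module, CPM energies) carry defaults
calibrated by this package against the emergent read-outs the model is
known to reproduce: a ~2 h plasma half-life, a 2.4%/97.6% excretion/uptake
split, glucuronidation 80-85% / sulfation 5-10% / oxidation ~10% of
elimination at 6 h, pericentral-only adduct accumulation at dose 450, and
first necrosis between 6.25 and 11.25 h across doses 350-650 (decreasing
with dose).  See docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

LN2 = math.log(2.0)

#: plasma elimination rate constant giving a 2 h APAP half-life (h^-1)
PLASMA_ELIMINATION_RATE = LN2 / 2.0
#: number of hepatocytes the uptake split was calibrated for
REFERENCE_N_HEPATOCYTES = 600


@dataclass
class PlasmaParams:
    """Well-mixed APAP pool: per-hepatocyte uptake and renal excretion.

    Defaults split elimination 2.4% excretion / 97.6% uptake (600 cells) at
    a 2 h half-life.  ``partition`` converts the per-cell plasma draw into
    cytosolic concentration units (plasma-pool to single-cell volume ratio).
    """

    k_e: float = 0.024 * PLASMA_ELIMINATION_RATE
    k_u: float = 0.976 * PLASMA_ELIMINATION_RATE / REFERENCE_N_HEPATOCYTES
    partition: float = float(REFERENCE_N_HEPATOCYTES)

    @property
    def cell_uptake_rate(self) -> float:
        """Rate constant for cytosolic influx, k_uc = partition * k_u (h^-1)."""
        return self.partition * self.k_u


@dataclass
class MetabolismParams:
    """Hepatocellular APAP metabolism rate constants (h^-1 or a.u.^-1 h^-1).

    Glucuronidation (k_g) dominates, sulfation (k_s) is capacity-limited by
    the PAPS pool (steady state b_S/d_S), oxidation to NAPQI scales with the
    cell's static P450.  NAPQI is detoxified by GSH (k_GSH), slowly reverts
    to APAP (k_N) or binds protein cysteines (k_PSH); adducts decay at d_C.
    GSH replenishes towards its zonated set point with turnover d_GSH.
    """

    k_g: float = 2.0
    k_s: float = 0.025
    b_S: float = 30.0
    d_S: float = 3.0
    k_P450: float = 0.220789
    k_N: float = 0.01
    k_GSH: float = 2.0
    k_PSH: float = 0.01709
    d_GSH: float = 0.2
    d_C: float = 0.02

    @property
    def paps_steady_state(self) -> float:
        return self.b_S / self.d_S


@dataclass
class DdrParams:
    """Reduced p53 / phospho-p53 / MDM2 / p21 module (mRNA removed).

    With no adducts (C = 0) and no receptor occupancy (RT = 0) the system
    has the closed-form basal state P53p = 0, MDM2 = ks_mdm2/kd_mdm2,
    P53 = ks_p53/(kd_p53 + kd_p53_mdm2*MDM2), P21 = ks_p21/kd_p21, which is
    used as the initial condition.  p53 phosphorylation is proportional to
    NAPQI-cys (k_p * P53 * C); TGF-beta receptor occupancy adds the printed
    k_stim * RT production to p21.
    """

    ks_p53: float = 0.5
    k_dp: float = 0.5
    k_p: float = 0.0168
    kd_p53: float = 0.18
    kd_p53_mdm2: float = 0.02
    kd_p53p: float = 0.18
    kd_p53p_mdm2: float = 0.02
    ks_mdm2: float = 0.2
    ks_mdm2_p53p: float = 0.8
    Km_mdm2: float = 1.0
    kd_mdm2: float = 0.2
    ks_p21: float = 9.6e-4
    ks_p21_p53p: float = 1.2e-5
    Km_p21: float = 0.6
    kd_p21: float = 0.0032
    k_stim: float = 12.0e-6
    hill_n: int = 4

    def basal_state(self) -> dict[str, float]:
        mdm2 = self.ks_mdm2 / self.kd_mdm2
        return {
            "P53": self.ks_p53 / (self.kd_p53 + self.kd_p53_mdm2 * mdm2),
            "P53p": 0.0,
            "MDM2": mdm2,
            "P21": self.ks_p21 / self.kd_p21,
        }


@dataclass
class ReceptorParams:
    """TGF-beta receptor binding; R + RT = 1 is conserved."""

    k_on: float = 3.0  # a.u.^-1 h^-1
    k_off: float = 6.0  # h^-1


@dataclass
class FateParams:
    """Cyclin/CDK dynamics and the stochastic fate rules.

    The proliferation and senescence thresholds bracket a 7.25e-5-wide
    window around the initial cyclin/CDK level; the basal production b_K is
    derived from the steady-state constraint
    b_K = d_K*K_init + k_inhib*P21_init*K_init.
    """

    d_K: float = 3.35e-3  # h^-1
    k_mit: float = 6.24e-4  # h^-1
    k_inhib: float = 24.0  # a.u.^-1 h^-1
    K_initial: float = 4.68637375  # midpoint of the fate window
    prolif_threshold: float = 4.68641
    senesc_threshold: float = 4.6863375
    necrosis_threshold: float = 4.0  # NAPQI-cys level triggering necrosis
    p_necrosis: float = 0.8  # per fate check
    p_proliferation: float = 0.001  # per fate check

    def b_K(self, p21_initial: float) -> float:
        return self.d_K * self.K_initial + self.k_inhib * p21_initial * self.K_initial


@dataclass
class FieldParams:
    """Diffusion / decay / production constants of the extracellular fields."""

    D_damp: float = 216.0  # um^2/h
    d_damp: float = 1.2  # h^-1
    r_damp: float = 6.0  # a.u./h, per necrotic pixel
    D_mcp1: float = 27e3
    d_mcp1: float = 2.4
    r_mcp1: float = 900.0  # per secreting-KC pixel
    D_mit: float = 27e3
    d_mit: float = 3.24
    r_mit: float = 48.0  # per macrophage pixel
    D_tgfb: float = 27e3  # not printed; fast like MCP-1/mitogens (~87 um decay length)
    d_tgfb: float = 3.6
    t_macrophage: float = 2.4  # per macrophage pixel, near necrosis
    t_senescent: float = 0.12  # per senescent-hepatocyte pixel


@dataclass
class ImmuneParams:
    """Kupffer-cell activation, macrophage recruitment and clearance rules."""

    damp_activation_threshold: float = 0.5
    mcp1_recruit_threshold: float = 1e-4
    p_recruit: float = 0.5  # per PV per MCS
    recruit_stop_fraction: float = 0.9  # stop once periportal MCP-1 < 0.9*max
    phagocytosis_contact_min: float = 750.0
    p_phagocytosis: float = 0.1
    senescent_contact_min: float = 300.0
    p_senescent_clear: float = 0.45
    retreat_age_min: float = 1000.0
    retreat_mcp1_threshold: float = 1e-5
    p_retreat: float = 0.005


@dataclass
class CpmParams:
    """Cellular Potts energies: adhesion matrix J, area constraint, temperature.

    J is indexed by contact class (medium, vein, healthy/senescent/necrotic
    hepatocyte, Kupffer cell, macrophage).  Values are calibrated so cells
    stay cohesive and motile through the 96-MCS initialization and Kupffer
    cells (target area 3.5 px) essentially never vanish by chance.
    """

    temperature: float = 6.0
    lambda_area: tuple[float, ...] = (0.0, 0.0, 2.0, 2.0, 2.0, 100.0, 4.0)
    mu_periportal: float = 600.0
    mu_near_necrotic: float = 2.0
    mu_default: float = 100.0
    J: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.J is None:
            # classes: 0 medium, 1 vein, 2 hep-healthy, 3 hep-senescent,
            #          4 hep-necrotic, 5 KC, 6 macrophage
            M, V = 0, 1
            J = np.full((7, 7), 10.0)
            J[M, M] = 0.0
            J[M, V] = J[V, M] = 0.0
            J[V, V] = 0.0
            for a in range(2, 7):
                J[M, a] = J[a, M] = 3.0   # cell-medium surface tension
                J[V, a] = J[a, V] = 6.0   # weak affinity for vein walls
                for b in range(2, 7):
                    J[a, b] = 1.5         # heterotypic cell-cell contact
                J[a, a] = 1.0             # homotypic adhesion
            # macrophages adhere strongly to other cells (invasive migration
            # through packed tissue) and weakly to open medium
            for b in range(2, 6):
                J[6, b] = J[b, 6] = 0.0
            J[6, 6] = 1.0
            J[0, 6] = J[6, 0] = 5.0
            self.J = J
        else:
            self.J = np.asarray(self.J, dtype=np.float64)
        if self.J.shape != (7, 7) or not np.allclose(self.J, self.J.T):
            raise ValueError("J must be a symmetric 7x7 matrix")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ModelParams:
    """All parameter blocks of one simulation."""

    plasma: PlasmaParams = field(default_factory=PlasmaParams)
    metabolism: MetabolismParams = field(default_factory=MetabolismParams)
    ddr: DdrParams = field(default_factory=DdrParams)
    receptor: ReceptorParams = field(default_factory=ReceptorParams)
    fate: FateParams = field(default_factory=FateParams)
    fields: FieldParams = field(default_factory=FieldParams)
    immune: ImmuneParams = field(default_factory=ImmuneParams)
    cpm: CpmParams = field(default_factory=CpmParams)

    def copy(self) -> "ModelParams":
        return ModelParams(
            plasma=replace(self.plasma),
            metabolism=replace(self.metabolism),
            ddr=replace(self.ddr),
            receptor=replace(self.receptor),
            fate=replace(self.fate),
            fields=replace(self.fields),
            immune=replace(self.immune),
            cpm=replace(self.cpm, J=self.cpm.J.copy()),
        )


# default zonation endpoints (a.u.); linear profiles anchored so the
# mid-axis values equal the printed flat levels 20.61 (GSH) / 1.15 (P450),
# with a steeper relative GSH span than P450 span
GSH_CV_DEFAULT = 4.0
P450_CV_DEFAULT = 1.65
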