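"""Per-hepatocyte ODE systems and threshold-based fate checks.

Each hepatocyte carries 12 dynamic variables — intracellular APAP (P_in),
PAPS (S), NAPQI (N), GSH (G), NAPQI-cys adducts (C), the reduced DNA damage
response (P53, phospho-P53, MDM2, P21), TGF-beta receptor proportions
(R, RT) and the cyclin/CDK pool (K) — plus a static P450 level and
cumulative elimination-route integrals.  The whole cohort is integrated
jointly with a fixed-step classical Runge-Kutta scheme (vectorized over
cells); correctness is checked in the test suite against an adaptive-step
reference integrator.

Cell fate is read off thresholds: adducts above the necrosis threshold kill
the cell with probability 0.8 per check, a cyclin/CDK level above/below a
razor-thin window around its basal value triggers proliferation (p = 0.001
per check) or irreversible senescence (deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (DdrParams, FateParams, MetabolismParams, ModelParams,
                     ReceptorParams)

#: dynamic state variables, in integration order
STATE_VARS = ("P_in", "S", "N", "G", "C", "P53", "P53p", "MDM2", "P21", "R", "RT", "K")
ROUTE_VARS = ("glucuronidated", "sulfated", "gsh_conjugated", "adduct_formed",
              "napqi_reversed", "oxidized", "uptaken")
N_VARS = len(STATE_VARS)
N_ROUTES = len(ROUTE_VARS)

# fate events
EVENT_NONE = 0
EVENT_NECROSIS = 1
EVENT_SENESCENCE = 2
EVENT_PROLIFERATION = 3


class HepatocyteCohort:
    """State arrays for ``n`` hepatocytes integrated in lockstep."""

    def __init__(self, gsh0: np.ndarray, p450: np.ndarray, params: ModelParams):
        gsh0 = np.atleast_1d(np.asarray(gsh0, dtype=np.float64))
        p450 = np.atleast_1d(np.asarray(p450, dtype=np.float64))
        if gsh0.shape != p450.shape:
            raise ValueError("gsh0 and p450 must have the same length")
        n = len(gsh0)
        self.n = n
        self.params = params
        self.P450 = p450.copy()
        self.b_GSH = params.metabolism.d_GSH * gsh0  # zonated set point
        self.y = np.zeros((N_VARS, n))
        basal = params.ddr.basal_state()
        self.y[STATE_VARS.index("S")] = params.metabolism.paps_steady_state
        self.y[STATE_VARS.index("G")] = gsh0
        self.y[STATE_VARS.index("P53")] = basal["P53"]
        self.y[STATE_VARS.index("MDM2")] = basal["MDM2"]
        self.y[STATE_VARS.index("P21")] = basal["P21"]
        self.y[STATE_VARS.index("R")] = 1.0
        self.y[STATE_VARS.index("K")] = params.fate.K_initial
        self.routes = np.zeros((N_ROUTES, n))
        self.b_K = params.fate.b_K(basal["P21"])

    def __getitem__(self, var: str) -> np.ndarray:
        return self.y[STATE_VARS.index(var)]

    def __setitem__(self, var: str, value) -> None:
        self.y[STATE_VARS.index(var)] = value

    def route(self, name: str) -> np.ndarray:
        return self.routes[ROUTE_VARS.index(name)]


def _rhs(y, routes_unused, P450, b_GSH, b_K, P_local, T_local, MIT_local,
         mp: MetabolismParams, dp: DdrParams, rp: ReceptorParams,
         fp: FateParams, k_uc: float, active):
    """Joint right-hand side; returns (dy, droutes)."""
    P_in, S, N, G, C, P53, P53p, MDM2, P21, R, RT, K = y

    influx = k_uc * P_local * active * np.ones_like(P_in)
    sulf = mp.k_s * S * P_in
    gluc = mp.k_g * P_in
    oxid = mp.k_P450 * P_in * P450
    rev = mp.k_N * N
    detox = mp.k_GSH * N * G
    bind = mp.k_PSH * N

    dP_in = influx - sulf - gluc - oxid + rev
    dS = -sulf + mp.b_S - mp.d_S * S
    dN = oxid - rev - detox - bind
    dG = -detox + b_GSH - mp.d_GSH * G
    dC = bind - mp.d_C * C

    n = dp.hill_n
    P53p_n = P53p**n
    hill_mdm2 = P53p_n / (dp.Km_mdm2**n + P53p_n)
    hill_p21 = P53p_n / (dp.Km_p21**n + P53p_n)
    phos = dp.k_p * P53 * C
    dP53 = dp.ks_p53 + dp.k_dp * P53p - phos - dp.kd_p53 * P53 \
        - dp.kd_p53_mdm2 * P53 * MDM2
    dP53p = phos - dp.k_dp * P53p - dp.kd_p53p * P53p \
        - dp.kd_p53p_mdm2 * P53p * MDM2
    dMDM2 = dp.ks_mdm2 + dp.ks_mdm2_p53p * hill_mdm2 - dp.kd_mdm2 * MDM2
    dP21 = dp.ks_p21 + dp.ks_p21_p53p * hill_p21 - dp.kd_p21 * P21 \
        + dp.k_stim * RT

    binding = rp.k_on * T_local * R - rp.k_off * RT
    dR = -binding
    dRT = binding

    dK = b_K - fp.d_K * K + fp.k_mit * MIT_local - fp.k_inhib * P21 * K

    dy = np.stack([dP_in, dS, dN, dG, dC, dP53, dP53p, dMDM2, dP21, dR, dRT, dK])
    droutes = np.stack([gluc, sulf, detox, bind, rev, oxid - rev, influx])
    return dy, droutes


def step_cohort(cohort: HepatocyteCohort, dt: float, P_local, T_local,
                MIT_local, active=1.0, substeps: int = 1) -> None:
    """Advance the full coupled system by ``dt`` hours (RK4, fixed step).

    ``P_local``, ``T_local`` and ``MIT_local`` are per-cell scalars or
    arrays, held constant over the step; ``active`` masks cells whose
    metabolism has stopped (necrotic) while leaving other variables frozen
    via the caller.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = cohort.params
    args = (cohort.P450, cohort.b_GSH, cohort.b_K, P_local, T_local, MIT_local,
            p.metabolism, p.ddr, p.receptor, p.fate,
            p.plasma.cell_uptake_rate, active)
    h = dt / substeps
    y = cohort.y
    routes = cohort.routes
    for _ in range(substeps):
        k1, r1 = _rhs(y, routes, *args)
        k2, r2 = _rhs(y + 0.5 * h * k1, routes, *args)
        k3, r3 = _rhs(y + 0.5 * h * k2, routes, *args)
        k4, r4 = _rhs(y + h * k3, routes, *args)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        routes = routes + (h / 6.0) * (r1 + 2 * r2 + 2 * r3 + r4)
        np.maximum(y[:5], 0.0, out=y[:5])  # metabolite non-negativity
    cohort.y = y
    cohort.routes = routes


# ---------------------------------------------------------------------------
# single-subsystem steps (the other variables are held fixed); these expose
# the individual modules for testing and for desk-scale analyses

def _rk4_subsystem(y0: np.ndarray, rhs, dt: float, substeps: int) -> np.ndarray:
    h = dt / substeps
    y = y0
    for _ in range(substeps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def step_metabolism(cohort: HepatocyteCohort, P_local, dt: float,
                    substeps: int = 60) -> None:
    """Advance only P_in, S, N, G, C (and the route ledgers)."""
    mp = cohort.params.metabolism
    k_uc = cohort.params.plasma.cell_uptake_rate
    idx = [STATE_VARS.index(v) for v in ("P_in", "S", "N", "G", "C")]

    def rhs(z):
        P_in, S, N, G, C, gluc, sulf, gshc, add, rev_i, ox_i, up = z
        sulf_f = mp.k_s * S * P_in
        gluc_f = mp.k_g * P_in
        oxid = mp.k_P450 * P_in * cohort.P450
        rev = mp.k_N * N
        detox = mp.k_GSH * N * G
        bind = mp.k_PSH * N
        influx = k_uc * P_local * np.ones_like(P_in)
        return np.stack([
            influx - sulf_f - gluc_f - oxid + rev,
            -sulf_f + mp.b_S - mp.d_S * S,
            oxid - rev - detox - bind,
            -detox + cohort.b_GSH - mp.d_GSH * G,
            bind - mp.d_C * C,
            gluc_f, sulf_f, detox, bind, rev, oxid - rev, influx,
        ])

    z0 = np.concatenate([cohort.y[idx], cohort.routes])
    z = _rk4_subsystem(z0, rhs, dt, substeps)
    z[:5] = np.maximum(z[:5], 0.0)
    cohort.y[idx] = z[:5]
    cohort.routes = z[5:]


def step_ddr(cohort: HepatocyteCohort, dt: float, substeps: int = 60) -> None:
    """Advance P53, P53p, MDM2, P21 at the current (frozen) C and RT."""
    dp = cohort.params.ddr
    C = cohort["C"]
    RT = cohort["RT"]
    idx = [STATE_VARS.index(v) for v in ("P53", "P53p", "MDM2", "P21")]

    def rhs(z):
        P53, P53p, MDM2, P21 = z
        n = dp.hill_n
        P53p_n = P53p**n
        phos = dp.k_p * P53 * C
        return np.stack([
            dp.ks_p53 + dp.k_dp * P53p - phos - dp.kd_p53 * P53
            - dp.kd_p53_mdm2 * P53 * MDM2,
            phos - dp.k_dp * P53p - dp.kd_p53p * P53p
            - dp.kd_p53p_mdm2 * P53p * MDM2,
            dp.ks_mdm2 + dp.ks_mdm2_p53p * P53p_n / (dp.Km_mdm2**n + P53p_n)
            - dp.kd_mdm2 * MDM2,
            dp.ks_p21 + dp.ks_p21_p53p * P53p_n / (dp.Km_p21**n + P53p_n)
            - dp.kd_p21 * P21 + dp.k_stim * RT,
        ])

    cohort.y[idx] = _rk4_subsystem(cohort.y[idx], rhs, dt, substeps)


def step_receptor(cohort: HepatocyteCohort, T_local, dt: float,
                  substeps: int = 60) -> None:
    """Advance R, RT under a constant local TGF-beta concentration.

    The pair relaxes along the exact conservation R + RT = const.
    """
    rp = cohort.params.receptor
    idx = [STATE_VARS.index(v) for v in ("R", "RT")]

    def rhs(z):
        R, RT = z
        b = rp.k_on * T_local * R - rp.k_off * RT
        return np.stack([-b, b])

    cohort.y[idx] = _rk4_subsystem(cohort.y[idx], rhs, dt, substeps)


def step_cyclin(cohort: HepatocyteCohort, MIT_local, dt: float,
                substeps: int = 60) -> None:
    """Advance the cyclin/CDK pool at the current (frozen) P21."""
    fp = cohort.params.fate
    P21 = cohort["P21"]
    iK = STATE_VARS.index("K")

    def rhs(K):
        return cohort.b_K - fp.d_K * K + fp.k_mit * MIT_local \
            - fp.k_inhib * P21 * K

    cohort.y[iK] = _rk4_subsystem(cohort.y[iK], rhs, dt, substeps)


def check_fate(C, K, rng: np.random.Generator, fate: FateParams,
               p_necrosis: float | None = None) -> np.ndarray:
    """Fate events for healthy hepatocytes, one check per cell.

    Rule order: adducts above threshold kill with ``p_necrosis``; otherwise
    a cyclin/CDK level above the proliferation threshold divides with
    p = 0.001, below the senescence threshold arrests deterministically.
    """
    C = np.atleast_1d(np.asarray(C, dtype=float))
    K = np.atleast_1d(np.asarray(K, dtype=float))
    pn = fate.p_necrosis if p_necrosis is None else p_necrosis
    u = rng.random(len(C))
    events = np.full(len(C), EVENT_NONE, dtype=np.int8)
    necro_zone = C > fate.necrosis_threshold
    events[necro_zone & (u < pn)] = EVENT_NECROSIS
    prolif_zone = ~necro_zone & (K > fate.prolif_threshold)
    events[prolif_zone & (u < fate.p_proliferation)] = EVENT_PROLIFERATION
    senesc_zone = ~necro_zone & (K < fate.senesc_threshold)
    events[senesc_zone] = EVENT_SENESCENCE
    return events


def reference_trajectory(cohort: HepatocyteCohort, t_span, P_local, T_local,
                         MIT_local, active=1.0, rtol=1e-10, atol=1e-12):
    """High-accuracy adaptive integration of the same system (scipy oracle)."""
    from scipy.integrate import solve_ivp

    p = cohort.params
    args = (cohort.P450, cohort.b_GSH, cohort.b_K, P_local, T_local, MIT_local,
            p.metabolism, p.ddr, p.receptor, p.fate,
            p.plasma.cell_uptake_rate, active)
    n = cohort.n

    def f(t, z):
        y = z[: N_VARS * n].reshape(N_VARS, n)
        dy, dr = _rhs(y, None, *args)
        return np.concatenate([dy.ravel(), dr.ravel()])

    z0 = np.concatenate([cohort.y.ravel(), cohort.routes.ravel()])
    sol = solve_ivp(f, t_span, z0, method="LSODA", rtol=rtol, atol=atol,
                    dense_output=True)
    return sol
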