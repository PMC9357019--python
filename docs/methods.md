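# Methods

`lobulesim` simulates acetaminophen (APAP) overdose injury and recovery in
one two-dimensional liver lobule by coupling three layers of dynamics:

1. a **cellular Potts model (CPM)** of the tissue — hepatocytes, resident
   Kupffer cells (KCs), recruited macrophages and fixed veins on a
   200 x 200 pixel lattice (3 um/pixel);
2. **per-hepatocyte ODE systems** — APAP metabolism, a reduced
   p53/phospho-p53/MDM2/p21 DNA-damage-response (DDR) module, TGF-beta
   receptor occupancy and a cyclin/CDK pool that encodes cell fate;
3. **extracellular fields** — a well-mixed plasma APAP pool and four
   diffusing species (DAMPs, MCP-1, mitogens, TGF-beta).

## Geometry and zonation

The lobule is a regular hexagon of circumradius 95 px centred at
(100, 100), with a central vein (CV, radius 14 px) and six portal veins
(PVs, radius 5 px) at the vertices; the rim-to-rim porto-central distance
is 228 um. 600 hepatocytes (target area 35 px) and 150 KCs (3.5 px) are
seeded as single pixels inside an 80 px disc and relax for 96 Monte Carlo
steps (MCS) before exposure. Seeding uses rejection sampling with a
Moore-neighbourhood exclusion so that no two single-pixel seeds start
adjacent; without this, a growing neighbour can engulf a fresh seed in the
first step or two.

Metabolic zonation assigns each hepatocyte static cytochrome P450 and an
initial/reset glutathione (GSH) level as linear functions of normalized
porto-central position, anchored so the mid-axis values equal the flat
levels 20.61 a.u. (GSH) and 1.15 a.u. (P450) used in the no-zonation
scenarios. Defaults: GSH 4.0 -> 37.22 a.u. and P450 1.65 -> 0.65 a.u. from
CV rim to lobule border, giving GSH the larger relative span. The profile
functions are injectable. Zonation scenarios `both | gsh_only | p450_only |
none` switch each gradient against its flat value.

## Plasma pool and uptake

Plasma APAP is one well-mixed pool (blood mixes in seconds, negligible
against the 5-min MCS). It decays by renal excretion `k_e` and
per-hepatocyte uptake `k_u` summed over alive (healthy + senescent)
hepatocytes. `k_e = 0.024 ln2/2` and `k_u = 0.976 ln2/(2*600)` h^-1 are
fixed by two observables: a 2 h half-life and a 2.4% / 97.6%
excretion/uptake split (closed form: excreted fraction `k_e/(k_e+600 k_u)`,
independent of dose and time). Cytosolic influx per cell is
`partition * k_u * P_ex` with `partition = 600`, the plasma-pool to
single-cell volume ratio; this keeps intracellular concentrations on the
scale at which the printed fate thresholds operate. For lobules of other
sizes (the 60 x 60 test fixture has 54 hepatocytes) `k_u` is rescaled by
`600/n` and the partition by `n/600`, so half-life, elimination split and
the per-cell exposure profile are invariant under lobule size.

## Hepatocellular metabolism

Each hepatocyte integrates intracellular APAP (P_in), PAPS (S), NAPQI (N),
GSH (G) and NAPQI-protein adducts (C): APAP is conjugated by
glucuronidation (`k_g P_in`) and PAPS-limited sulfation (`k_s S P_in`,
PAPS replenished at `b_S - d_S S`), or oxidized to NAPQI
(`k_P450 P_in P450`). NAPQI reverts slowly to APAP (`k_N`), is detoxified
by GSH (`k_GSH N G`, GSH resynthesized towards its zonated set point at
turnover `d_GSH`) or binds protein thiols (`k_PSH N`); adducts decay at
`d_C`. Cumulative route integrals (glucuronidated, sulfated,
GSH-conjugated, adducts, reverted, net oxidized, uptaken) support the
elimination-route accounting; "oxidation share" counts everything that
passed through NAPQI.

These rate constants are not published; they are **calibrated** against
the emergent read-outs the model is known to reproduce:

* glucuronidation 80–85%, sulfation 5–10%, oxidation ~10.0% of hepatic
  elimination at 6 h, nearly dose-independent over doses 250–650;
* adducts exceed the necrosis threshold (C > 4) only pericentrally at
  dose 450, and never at dose 250 (peak C ~3.7);
* first necrosis between 6.25 h (dose 650) and ~11.1 h (dose 350),
  decreasing with dose.

The onset window forced a specific kinetic regime: NAPQI acts as a
long-lived reservoir (small `k_N + k_PSH`) fed while plasma APAP lasts and
drained slowly into adducts, with sustained GSH resynthesis acting as a
constant subtraction. Adducts then cross the threshold on a slow late
rise, which spreads the crossing times of a 1.86-fold dose range over the
~1.8-fold onset-time window. Fast-drain regimes compress all onsets into
2–4 h and cannot reproduce the window.

## DNA damage response and cell fate

The reduced DDR keeps protein species only. p53 is phosphorylated
proportionally to the adduct load (`k_p P53 C`); phospho-p53 induces MDM2
and p21 through Hill-4 terms; MDM2 degrades both p53 forms; occupied
TGF-beta receptors add `k_stim RT` (k_stim = 12e-6 a.u. h^-1) to p21
production. With C = 0 and RT = 0 the basal state is closed-form
(phospho-p53 = 0) and is used as the initial condition. MDM2-mediated
degradation is kept a small share of basal p53 turnover, so weakening the
feedback 100-fold barely changes the phospho-p53 response while
strengthening it 100-fold suppresses p53, phospho-p53 and p21 strongly —
the observed asymmetry of the feedback perturbation.

Fate is read off the cyclin/CDK pool
`dK/dt = b_K - d_K K + k_mit MIT - k_inhib P21 K` with the printed
constants (d_K = 3.35e-3 h^-1, k_mit = 6.24e-4 h^-1,
k_inhib = 24 a.u.^-1 h^-1) and thresholds: proliferation above 4.68641
(p = 0.001 per 5-min check), irreversible senescence below 4.6863375,
necrosis at C > 4 (p = 0.8 per check). K starts at the window midpoint
and `b_K` comes from the steady-state constraint, re-derived whenever
`k_inhib` is perturbed so the basal state remains a fixed point.

The fate window is only 7.25e-5 a.u. wide (1.5e-5 relative), so fate is a
near-threshold read-out of the forcing balance
`k_inhib * dP21  vs  k_mit * MIT`. The unpublished DDR magnitudes were
chosen so that: sustained adduct loads above C ~ 1.4 arrest a cell about a
day after exposure (senescence must not pre-empt necrosis in the
pericentral race); the TGF-beta output of an isolated senescent band stays
below the arrest threshold (senescence growth halts within ~24 h when no
macrophages are present); and macrophage-derived TGF-beta exposure
accumulated while necrosis persists can push the tissue into a
self-sustaining senescence wave once macrophages withdraw — the mechanism
behind the loss of recovery at high dose. Because the printed k_stim is
four orders of magnitude below k_inhib*P21 scales, this balance is
delicate; see "Known limitations".

## Extracellular fields

DAMPs (D = 216 um^2/h, d = 1.2 h^-1, 6 a.u./h per necrotic pixel), MCP-1
(27e3, 2.4, 900 per secreting-KC pixel), mitogens (27e3, 3.24, 48 per
macrophage pixel) and TGF-beta (d = 3.6, 2.4 per macrophage pixel near
necrosis, 0.12 per senescent pixel) evolve by diffusion + production -
first-order decay with no-flux boundaries. Production is applied per
pixel. The TGF-beta diffusion constant is not published; the default
27e3 um^2/h (like MCP-1/mitogens) makes TGF-beta a lobule-scale signal,
which is what lets total producer mass - not local contiguity - control
the senescence wave.

The solver applies the exact matrix exponential of the 5-point Neumann
Laplacian in the DCT-II basis each substep (3 substeps per MCS), with
production added explicitly before the propagator. It is unconditionally
stable (forward Euler would need ~1000 substeps/MCS for MCP-1), conserves
mass to machine precision when decay is off, and clips the O(1e-16)
spectral ringing to keep concentrations non-negative. Receptor exchange
removes the net per-hepatocyte binding flux `(k_on T R - k_off RT) dt`
from the field over the cell footprint.

## Immunosurveillance

KCs secrete MCP-1 (while their mean footprint DAMP exceeds 0.5 a.u.).
When the 1 h running mean of periportal MCP-1 (pixels Moore-adjacent to a
PV) exceeds 1e-4 a.u., each PV makes one Bernoulli(0.5) seeding attempt
per MCS; recruitment disarms permanently once that signal falls 10% below
its running maximum. The running mean matters: single-MCS flicker of the
producer set otherwise trips the stop rule during the build-up.
Macrophages (target 17.5 px) chemotax along MCP-1 with strength 600 while
touching the periportal entry zone, 2 when Moore-adjacent to necrosis
(parked) and 100 elsewhere; the context is evaluated per cell per MCS.
Phagocytosis removes a necrotic cell with p = 0.1 per check after more
than 750 cumulative minutes of macrophage contact (current adjacency
required); senescent cells are cleared with p = 0.45 after 300 min;
macrophages older than 1000 min retreat with p = 0.005 once periportal
MCP-1 drops below 1e-5. Contact timers accumulate cumulative minutes per
target cell and never reset.

## CPM energies

Energies: adhesion J(cell, medium) = 3, J(heterotypic) = 1.5,
J(homotypic) = 1, J(cell, vein) = 6; macrophages adhere strongly to other
cells (J = 0) and weakly to medium (J = 5), which lets them wedge through
packed tissue toward the pericentral necrotic zone in about a day; area
weights lambda = 2 (hepatocytes), 100 (KCs), 4 (macrophages);
T = 6. Two constraints shaped these numbers: (a) no hepatocyte and
essentially no KC may vanish by chance during initialization — a growing
single-pixel cell's area-term gain is ~ -67*lambda_hep, so KC survival
requires lambda_KC >> lambda_hep; (b) macrophage migration speed — at
low temperature or high surface tension the lattice freezes and
macrophages never reach the necrotic core. Necrotic cells are immotile
(excluded as source and target of copy attempts); cell connectivity is
not enforced. A cell squeezed to zero pixels is removed and logged (rare
under defaults).

## Update order and time

1 MCS = 5 simulated minutes. Per MCS, in fixed order: plasma and field
substeps; vectorized RK4 on the joint 12-variable intracellular system
(20 substeps per MCS; verified against an adaptive-step LSODA reference
to better than 1e-6 relative, and ~1e-14 on K, whose fate window needs
~1e-8); fate checks and immune rules in ascending cell-id order; one CPM
Monte Carlo step (as many copy attempts as non-vein lobule pixels);
recording. All randomness comes from one per-run generator in a fixed
draw order, so a (config, seed) pair reproduces bitwise.

## Perturbations and therapies

MDM2 feedback scaling multiplies both MDM2-mediated p53-degradation
constants by r in {0.01..100}. Cyclin/CDK regulation scaling multiplies
k_inhib, k_mit or k_stim (printed factor sets). Macrophage removal sets
the recruitment probability to zero. Therapies apply once at their
scheduled hour: NAC adds twice the pre-exposure maximum GSH (over all
hepatocytes during initialization) to every alive hepatocyte; 4MP scales
the p53 phosphorylation rate by 0.2 and static P450 by 0.1 and sets
p_necrosis = 5e-5; pifithrin-alpha halves the phospho-p53-dependent
production of MDM2 and p21, scales phospho-p53 and its formation rate by
0.67 and sets p_necrosis = 1; clodronate removes all KCs.

## Calibration utility

`lobulesim.calibrate` wraps Latin-hypercube multistart (scipy QMC) over
box bounds followed by trust-region least squares; zero-residual starts
are returned unchanged, non-finite starts discarded, and all starts
reported.

## What the tests do and do not show

The test suite exercises the full machinery at two scales: desk-scale
component checks (closed forms, brute-force oracles, adaptive-integrator
references) and 168 h runs of a 60 x 60 miniature lobule (54 hepatocytes,
14 KCs, same pixel size and per-cell dynamics). The miniature reproduces
the no-necrosis/senescence-only regime at dose 250, the onset-window
chemistry, necrotic clearance within ~2 days, halted senescence growth
without macrophages, full recovery at doses <= 500, and certain collapse
at dose 650.

Known limitations:

* **Small-number noise in the miniature.** With 54 hepatocytes the
  necrotic load differs by only a few cells between doses 500 and 550,
  below replicate-to-replicate noise, so the sharp recovery/failure
  tipping cannot be pinned between those doses at this scale: collapse at
  550 occurs in some replicates only, while 650 collapses reliably and
  <= 500 always recovers. The full 600-cell lobule sharpens the boundary
  but needs much longer runs.
* **Macrophage senescence amplification is delicate.** The printed
  coupling constants put macrophage-derived mitogen protection
  (k_mit = 6.24e-4) many orders above the TGF-beta arrest drive
  (k_stim = 1.2e-5), and the senescent-clearance rule (p = 0.45 per
  check) removes arrested cells wherever macrophages roam. The shipped
  calibration does reproduce the with-macrophage doubling of senescence
  at 96 h in the fixture, but the margin is small and the effect depends
  on the slow-p21 integrator regime chosen here.
* **Sparse injury escapes surveillance in the miniature.** At dose 350
  the fixture produces only 1-4 necrotic cells; when a lone necrotic
  cell forms far from every Kupffer cell, its short-ranged DAMP plume
  (~13 um decay length) may activate no sensor for days, delaying
  clearance past the expected window.
* Real-data features not represented: sinusoidal flow and advection, 3D
  geometry, mRNA-level DDR species, JNK/mitochondrial amplification of
  necrosis, KC-derived regenerative cytokines, gradual macrophage decline
  after clearance.
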