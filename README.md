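# lobulesim

Multiscale simulation of acetaminophen (APAP/paracetamol)-induced liver
injury and recovery in a single hepatic lobule.

Overdosed APAP is oxidized by pericentral cytochrome P450 into the
reactive metabolite NAPQI; once glutathione (GSH) is depleted, NAPQI
binds proteins (NAPQI-cys adducts), killing pericentral hepatocytes by
necrosis, arresting perinecrotic ones by p53/p21-driven senescence, and
triggering an immune response: necrotic DAMPs activate Kupffer cells,
whose MCP-1 recruits macrophages that clear debris, spread senescence via
TGF-beta and drive regeneration via mitogens. `lobulesim` models this as

* a 2D cellular Potts model of the hexagonal lobule (Metropolis
  pixel-copy dynamics, `P(accept) = 1` if `dH < 0`, else `exp(-dH/T)`,
  with adhesion + area-constraint energies and MCP-1 chemotaxis for
  macrophages),
* per-hepatocyte ODEs for APAP metabolism
  (`P_in, PAPS, NAPQI, GSH, NAPQI-cys`), the reduced
  p53/phospho-p53/MDM2/p21 damage response, TGF-beta receptor occupancy
  (`R + RT = 1`) and a cyclin/CDK pool `K` whose razor-thin threshold
  window decides proliferation vs irreversible senescence,
* reaction-diffusion fields (DAMP, MCP-1, mitogens, TGF-beta) solved
  with an exact spectral propagator, plus a well-mixed plasma APAP pool
  with a 2 h half-life and a 2.4% / 97.6% renal/hepatic elimination
  split.

It is intended for in-silico experiments on zonation, damage-response
perturbations and timed therapies (N-acetylcysteine, 4-methylpyrazole,
pifithrin-alpha, clodronate).

## Worked example

```python
import lobulesim as ls

cfg = ls.RunConfig(dose=450.0, horizon_h=24.0, seed=1)
record = ls.run_simulation(cfg)
row = record.timeseries.query("time_h >= 24").iloc[0]
print(f"t={row.time_h:.1f} h  healthy={row.healthy}  senescent={row.senescent} "
      f"necrotic={row.necrotic}  macrophages={row.macrophages}  P_ex={row.P_ex:.2f}")
```

prints

```
t=24.0 h  healthy=538  senescent=0  necrotic=65  macrophages=49  P_ex=0.17
```

24 h after a dose of 450 a.u., plasma APAP is essentially eliminated
(0.04% of the dose left), 65 of the 600 hepatocytes — the pericentral
band with high P450 and low GSH — have died by necrosis (first necrosis
appears at ~8.5 h at this dose; perinecrotic senescence follows over the
next days), and ~50 macrophages have been recruited through the portal
fields. Continuing the run shows clearance of the necrotic debris and
regeneration by proliferation.

The same model runs from the shell:

```bash
lobulesim simulate --dose 450 --horizon-h 24 --seed 1 --out runs/d450
lobulesim sweep --doses 250,350,450,550,650 --replicates 3 --miniature --out runs/sweep
lobulesim summarize runs/sweep
```

A 60 x 60 miniature lobule (54 hepatocytes, scale replica of the
full geometry) is built in for fast experiments via
`RunConfig(miniature=True)`.

## Layout

```
src/lobulesim/
  geometry.py       hexagonal lobule, veins, seeding, zonation profiles
  cpm.py            Potts engine (numba kernel), division, removal
  intracellular.py  per-hepatocyte ODE systems and fate checks
  fields.py         plasma pool and spectral diffusion fields
  immune.py         Kupffer/macrophage rule layer
  perturb.py        perturbations, therapies, LHS+least-squares calibration
  driver.py         run orchestration, records, summaries
  io.py             CSV/YAML persistence and snapshot rendering
  cli.py            typer command-line interface
docs/methods.md     model description, parameter provenance, limitations
```
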