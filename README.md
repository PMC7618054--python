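# atosense

Mechanistic modelling and global sensitivity screening for whole-cell
biosensors built on the acetoacetate-sensing **AtoSC two-component system
(TCS)** of *E. coli*, plus a synthetic flow-cytometry study generator for
end-to-end dose-response characterisation without any external data.

It is aimed at synthetic biologists designing TCS biosensors who want to
know, before cloning anything, *which tunable quantities (protein levels,
promoter copy number, binding rates) actually move the transfer function* —
and at method developers who need a compact, fully tested Morris
elementary-effects pipeline over an ODE model.

## What it computes

**Model.** A mass-action ODE model of the AtoSC TCS: the AtoS histidine
kinase (HK) autophosphorylates at rate `k_ap` (the proxy for acetoacetate),
phosphotransfers to the AtoC response regulator (RR), phospho-AtoC binds
the Pato promoter, and an occupied promoter drives a GFP reporter cascade
(mRNA → immature → mature GFP). Total HK, RR and promoter are conserved.
Steady states are found by stiff integration with a Newton polish,
certified by a windowed stationarity criterion.

**Transfer function.** Sweeping `k_ap` gives a steady-state dose-response
curve, characterised by a four-parameter Hill function with basal
expression:

```
GFP(d) = f_min + (f_max − f_min) · d^n / (K^n + d^n)
```

with derived amplitude metrics *dynamic range* = (f_max − f_min)/f_min and
*fold change* = f_max/f_min; `K` is the sensitivity midpoint K₁/₂.

**Sensitivity.** A from-scratch Morris elementary-effects screen over the
16 TCS parameters (rates plus the S/C/pato totals): radial trajectories on
a p-level grid, Campolongo spread-maximising subset selection, per-feature
μ, μ\* and σ, and the per-column-normalised μ\* heatmap used to rank
engineering handles.

**Synthetic assays.** A generator emulating per-well flow cytometry
(10,000 log-normal events/well, ≥3 biological replicates, rainbow-bead
calibration from arbitrary units to molecules of equivalent fluorophore),
so Hill fitting can be exercised as a parameter-recovery experiment.

## Worked example

```bash
$ atosense sweep --out runs/sweep
  Hill: fmin=0.009114 fmax=0.9088 K=0.09158 n=1 fold_change=99.71
```

The model's steady-state GFP rises ~100-fold across four decades of
`k_ap`, with half-maximal response at `k_ap ≈ 0.092` — the shape the
screen perturbs. A synthetic cytometry study generated from the high-copy
reporter-only biosensor characterisation (K₁/₂ = 344 μM, fold change 115)
and re-fitted blind:

```bash
$ atosense synthstudy --fixture asah0 --seed 1 --out runs/study
  Hill: fmin=100.6 fmax=1.154e+04 K=340.6 n=1.52 fold_change=114.7
```

i.e. with 3 replicates and 5% replicate noise the fit recovers the
generating midpoint (340.6 vs 344 μM) and amplitude. The Morris screen
(`atosense morris --seed 1 --out runs/morris`) writes the tidy statistics
and the normalised μ\* heatmap; with the default bounds it flags promoter
availability (`pato`), RR level (`C`) and HK level (`S`) among the most
influential handles on basal level, maximum output and K₁/₂ — the levers a
plasmid engineer can actually turn (copy number, constitutive expression).

Python API mirrors the CLI:

```python
from atosense import TCSParameters, sweep_dose_response, fit_hill
fit = fit_hill(sweep_dose_response(TCSParameters()))
print(fit.K, fit.fold_change)
```

## Layout

- `atosense.model` — ODE model, reaction network, steady-state solver
- `atosense.doseresponse` — `k_ap` sweeps, Hill fitting, amplitude metrics
- `atosense.morris` — trajectory design, selection, elementary effects
- `atosense.cytometry` — events, bead calibration, well summaries, studies
- `atosense.pipeline` / `atosense.cli` — config-driven runs and the CLI
- `docs/methods.md` — model equations, defaults, numerical choices, limits
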