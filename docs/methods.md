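# Methods

## The AtoSC two-component-system model

The model is a mass-action reaction network over 12 species: free and
phosphorylated AtoS histidine kinase (S, Sp), free and phosphorylated AtoC
response regulator (C, Cp), the three HK·RR complexes (SpC, SCp, SC), free
and occupied Pato promoter (P, PCp), and the reporter cascade (mRNA M,
immature GFP Gi, mature GFP Gm). The 15 reactions (19 mass-action rate
laws, counting each reversible binding as two):

| # | reaction | rate law |
|---|----------|----------|
| 1 | S → Sp | k_ap·S (acetoacetate proxy) |
| 2 | Sp → S | k_ad·Sp |
| 3 | Sp + C ⇌ SpC | k_b1·Sp·C / k_d1·SpC |
| 4 | SpC → S + Cp | k_pt·SpC (phosphotransfer) |
| 5 | S + Cp ⇌ SCp | k_b2·S·Cp / k_d2·SCp |
| 6 | SCp → S + C | k_ph·SCp (phosphatase) |
| 7 | S + C ⇌ SC | k_b3·S·C / k_d3·SC |
| 8 | Cp + P ⇌ PCp | k_bnd·Cp·P / k_unbnd·PCp |
| 9 | P → P + M | k_lgexp·P (leaky) |
| 10 | PCp → PCp + M | k_pmgexp·PCp (induced) |
| 11 | M → M + Gi | k_trl·M |
| 12 | Gi → Gm | k_mat·Gi |
| 13–15 | M, Gi, Gm → ∅ | d_m·M, d_g·Gi, d_g·Gm |

Phosphotransfer releases both partners in a single step (SpC → S + Cp) and
the phosphatase route likewise (SCp → S + C) — the standard kinetic
scheme for TCS modelling. Three moieties are conserved exactly by
construction: total HK S_tot = S+Sp+SpC+SCp+SC, total RR
C_tot = C+Cp+SpC+SCp+SC+PCp, and total promoter P_tot = P+PCp. The totals
are treated as parameters (initial conditions), not synthesis rates:
protein levels and plasmid copy number are the experimental dials of
interest, and modelling them as conserved pools keeps them directly
interpretable. Host/plasmid expression differences are captured only
through the values of S_tot, C_tot, P_tot. Growth dilution of HK/RR and
stochastic (SSA) dynamics are out of scope.

### Default parameters

Rates are in reciprocal time units, concentrations in arbitrary units; the
defaults describe a plausible, strongly switching biosensor rather than
measured constants (none are published for this system):

* phosphorylation cycle: k_ap nominal 0.1 (swept as the dose), k_ad 0.1,
  k_pt = k_ph = 1;
* binding: k_b1 = k_b2 = 10, k_d1 = k_d2 = 0.1 (tight signalling
  complexes), k_b3 = k_d3 = 1 (weaker dead-end complex),
  k_bnd = 10, k_unbnd = 0.1 (tight promoter binding);
* expression: k_pmgexp/k_lgexp = 100 (induced vs leaky transcription),
  reporter constants k_trl = k_mat = d_m = 1, d_g = 0.1 — the reporter
  cascade only rescales the output and is excluded from screening;
* totals: S_tot = 1, C_tot = 2 (RR in excess of HK, as typical for TCS),
  P_tot = 0.1.

With these defaults the steady-state transfer function rises ~100-fold
over four decades of k_ap with midpoint near k_ap ≈ 0.09.

### Steady-state solver

`simulate_to_steady_state` integrates with LSODA (stiff-capable; binding
and expression rates differ by orders of magnitude) using an analytic
Jacobian, over geometrically growing horizons (100, 400, 1600, …, capped
at t_max = 1e6). After each horizon t the state is declared stationary
when the maximum relative change of every species over a probe window of
0.1·t falls below rel_tol = 1e-6 (denominator floored at 1e-9 of the
largest total so species that are exactly zero do not divide by zero).
Each integrated checkpoint is first handed to a Newton solve of the
algebraic steady-state system in which the three redundant rows (S, C, P)
are replaced by the conservation constraints; a Newton root is accepted
only after passing the same probe-window criterion, which guards against
unstable roots and keeps the returned state certified by the windowed
test. The polish cuts a typical random-parameter solve from ~100 ms to a
few ms and can be disabled (`newton_polish=False`); both paths agree to
~1e-5 relative in tests. Dose sweeps warm-start each solve from the
previous dose's steady state (the totals are shared across a sweep).

## Hill characterisation

Curves are fitted to GFP(d) = fmin + (fmax−fmin)·d^n/(K^n+d^n) by bounded
nonlinear least squares (trust-region reflective via `scipy.curve_fit`),
with multi-start initialisation — fmin₀ = min response, fmax₀ = max
response, K₀ = dose nearest the midpoint response, n₀ ∈ {0.5, 1, 2, 4} —
keeping the lowest-SSE converged fit. Bounds: all parameters ≥ 0, n ≤ 10.
The Hill coefficient is fitted by default and can be clamped (`n_fixed`).
Dose 0 is a legal grid point (it anchors fmin). Standard errors are the
asymptotic ones from the local covariance; reported uncertainties of this
kind are treated as SEs throughout. Fold change is computed as fmax/fmin
and dynamic range as fold change − 1, making the identity
fold_change − dynamic_range = 1 exact by construction.

**Weighting.** Unweighted by default. When per-dose replicate SDs are
available they are pooled under a constant-CV error model
(σᵢ = pooled_cv · responseᵢ) before inverse-variance weighting: raw SDs
from 3 replicates carry ~2 degrees of freedom each, and weighting by them
directly produced unstable weights and ~89% empirical coverage of the
3-SE interval in the round-trip Monte Carlo, versus ~98% with pooling.
The default dose grid for model sweeps is an explicit zero plus 12
log-spaced points over k_ap ∈ [1e-3, 10].

## Morris elementary-effects screening

The screened space is the 16 TCS parameters (all rates except k_ap, plus
S, C, pato); k_ap is the swept dose and the reporter constants are fixed.
Default bounds span two decades centred on each nominal value, sampled
uniformly on log10 scale (rates and concentrations vary over decades and
influence should not be an artefact of absolute magnitude); both bounds
and scales are configurable, and these defaults are the package's stand-in
rather than published values. Each sample point maps to a full parameter
set, a 9–13-point k_ap sweep, and a Hill fit, yielding five output
features: fmin, fmax, K, n and fold change.

Design: p = 4 grid levels with Δ = p/(2(p−1)) = 2/3 (the literature
standard), R = 1000 candidate radial trajectories from which r = 50 are
selected by the Campolongo criterion — maximise the root-sum-of-squares of
pairwise trajectory distances, a trajectory distance being the sum of
Euclidean distances between all point pairs. Subset search is exact
(enumeration) up to 10,000 candidate subsets and otherwise greedy
construction (best pair, then best single extension) with single-swap hill
climbing; the greedy path is validated against enumeration on small
instances and against random subsets on larger ones. Scaled-down defaults
used by the test suite (R = 100, r = 10, 9-point grid) reproduce the
qualitative ranking in ~20 s on one CPU; the full R = 1000/r = 50 screen
is configurable.

EEs are (y_after − y_before)/(±Δ) per one-coordinate step; per (parameter,
feature) cell the screen reports μ (signed mean), μ\* (mean absolute) and
σ (SD, denominator r−1). Failed sweeps or fits propagate as missing EEs —
never zero-imputed, which would bias μ toward 0 — and are excluded from
the means with counts reported; a run aborts if more than 10% of feature
evaluations fail, and any cell with fewer than two usable EEs is an error.
μ\* is normalised per output column by the column maximum for the heatmap.
Rankings are by μ\* descending with ties broken by σ descending then name;
reporter-related names can be excluded before ranking. n is included among
the analysed features and excludable via the ranking interface.

## Synthetic cytometry studies

The generator emulates the experimental characterisation workflow:

* **Single-cell fluorescence** is log-normal (strictly positive,
  right-skewed — the standard cytometry noise model) with the log-median
  set to the well median and log-SD √(ln(1+cv²)), so the linear-scale CV
  equals the requested `event_cv` (default 0.4, a typical single-cell
  spread). 10,000 events per well.
* **Biological replicates** (default 3) multiply the true well median by a
  median-preserving log-normal factor with CV `noise_cv` (default 0.05).
* **Bead calibration**: rainbow-bead ladders with known MEF values are fit
  by OLS of log10(MEF) on log10(a.u.); because the map is monotone,
  calibrating the median equals the median of calibrated events. The
  default study uses the identity calibration.
* **Ground truths** are Hill-shaped fixtures. `asah0` encodes the
  high-copy reporter-only biosensor characterisation (K₁/₂ = 344 μM, fold
  change 115, fmin set to 100 a.u.); `asah2j06` (K₁/₂ = 31.7 μM) and
  `asal2j06` (K₁/₂ = 40.1 μM) encode the plasmid-expression variants with
  plateaus chosen to respect the observed qualitative ordering (higher
  basal and lower maximum than `asah0`; the low-copy variant lower in
  both) — their exact plateaus are not published, so only K₁/₂ and the
  `asah0` fold change are pinned to reported values. All fixtures use
  n = 1.5, a typical TCS steepness. The default concentration grid is
  {0, 5, 10, 25, 50, 100, 250, 500, 1000, 2500, 5000, 10000, 20000} μM —
  a stand-in spanning sub-K₁/₂ to the 20 mM saturating ceiling.

What passing recovery tests show — and what they do not: the round trip
(generate → summarise medians → fit) demonstrates that the fitting stage
is unbiased and well-calibrated *under this noise model* (log-normal,
constant CV, independent wells). Real cytometry data add autofluorescence
background, gating artefacts, day effects correlated across wells and
instrument drift, none of which are emulated; recovery here validates the
software, not the assay.

## Reproducibility

Every stochastic component takes an explicit seed (numpy Generator); a
study is byte-reproducible from (fixture, grid, seed). Pipeline runs write
a manifest with the seed, a SHA-256 hash of the resolved configuration,
and package versions; deterministic modes rerun bit-identically. Morris
feature evaluations are independent and may run in a process pool;
aggregation is keyed by trajectory/point index so results are independent
of completion order.

## Known limitations

* Parameter values and screening bounds are plausible defaults, not
  measurements; rankings should be read as structural, not quantitative.
* The model omits HK/RR synthesis/degradation (growth dilution) — totals
  are strictly conserved — and any cross-talk with host regulation.
* Hill fits assume a monotone, saturating response; biphasic behaviour is
  out of scope.
* The Morris subset search above the enumeration cutoff is heuristic; it
  matches the exact optimum on all tested small instances but carries no
  global guarantee.
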