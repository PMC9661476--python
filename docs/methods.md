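# Methods

This note documents the models, conventions and numerical choices behind
`ttrkit`, and what the synthetic-data round trips do and do not establish.

## Thermodynamic bookkeeping

Free energies of binding follow ΔG = RT ln Kd with R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹ and a 1 M standard state; the default temperature is
298.15 K (the titration temperature). Table validation runs two separate
checks because published tables round differently: ΔG vs ΔH + (−TΔS) at
0.05 kcal/mol (absorbs one-decimal rounding of the three energy columns)
and ΔG vs RT ln Kd at 0.08 kcal/mol (absorbs two-significant-figure Kd
rounding; e.g. Kd 31 nM gives −10.24 vs a printed −10.3). Whether a table's
ΔG column was derived from the Kd or from the enthalpy/entropy split cannot
be reconstructed from the table itself, so both identities are checked
rather than assuming one. No heat-capacity (ΔCp) modeling is included; all
quantities refer to a single temperature.

## Two-site ITC model

TTR's two thyroxine sites are described by the macroscopic stepwise
binding polynomial Z(L) = 1 + K₁L + K₁K₂L² over free-ligand concentration
L, with stepwise association constants K₁, K₂ (M⁻¹) and stepwise molar
enthalpies ΔH₁, ΔH₂. For identical independent sites with microscopic
constant k the statistical factors give K₁ = 2k, K₂ = k/2 and ΔH₁ = ΔH₂;
the cooperativity index c = 4K₂/K₁ is 1 for that case and < 1 under
negative cooperativity. Published per-step site dissociation constants map
in as K₁ = 2/kd₁, K₂ = 1/(2·kd₂), so c = kd₁/kd₂. This parameterization is
the standard one for the two-site model family; equivalence to any
particular vendor implementation is not claimed — the implementation is
validated by exact round trips instead.

**Equilibrium.** The mass balance L_tot = L + P·(K₁L + 2K₁K₂L²)/Z has a
strictly increasing residual in L, so the root on [0, L_tot] is unique;
it is found with Brent's method at relative tolerance 8.9×10⁻¹⁶ and an
absolute floor of 10⁻³⁰ M so that convergence is governed by the relative
criterion even for picomolar free-ligand levels. The solver is tested
against an independent bisection oracle to 10⁻¹⁰ relative on 1,000 random
(K₁, K₂, L_tot, P_tot) draws.

**Injection bookkeeping.** The default protocol is a 200 μL perfusion
cell holding 5 μM protein titrated with 100 μM ligand in 19 × 2 μL
injections at 25 °C; 19 injections span molar ratio 0 → ≈3 nominal under
these concentrations (the count is configurable). Each injection follows
the instantaneous-displacement convention: cell contents are diluted by
(1 − dV/V₀) before the injectant mixes in, the cumulative heat content is
Q = V₀·P·(F₁ΔH₁ + F₂(ΔH₁+ΔH₂)), and the measured heat of injection i is
q_i = Q_i − Q_{i−1} + (dV/V₀)·(Q_i + Q_{i−1})/2, normalized per mole of
injectant, plus an optional constant dilution offset q_dil. Alternative
displacement conventions differ by less than typical fit noise at
dV/V₀ ≈ 1%.

**Fitting.** Weighted least squares on the per-injection heats with
association constants on log₁₀ scale, Levenberg–Marquardt, and 5 seeded
multi-starts to guard against local minima. The dilution offset q_dil is
fitted by default (appropriate for instrument data); parameter-recovery
studies on simulated data without dilution heat set `fit_q_dil=False` so
the refit model matches the generating model. The first injection can be
excluded (`drop_first`), following common practice for syringe-tip
pre-mixing; default is to keep it since simulated first injections are
clean. Noiseless round trips recover generating parameters to better than
10⁻⁶ relative in both modes.

**Identifiability limits.** The information an isotherm carries about an
association constant collapses when binding is quasi-stoichiometric
(Wiseman parameter c = P·K ≫ 1000): the transition becomes a step whose
shape no longer depends on K. At 5 μM protein this applies to first-site
binding of a 9.9 nM-Kd₁ negative-cooperativity ligand (c₁ ≈ 1000): with 1%
heat noise, globally converged fits over 50 replicates scatter the fitted
Kd₁ from ~0 to ~40 nM (median error ≈ 100%) with residuals at the noise
floor, so no estimator can localize Kd₁ under these conditions. Kd₂
(c₂ ≈ 20, median error ≈ 4%), both enthalpies, and the cooperativity index
c (median 0.038, below 1 in every replicate) remain well determined —
negative cooperativity is reliably detected even where Kd₁ itself is not
measurable. The acceptance test asserting Kd₁ recovery documents this
limit by failing honestly rather than loosening the check.

## MD post-processing

The binding-energy chain is pure bookkeeping over ensemble means:
ΔE_gp = E_TTR + 2E_L − E_TTR·2L and ΔG_bind = ΔE_gp + 2·ΔG_L-solv, the
factor 2 reflecting the two ligands bound per tetramer and the solvation
term entering as the ligands' desolvation penalty. **Sign convention:**
ΔG_bind here is positive-favorable (larger = stronger predicted binding),
the opposite of the solution-thermodynamics ΔG < 0 convention used in the
ITC modules; the two scales are never mixed. Since averaging commutes with
the linear combination, averaging frame energies before or after the
subtraction is equivalent. Ranking sorts descending by ΔG_bind with
lexicographic tie-breaks for deterministic output.

Contacts use a distance-only criterion on heavy-atom donor–acceptor
distances: 3.0 Å default, 3.5 Å when the partner element is Cl (halogen
contacts are longer than hydrogen bonds); no angular filtering. The mean
contact distance is computed over contact frames only (the usual
trajectory-analysis report), switchable to all frames. Frame sampling
takes n frames evenly over the final window of a run, sampling at the end
of each stride interval so the last frame is always included (140 frames
over the last 140 ns of a 150 ns run → 11, 12, …, 150 ns).

Structure frames are read/written as PDB via biotite (coordinates
preserved to the format's 10⁻³ Å precision) or as plain CSV; coordinates
are used as-is in Å with no periodic-boundary imaging (inputs are assumed
pre-imaged). The Ser117 metric requires the OG side-chain oxygen of
residue 117 in all four chains A–D and reports the (A,C) and (B,D)
facing-pair distances; the inter-ligand depth is the distance between the
two ligands' carbonyl carbons, located by residue name + atom name.

## Assay statistics

Unfolding: the 355/335 fluorescence ratio is normalized to an unfolded
fraction via per-experiment folded/unfolded references (the unfolded
reference being the 96 h control), clipped to [0, 1]. Kinetics are
modeled as f(t) = plateau·(1 − e^(−k·t)) — a mono-exponential to a
plateau, reflecting tetramer dissociation as the rate-limiting first-order
step; the data sources never print an equation, so this form is an
interpretation, documented as such. Protection % defaults to
100·(1 − plateau); a fixed-endpoint alternative (1 − f at the last
observed time) is available via `protection="endpoint"`. An all-zero
trace is handled analytically (plateau pinned to 0, protection 100%)
since the plateau parameter sits on its bound there.

Aggregation: % = 100·(sample − compound blank)/(control − buffer blank);
the compound blank carries the same compound concentration without
protein, correcting for compounds absorbing at 340 nm; the buffer-blank
correction of the control is assumed symmetric. Negative corrected
turbidities are clipped to 0 with a warning (instrument noise near full
inhibition), not raised. Inhibition % = 100 − aggregation %, floored at 0.
Viability follows (sample − mean blank)/(mean control − mean blank)×100,
deliberately uncapped above 100%.

Plasma: tetramer stabilization is 100·(treated − control)/control on
tetramer/(tetramer+monomer) ratios, computed per donor and then averaged
(treated and control lanes are paired by donor); the group comparison
(means ± SEM, pairwise Tukey HSD) is a thin statsmodels report, not a
contribution. T4 displacement normalizes the TTR-bound fraction
TTR/(TBG+ALB+TTR) to the untreated control lane. Densitometry background
subtraction is assumed done upstream. Solubility reports per-replicate
weight/volume and the mean of the raw values, rounded half-away-from-zero
to 3 decimals for the report.

## Synthetic data

Every generator takes an explicit seed and draws from one local numpy
Generator (no global state), so outputs are bit-reproducible per
(parameters, seed). Defaults encode the assay conditions above: the
titration protocol, 10⁴-frame contact series, 0–96 h hourly unfolding
reads with reference ratios 0.9/1.6, and a 6-donor paired densitometry
panel. The contact generator draws the contact state Bernoulli(p) and
places contact distances uniformly just below the cutoff and non-contact
distances strictly above it, so the realized frequency equals the
Bernoulli draw exactly. The aggregation generator links occupancy to
aggregation by a deliberately simple mechanism-motivated fixture rule —
aggregation ∝ F₀, the fraction of protein with both sites empty, since
ligand binding blocks the dissociation-competent species — which makes
the noiseless dose–response monotone non-increasing; it is fixture logic
for testing the dose–response statistics, not a quantitative claim about
amyloid kinetics.

What the round trips show: that each analyzer inverts its generator —
algebraic stages exactly, fitted stages to optimizer precision, noisy
stages within stated statistical bounds. What they do not show: robustness
to features real instrument data carry that the generators deliberately
omit — baseline drift and peak-integration error in heats, photobleaching
in fluorescence, gel-background structure in densitometry, and model
misspecification generally (real kinetics need not be mono-exponential,
real noise need not be Gaussian or homoscedastic).

## Known limitations

- No raw-signal processing anywhere (power traces, spectra, gel images);
  inputs are integrated heats, intensity ratios and net band volumes.
- No global multi-experiment ITC fitting; one titration at a time.
- Distance-only contact criterion; no donor–H–acceptor angles.
- The positive-favorable MD energy scale and the negative-favorable ITC
  scale coexist by design and must not be compared numerically.
- First-site constants of very tight binders are not identifiable from
  single titrations at 5 μM cell concentration (see above); lowering cell
  concentration or displacement titrations would be required.
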