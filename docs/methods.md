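# Methods

## Aggregation model

Fibril formation is described by the standard two-moment reduction of
filamentous self-assembly: fibril number P(t) and fibril mass M(t) (monomer
equivalents) evolve as

    dP/dt = kn·m^nc + k2·m^n2·M
    dM/dt = 2·k+·m·P,        m(t) = m0 + M0 − M(t)

with primary nucleation (kn), fibril-surface-catalysed secondary nucleation
(k2) and elongation at both fibril ends (k+).  Fragmentation,
depolymerisation and saturation of either nucleation pathway are outside
scope, as are oligomer populations and spatial effects.  Total protein is
conserved exactly by construction; the integrator (LSODA, rtol 1e-10)
reproduces an independent Radau integration to ~4e-11 in normalized units.

Unseeded bulk experiments identify only the products k+kn and k+k2, so
those are the model parameters everywhere; the ODE integrator accepts an
arbitrary elongation constant to split the products and the normalized
unseeded solution is invariant to that split (asserted in tests).

The closed-form integrated rate law (see README) is used for fitting.  Its
parameters are the pathway rate scales λ = √(2·k+kn·m0^nc) and
κ = √(2·k+k2·m0^(n2+1)).

### Closure accuracy

The closed form is an approximate closure of the moment equations: exact at
t = 0, exact as t → ∞, and exact in the strongly secondary-dominated limit.
Measured against the ODE oracle (max absolute deviation in normalized
units, grid out to three half-times):

| κ/λ | 2 | 3 | 5 | 10 | 30 | 100 |
|-----|------|------|------|------|------|------|
| max dev | 0.085 | 0.061 | 0.037 | 0.017 | 0.007 | 0.006 |

The law is therefore quantitative (≲2%) in the secondary-dominated regime
κ/λ ≳ 10 that is characteristic of Aβ42, and degrades as primary nucleation
becomes comparable; its fitted half-time lags the exact solution by ~1.4%
at κ/λ = 10.  Because fits compare conditions against a reference fitted
with the same functional form, this systematic error largely cancels in the
reported rate *ratios*.

## Reaction orders and units

nc = n2 = 2 by default (the standard choice for Aβ42 monomer-dependence);
both are overridable on every model constructor.  Time is seconds and
concentration molar throughout; readers convert at the boundary (the plate
reader importer accepts minutes/hours).

## Global fitting

`AggregationKineticsModel` performs bounded least squares in
(log10 λ, log10 κ) space — an exact reparameterisation of the products at
fixed m0 and orders.  Working on the rate scales rather than the products
keeps the search box concentration-unit-free: bounds of [1e-8, 1e-1] s⁻¹
cover half-times from under a minute to years.  Eight deterministic starts
are used: a data-driven one (κ ≈ 10/t½ from the observed half-time, λ = κ/10),
plus seeded log-uniform draws; ties within 1e-9 relative loss resolve toward
the first start.  Standard errors come from the Gauss–Newton covariance at
the optimum and are reported on the log10-product scale.  Residuals are
unweighted by default (no error model is assumed); replicate standard
deviations can be used as weights.

Apparent (per-condition) fits refit both products.  Because an inhibited
curve can sit many decades from the reference, the refit starts both from
the reference parameters and from a half-time-rescaled copy (λ, κ scaled by
t½_ref/t½_obs), which lands near the optimum even for 10⁵-fold suppression.
A mechanism note records whether a kn-only or k2-only perturbation of the
reference reproduces the curve within 5% of the two-parameter loss (with an
absolute floor so noise-free fits compare sanely).

Wells with no baseline-to-plateau climb (flat: fully inhibited at the run's
horizon) and wells that never plateau are censored, never fitted: their
ratios are reported as upper bounds at the search-box floor with a flag.

## Normalization

y = (F − baseline)/(plateau − baseline), baseline the mean of the first 5
points and plateau the mean of the last 10 — robust for a 2-min cadence
over multi-hour runs.  The flat-well test compares the baseline-to-plateau
climb against the trace's full excursion (threshold 0.2), which is
invariant to affine transforms of the raw signal, as is the normalization
itself.  A plateau-drift check (relative drift > 5% of the dynamic range
across the last window) rejects unfinished runs.

## Seeded elongation analysis

Adding preformed fibrils at 30% monomer equivalents makes early growth
elongation-dominated, so the initial slope of the normalized signal reads
out k+ directly: dM/dt(0)/(m0+M0) = 2·k+·P0·m0/(m0+M0).

Seed number is derived from seed mass via a mean fibril length L (default
500 monomers): P0 = M0/L.  Seeded observables depend on k+ and P0 jointly,
so the package fixes one literature-magnitude elongation constant,
k+ = 7e5 M⁻¹s⁻¹, package-wide.  With L = 500 this choice balances the two
systematic errors of an initial-slope readout — monomer depletion (bias
∝ k+P0) and residual secondary nucleation (bias ∝ (k+P0)⁻¹) — at ≈2% each
and of opposite sign over the fitted window.

The slope window is the longest prefix with linear-fit R² ≥ 0.99 (minimum
5 points), additionally confined to the first 4% of the trace's observed
span.  The rise cap matters: a smooth saturating curve keeps R² above 0.99
far into its bend, so an R²-only window over-extends and biases slopes by
tens of percent.  The cap is a fraction of the observed span, hence
affine-invariant, and slope *ratios* (sample/control) are invariant to
common normalization errors.  Seeded pairs are generated at 5-s sampling
over 1 h — a kinetic-mode read of a well pair — because the initial linear
regime of a 30%-seeded reaction is too short to give a 5-point window at
the 2-min full-plate cadence.

`seeding_dominance_check` certifies the assay premise: integrating the same
seeded reaction with and without nucleation, the nucleation share of fibril
mass at the early-growth horizon (time to 10% added mass) is ~1.2% under
the default parameters — comfortably negligible.

## Synthetic data generator

Emulates the screening design: 1.5 µM monomer, antibody:monomer ratios
0.5/0.25/0.125, triplicates, 2-min cadence, 12-h horizon (an overnight
run, long enough for strongly inhibited wells to plateau); seeded mode uses
30% monomer-equivalent seeds.  Reference parameters are λ = 2.3e-4 s⁻¹,
κ = 2.3e-3 s⁻¹ at 1.5 µM — an uninhibited half-time of 40.6 min and a
secondary-dominated balance (κ/λ = 10) typical of Aβ42.  These are fixed,
plausible values, not measurements.

Each well maps M(t) to raw AU through a per-well affine transform (gain
U[800, 1200], baseline U[80, 120]) — deliberately forcing the normalization
path — plus multiplicative Gaussian signal noise (σ = 1%) and additive
baseline noise (2 AU).  Inhibitor effects multiply the rate products; the
built-in dose–response scales the log-suppression linearly with the
antibody:monomer ratio, so factors tend to 1 at vanishing antibody.  A
ground-truth manifest (JSON) records the design, reference parameters,
noise and per-condition true products; identical RNG seeds give
bit-identical files.

What the generator does *not* emulate: ThT photophysics and dye-binding
saturation, well-position and evaporation effects, lag-phase outliers,
non-Gaussian plate-reader artefacts, and any explicit antibody binding
equilibrium (effects are fixed multiplicative factors).  Passing recovery
tests therefore demonstrates that the fitting pipeline is correct and
well-conditioned under the stated noise model — not that real plates meet
that model.

## Thermal stability

CD melts are fitted with a two-state folded⇌unfolded model, ΔG(T) =
dH_vh·(1 − T/Tm) (ΔCp = 0 by default; a ΔCp term is available), with linear
pre- and post-transition baselines since raw ellipticity drifts.  The
initial Tm comes from the peak of the Savitzky–Golay-smoothed |dθ/dT|; a
curve whose derivative peak does not stand out (3× the median absolute
derivative) raises a no-transition error.  More than one separated
derivative peak flags a multistep melt — the two-state fit is then suspect
and no multi-state model is attempted.  Two variants are called
"indistinguishable" when |ΔTm| < 2·SE(ΔTm), the SEs taken from the fit
covariance (lmfit/leastsq).

## Intact-mass bookkeeping

Average masses are computed from residue elemental compositions and IUPAC
atomic weights (sum of residues + one water); a monoisotopic mode exists.
Deltas: Cys→Dha = −mass(H2S) = −34.08 Da; thia-Michael addition of a thiol
RSH to Dha = +mass(RSH) (the whole thiol adds across the alkene), e.g.
+77.15 Da for cysteamine.  Deltas compose additively, and an H2S "adduct"
after Dha conversion restores the cysteine-mutant mass exactly.  The
scaffold sequence (with N-terminal Met and His-tag kept verbatim) is built
in; Biopython's independent mass calculator agrees to 0.23 Da (average;
atomic-weight table differences) and 5e-5 Da (monoisotopic).

## Numerical choices and degenerate inputs

- Analytic branch requires both products > 0; zero products raise and the
  caller falls back to the ODE (which handles kn = k2 = 0 exactly).
- Normalized masses outside [0, 1] by more than 1e-9 raise rather than
  clip, to surface pathological parameters; within 1e-9 they are clipped.
- κt is capped at 500 inside the closed form; beyond that the bracket has
  saturated and e^{−k∞t} has underflowed, so the cap is exact.
- Half-times are found by geometric bracketing plus Brent's method.
- The canonical long CSV round-trips bit-exactly (shortest-roundtrip float
  text on write, round-trip parsing on read).

## Problem sizes

Recovery studies use 20 independent repeats; melt recovery 20 curve pairs
at 0.1 °C sampling over 20–98 °C; the oracle comparison 6 rate-ratio
regimes × 200 time points.  These sizes give stable pass/fail margins while
keeping the whole suite fast.

## Known limitations

- The closed-form law should not be trusted quantitatively for κ/λ ≲ 5
  (see table above); fit such data against the ODE directly if absolute
  parameters matter.
- Only rate-product *ratios* are meaningful across conditions; absolute
  products inherit any error in m0 and the assumed orders.
- Censored (flat-well) ratios are bounds tied to the search-box floor, not
  measurements.
- The elongation readout assumes seed number scales with seed mass (fixed
  mean length); systematic length differences between preparations would
  bias relative elongation.
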