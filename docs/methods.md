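# Methods

## The reaction network

The actomyosin ATPase cycle is integrated as a mass-action ODE system over
twelve state variables: eight myosin-containing species (the actin-detached
branch M, M·ATP, M·ADP·Pi, M·ADP and the attached branch AM, AM·ATP,
AM·ADP·Pi, AM·ADP) and four free pools (ATP, ADP, Pi, and F-actin binding
sites A). Concentrations are in µM, first-order rates in s⁻¹, second-order
rates in µM⁻¹s⁻¹. The transcribed rate-constant table
(`src/actokin/data/constructs.yaml`) stores every measured constant for the
three constructs, keeping alternates where the same constant was measured
with more than one optical signal; a precedence table (data, not code)
records which measurement feeds each derived ratio.

Representation choices, and why:

* **ATP binding to myosin** is a single effective second-order step with
  rate K₁k₊₂·[ATP]. The collision equilibrium is not resolved in the
  detached branch: only the effective constant is measured, and the single
  step preserves the pseudo-first-order identity k_obs = K₁k₊₂·[ATP] that
  the mant-nucleotide experiments report at sub-saturating ATP.
  Consequence (documented, deliberate): the simulated tryptophan k_obs
  against [ATP] is the relaxation of a two-step sequence
  (binding → hydrolysis) rather than a true binding-equilibrium hyperbola.
  Where the two rates are comparable the apparent hyperbolic maximum of the
  series overestimates the hydrolysis equilibration rate by 10–20%. The
  hydrolysis rate k₃+k₋₃ is therefore extracted from a *saturating*-ATP
  transient (binding ≥15× faster than hydrolysis; double-exponential fit,
  slow phase), which recovers it within ~1% and mirrors how the plateau of
  the experimental series is read.
* **ATP binding to actomyosin** is a rapid-equilibrium collision
  (dissociation constant 1/K₁; collision on-rate 100 µM⁻¹s⁻¹, fast enough
  that its equilibration never limits the observed rate) followed by the
  irreversible isomerization k₊₂ that releases actin. The hyperbola
  k_obs = k₊₂[ATP]/(1/K₁+[ATP]) then *emerges* from the simulation rather
  than being imposed; the residual rapid-equilibrium error is ≲1% at the
  concentrations used.
* **Hydrolysis** is a reversible first-order step whose forward and reverse
  rates sum to the measured k₃+k₋₃. The split is not measurable; the
  equilibrium constant defaults to 10 (favouring M·ADP·Pi) and is
  configurable (`hydrolysis_equilibrium`).
* **Phosphate release.** Basal release from M·ADP·Pi defaults to
  0.02 s⁻¹ (configurable; the actin-free turnover is not printed). Actin
  activation is realized as weak, fast mass-action binding of M·ADP·Pi to
  actin with dissociation constant K_app (on-rate 10 µM⁻¹s⁻¹) followed by
  release at k_cat from AM·ADP·Pi. With binding pre-equilibrated and
  release rate-limiting, the release flux reproduces the Michaelis–Menten
  envelope v([A]) = k_cat·[A]/(K_app+[A]) without inventing unmeasured
  microstates. Note that the *full-cycle* steady-state turnover of the
  simulated network is necessarily somewhat below this envelope (ADP
  release and rebinding also take time); the envelope parameters are
  recovered exactly by the dedicated curve generator + fit, which is how
  the steady-state analysis is defined.
* **Integration**: LSODA (stiff-capable) with rtol 1e-8, atol 1e-10 µM.
  Myosin and actin totals are checked to 1e-6 relative on every trajectory
  and any occupancy below −1e-9 µM raises; failures raise with solver
  diagnostics, never silently clip. Pseudo-first-order clamping holds
  selected free pools constant (all four, or a named subset such as
  `("ATP",)`).

## Observables

Signals are linear projections, signal(t) = baseline + Σ w_s·c_s(t), with
relative (unitless) weights — downstream fits treat amplitudes as free
parameters, so only weight orderings matter. Shipped tables: mant
fluorescence lights every nucleotide-occupied myosin state (1 vs 0); pyrene
fluorescence is quenched in strongly bound states (AM, AM·ADP at 0;
dissociated actin at 1; weakly bound collision/product states at 0.15);
tryptophan weights the post-hydrolysis state higher (1.25 vs 1.05/1.0),
reflecting the relay-loop tryptophan's response to the recovery-stroke
conformation; light scattering weighs attached mass; the NADH-coupled assay
is represented as accumulated product rather than a modelled enzyme
cascade — the cascade is instrumentation, the observable is the rate. A
construct whose intrinsic fluorescence does not respond to nucleotide is
represented by equal tryptophan weights across states, which provably
projects any trajectory to a flat signal.

## Fitting ladder

`fit_exponential` does bounded nonlinear least squares on 1–2 phases with
start values from a log-linear regression of the tail-subtracted signal and
restarts from ×0.1/×10/×0.01/×100 rate perturbations. A phase whose
amplitude falls below 3× the residual noise is suppressed (flagged, kept
separately) rather than reported; two phases whose rates differ by less
than a factor 1.5 are merged into a single-phase fit. Dead-time samples are
removed at generation (default 1.5 ms, configurable) before any fit.
Secondary fits: ordinary least squares for the sub-saturating linear regime
(slope = second-order on-rate, intercept = off-rate, with standard errors)
and bounded `curve_fit` for the saturating hyperbola; a series that does
not reach saturation still returns estimates but carries a wide-CI warning.
Michaelis–Menten ATPase fits work the same way, with an optional
basal-subtraction switch (default off — whether published k_cat values are
basal-subtracted is generally unstated).

## Derived constants

Equilibrium constants are off/on ratios with unit bookkeeping
(s⁻¹ ÷ µM⁻¹s⁻¹ → µM). Ratios of two release rates use chase-derived
measurements on both sides where available (a chase isolates the release
step); the ADP-affinity ratio uses the intercept-derived k₋D; the
nucleotide selectivity divides the mant-measured **k₊AD** by the
mant-measured **K₁k₊₂** (like signal against like signal). These choices
live in the shipped precedence table with the data. Any constant that is
not measurable for a construct propagates as an `Unavailable` carrying a
human-readable reason chain, mirroring how kinetic tables mark
inaccessible entries.

The duty ratio at actin concentration [A] and saturating ATP is computed as
v([A])/**k₋AD** with v the Michaelis–Menten flux — the attached-time
fraction when ADP release gates detachment. Values above 1 (possible when
the cycling flux estimate exceeds the release rate) are clipped to 1.0 and
flagged. For the charge-reversal mutant the three chase measurements of
**k₋AD** (0.19, 0.15, 0.14 s⁻¹) put the duty ratio between 0.85 and 1.0;
`duty_ratio_variants` reports all of them rather than hiding the spread.
One known bookkeeping discrepancy is surfaced deliberately: the R788E ADP
affinity computed from its printed on/off rates is 0.09/0.03 = 3.0 µM,
while the corresponding published summary value (~2.68 µM) implies inputs
that were not printed; the package reports the ratio of the printed inputs.

The thermodynamic-box diagnostic compares the two routes around the
actin/myosin/ADP cycle (K_AD/K_D vs K_DA/K_A). For a self-consistent rate
set they agree exactly; for the measured NM2C set they agree within a
factor 1.18 (0.106 vs 0.125) — reported, never enforced, since measured
sets carry experimental error.

## Structural metrics

PDB reading goes through gemmi behind a fixed-width pre-validator that
reports malformed ATOM/HETATM records with their line number. Altlocs keep
the highest-occupancy conformer (ties → 'A'); residue numbering follows the
file verbatim. Multi-MODEL files become trajectories with an enforced
shared atom roster. Superposition pairs atoms 1:1 by (chain, residue
number, atom name), requires ≥3 non-collinear atoms, and returns a proper
rotation (Kabsch via `Rotation.align_vectors`); the test suite checks it
against an independently implemented quaternion (Horn) closed form.
Hydrogen bonds default to a donor–acceptor heavy-atom distance ≤3.5 Å with
no angle term (crystal structures lack hydrogens; an optional angle cutoff
exists for hydrogenated trajectories). Contacts are classed `hbond` when
both atoms are N/O within the H-bond cutoff, else `vdW`, with a default
4.0 Å contact cutoff. Domain rotations superpose on a core selection and
report the axis–angle magnitude (0–180°) of the residual domain fit.
The pocket metric is an inscribed sphere: radius = distance from the
centroid of a center selection to the nearest non-selected protein heavy
atom, minus a probe radius, floored at zero. It is one plausible reading of
"the sphere that describes the active-site volume": shells at 5.50 and
9.0 Å give 696.9 and 3053.6 Å³, i.e. the published 697 → 3054 Å³ (4.3-fold)
comparison corresponds to inscribed radii of 5.50 and 9.0 Å under this
definition. Which atoms define the center is likewise a caller choice.

## Synthetic data

The generators exist so every stage is testable without downloads; all
ground truth is embedded in output metadata and identical (spec, seed)
pairs are bit-identical. Noise is additive iid Gaussian (absolute, or
relative to the noiseless amplitude); no photon-shot statistics, mixing
artifacts, bleaching or inner-filter effects are emulated — passing tests
therefore demonstrate correctness of the extraction logic, not robustness
to every instrument pathology. Concentration-series presets mirror the
standard experiment designs (mant-nucleotide binding to myosin and
actomyosin, tryptophan–ATP, pyrene-actomyosin dissociation, light-scattering
actin binding), simulate one transient per concentration with the window
scaled to ~6 predicted relaxation times, and fit each for k_obs. The
acto-ADP design uses a 100-fold actin excess over myosin (2 µM vs 0.02 µM)
because with equimolar actin the slow rigor-dissociation leak measurably
contaminates the intercept. Round-trip designs place concentration windows
around the relevant equilibrium constant (0.5–12× K) so slope and
intercept are jointly identifiable, average 3 replicates where the
intercept is the target, and use 16-point actin titrations to 5×K_app for
the steady-state fit; at 1% noise every targeted constant then returns
within 5% (worst observed ≈4% across seeds).

Structure generators build poly-alanine backbones from standard internal
coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; τ(N–CA–C) 111.2°,
ω = 180°) via NeRF placement, so φ/ψ used in construction are exactly
recoverable. Trajectory plants — an end-to-end rigid domain rotation about
a seeded random axis, an H-bond occupancy realized by assigning exactly
round(f·n) frames to the bound distance, a Cα angle set by repositioning
one atom in the plane of the triple — are exact by construction; optional
Gaussian jitter applies only to atoms not involved in any plant.

## Problem sizes and runtime

Default test problem sizes: 300–600 samples per transient, 7–8 (kinetics)
or 16 (ATPase) points per series, 3 constructs, 40–1000 frames per
synthetic trajectory, ≤500-atom clouds for geometry oracles. The entire
suite runs in a few seconds on one CPU; the acceptance script in well under
a minute.

## Known limitations

* No lever-arm mechanics, load dependence, or interhead gating; the duty
  ratio is a solution-kinetics quantity.
* No global multi-experiment fitting; constants are extracted one
  experiment at a time, as in the source analyses.
* The detached-branch ATP binding is an effective one-step process (see
  above); quantities that depend on resolving the collision equilibrium of
  the detached branch are outside the model.
* Uncertainties are asymptotic standard errors, not posterior intervals.
* mmCIF is not read in v1; structures must be PDB-format.
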