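# Methods

This note documents the models implemented in `socbalance`, their
assumptions, the defaults of the synthetic-data generator, and the design
choices made where the methodology was genuinely open.

## Depth conventions and stock integration

Depths are in cm, positive downward, with 0 at the *current* surface of
each profile; horizon intervals are half-open `[top, bottom)` so every
depth belongs to exactly one horizon. A degraded profile's local depth z
corresponds to reference depth `z + crack_depth`: the crack depth is the
vertical extent of topsoil already removed and aligns the two frames.

Stocks use `stock = 100·content·BD·depth` (kg ha⁻¹; content g kg⁻¹, BD
g cm⁻³, depth cm), converted to kg m⁻² by 10⁻⁴. Content and BD are
treated as uniform within a horizon, so a horizon crossing the
integration limit (default 30 cm) contributes the prorated part of its
thickness. Profiles shallower than the limit contribute their full depth
with a logged warning rather than an error — pedons on eroded plots are
often shallower than 30 cm. Stocks are compared at fixed depth, not at
equivalent soil mass; with bulk density rising along the degradation
gradient a fixed-depth comparison samples more mineral soil at degraded
stages, which is conservative for the loss estimate. An equivalent-mass
variant would be a natural extension but is deliberately out of scope.

## Loss partitioning and the closure identity

For degraded stage s with stage-mean crack depth e:

* **Erosion loss** integrates `c_ref(z)·BD_ref(z)` over reference depths
  `[0, e]`, per reference replicate (the eroded material no longer exists
  on the degraded plots, so only the reference can price it). The eroded
  soil mass is the BD integral over the same window. The point estimate
  uses the stage-mean crack depth; the spread of per-plot crack depths is
  folded into the SE in quadrature with the between-replicate spread.
* **Mineralization / reduced-input loss** works horizon-by-horizon in
  the reference frame: for each reference horizon slice inside
  `[e, 30 cm]` (mean boundaries across S0 replicates), the loss is the
  reference slice stock minus the degraded stage's content×BD over the
  same slice thickness. Degraded horizons are matched to surviving
  reference horizons by ordinal position after dropping fully eroded
  ones; label mismatches warn, count mismatches abort. A partially
  eroded reference horizon contributes its eroded part to erosion and
  its remainder to this bookkeeping — without that split the components
  would not conserve mass.
* **Total loss** is reported in two windows. The headline number
  compares each stage's stock over its own `[0, 30 cm]`; the closure
  bookkeeping integrates the degraded stock from its surface down to
  *reference* depth 30 cm. In the reference-frame window the three
  quantities satisfy `total = erosion + mineralization` exactly on
  noise-free data (an algebraic identity, verified to ≤1e−10 kg C m⁻²
  across randomized scenarios in the test suite). Both windows are
  computed and their difference logged; they coincide when the degraded
  pedon is shallower than `30 − e` cm and diverge when deep horizons
  back-fill the local window.

**Closure test.** Per stage, per-replicate total losses are compared with
erosion + per-replicate mineralization losses by a two-sided Welch
t-test (α = 0.05) — the least-assumption two-sample default; the test
suite checks its accept/reject decisions against a permutation oracle
(≥95% agreement). Degenerate zero-variance inputs are resolved directly
(identical means → p = 1). Note that when replicate noise enters content
and BD only, the per-replicate total and component sums are algebraically
correlated and the test accepts trivially; the test has power against
thickness, crack-depth and measurement-model discrepancies, which is
what it is for.

## Meta-analysis engine

Inclusion criteria are applied record-wise with a per-study reference
check: a degradation classification must be present, at least one of
SOC/N/BD reported, depth intervals given and exactly 10 cm wide, and the
study must contain a non-degraded reference. Label→stage regrouping is
an explicit table (`DEFAULT_STAGE_MAPPING`, user-overridable via CSV or
config); labels are matched case-folded and never guessed, because
regrouping verbal degradation descriptions is a judgment call that must
stay visible. The printed form of the effect-size equation in the field
literature, `ES = (D−R)/(R·100%)`, is dimensionally inconsistent with an
effect "in %"; the implementation uses `ES = 100·(D−R)/R`, which is what
the stated sign interpretation and all reported percentages require.

Effects are computed on stocks whenever both sides have BD (SOM converted
to SOC by the factor 2.0 first), otherwise on contents, with the basis
recorded per effect; aggregation is the simple mean ± SE per
variable × stage × depth cell with equal weighting of observations.
Inverse-variance weighting and publication-bias diagnostics are
deliberately out of scope — the engine reproduces the plain-means
convention of the degradation-gradient literature.

## δ¹³C–lignin two-pool mixing

Bulk SOC is modelled as lignin C (δ¹³C = δ_plant − depletion, default
4.3‰) plus a non-lignin residue whose δ¹³C is held fixed between the
compared states. The measurable VSC phenol fraction is corrected to a
lignin-C fraction by dividing by the CuO recovery (default 0.38), so a
change Δf of the lignin fraction shifts bulk δ¹³C by `Δf·(−4.3‰)`.
Whether reported "% of SOC" lignin values are raw VSC fractions or
already recovery-corrected is ambiguous in practice; both conventions
are implemented behind the `correct_recovery` flag, with division by
recovery as the default (the corrected shift equals the uncorrected one
divided by the recovery, exactly). Kinetic ¹³C fractionation of the
residual pool during advanced decomposition is outside the model and is
flagged in the CLI output note; the observed bulk shift is therefore an
explicit user input, never inferred from chosen endpoints.

## Synthetic-data generator

The generator defines the study conditions for all validation. The
reference pedon has horizons 0–5–15–25–35 cm with content
`c(z) = c₀·e^(−kz)` (c₀ = 68 g C kg⁻¹, k = 0.006 cm⁻¹) and bulk density
`b(z) = 0.58 + 0.019·z` g cm⁻³, evaluated at horizon midpoints. Stage
erosion depths (2, 4.5, 7, 9.5, 11.6 cm) and mineralization factors
`f = 1 − intensity·depth_weight` (intensities 0.08…0.42, weights 1.0,
0.9, 0.6, 0.3 — mineralization is strongest near the surface) produce a
reference 0–30 cm stock of ≈16 kg C m⁻², a final-stage eroded soil mass
of ≈82 kg m⁻² carrying ≈5.4 kg C m⁻², and an ≈2:1
erosion:mineralization split — magnitudes chosen to be visually
comparable to published degradation sequences of this ecosystem without
claiming to reproduce any particular site. Four replicates per stage
with 10% CV multiplicative Gaussian noise (truncated at 5% of the mean)
on contents and bulk densities mirror the usual field design; crack
depths are deterministic per stage so the generative truth is well
defined. δ¹³C is set per stage from the two-pool rule with the
non-lignin end-member equal to bulk plant tissue (−26.5‰), which makes
the generated isotopic shifts fully lignin-attributable — the round-trip
test exploits exactly this.

The literature-corpus generator gives every study a reference and 1–5
degraded stages at 10-cm intervals, a study-level Gaussian effect
deviation (default SD 8 percentage points around stage-truth effects of
−8…−42%), SOM-instead-of-SOC reporting with probability 0.3 (contents
doubled and flagged) and missing BD with probability 0.2. What the
generator does *not* emulate: real horizon-thickness variability between
replicates, correlated content–BD errors, within-study depth trends in
the effect, non-10-cm reporting, or any microbial/enzymatic variables —
so passing tests demonstrate estimator correctness under the stated
noise model, not robustness to every pathology of field data.

## Numerical choices

* Means ± SE with `ddof = 1`; SE is NaN for n = 1 and such cells are
  reported, not dropped.
* Horizon contiguity and boundary checks use an absolute tolerance of
  1e−9 cm; stage-mean crack depths are compared to profile depth with
  the same guard.
* CSV output is written at 6 significant digits with a commented header
  carrying the package version and the active configuration; round-trip
  tests assert equality at that declared precision.
* All random draws flow from a single `numpy` Generator seed; no global
  state is touched.

## Known limitations

* No equivalent-soil-mass correction (see above).
* The partitioning is C-only; N stocks are computed but not partitioned.
* The mineralization component conflates reduced C input with
  accelerated mineralization by construction; separating them needs
  flux data the stock bookkeeping cannot supply.
* The meta-analysis engine performs no study retrieval and no
  random-effects modelling.
* Import adapters for repository-native profile formats are an
  extension point; only the package's own CSV schema is parsed.
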