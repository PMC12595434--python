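# Methods

## The melt-shift model

A protein's soluble fraction after brief heating is modeled as a
three-parameter logistic in temperature,

    f(T) = plateau + (1 − plateau) / (1 + exp((T − tm) / slope)),

with the upper asymptote fixed at 1 because curves are normalized to
non-denatured reference samples. `plateau` is the residual heat-stable
fraction, `slope` the transition width in °C, and `tm` the midpoint. The
melting temperature proper is defined as the temperature where f crosses
0.5; for plateau > 0 this sits above the midpoint by
`slope · ln((1 − plateau)/(0.5 − plateau) − 1)`, and the synthetic ground
truth records the crossing, not the midpoint. Ligand engagement is
modeled as an additive shift of the treated-condition midpoint; the
vehicle curve is shared.

## Normalization

Stages run strictly in order and tag their output:

1. **Depth scaling.** Each denaturation run's abundances are multiplied by
   `precursor_count(run) / mean(condition precursor counts)`. This is the
   multiplicative convention (deeper runs scaled up); the conventional
   inverse correction is available via `invert_scaling`. Reference runs
   are excluded from the mean and never rescaled.
2. **Per-protein median division.** For each condition, every value of a
   protein (including its reference runs) is divided by the median of its
   non-missing values across that condition's denaturation runs.
   Reference runs are excluded from the median itself — they are not part
   of the melt series — but must be divided by it so that stage 3 can
   return curves on the absolute 0–1 scale. Proteins with no usable value
   in a condition are left missing and flagged, never zero-filled.
3. **Reference division.** Per condition, each protein is divided by its
   median across the reference runs; proteins absent from the references
   fall back to the median over proteins of the per-protein reference
   medians.
4. **Missing-pattern filter.** A curve (protein × condition × replicate)
   is dropped iff it has more than 3 missing values across the 10 ladder
   temperatures and is not complete over the 5 lowest temperatures. The
   exception keeps early-melting proteins that legitimately vanish from
   the upper ladder.

On noiseless, complete, equal-depth synthetic data the composition of
stages 1–3 returns exactly the analytic melt curve (unit asymptote),
which the test suite asserts to 1e−9. Medians of even-count sets are the
mean of the two central values throughout.

## T\_m estimation

Three branches, applied per curve:

- **direct** — if a measured point lies within 0.5 ± 0.05, its ladder
  temperature is returned (closest to 0.5 wins; equidistant pairs resolve
  to the lower temperature, with distances rounded at 1e−9 so that
  0.5 ± d pairs tie despite float error);
- **spline** — otherwise a natural cubic interpolating spline through the
  non-missing points is evaluated on a 0.01 °C grid over the ladder range
  and the lowest grid temperature where it crosses 0.5 from above is
  returned (≥ 4 points required);
- **fallback** — with no crossing, T\_m is the ladder maximum (64 °C),
  tagged so downstream consumers can exclude saturated estimates.

Accuracy of the spline branch is limited by the ladder geometry, not by
noise: the edge intervals of the 10-point ladder are 3.7 and 2.8 °C wide,
and cubic interpolation of a sigmoid with a ~2 °C transition there can
err by up to ~0.07 °C, versus ≤ 0.05 °C for crossings in the
well-sampled interior (documented bounds asserted in the test suite; we
verified that not-a-knot, clamped, quintic, PCHIP and Akima interpolants
do not improve the worst case). A logit-space spline would be exact for
plateau-free curves but amplifies tail noise catastrophically (90th
percentile T\_m error grows from 0.4 to 5.5 °C at the study noise level),
so the plain abundance-space spline is kept.

## Shift testing and hit calling

ΔT\_m is the difference of condition means over replicate T\_m values
(replicates are not paired across conditions). The replicate-level test
is a two-sided Welch t-test by default; an exact/Monte-Carlo permutation
test is available. Zero-variance-both-sides degenerate inputs yield p = 1
for equal means. A hit requires |ΔT\_m| ≥ 1.5 °C and p < 0.05 (raw
p-values by default, mirroring common practice; Benjamini–Hochberg
adjustment is optional). The robustness flag requires the per-condition
coefficient of variation of replicate T\_m values to stay below 0.1 in
every condition. Results sort by |ΔT\_m| descending.

## Screen and titration analytics

Velocities are OLS slopes of fluorescence vs. time (optionally windowed;
≥ 3 samples). A compound well is a screen hit iff its velocity is at or
below 2× the mean velocity of the full-inhibition (DEAB) control wells;
plates whose DMSO mean does not exceed their DEAB mean are rejected as
degenerate. Percent inhibition is reported on the DMSO–DEAB scale,
clipped to [0, 100].

Dose-response curves use the 4-parameter logistic fitted in
log-concentration space with 5 data-driven starts (IC₅₀ starts sweep the
measured concentration quantiles) to avoid the well-known local minima;
the Hill magnitude is bounded to [0.2, 10], and fits with top < bottom
are reported with swapped asymptotes and negated Hill so top ≥ bottom
always holds. Binding isotherms use the 1:1-site hyperbola
`baseline + amplitude · L/(L + Kd)` with Kd fitted on a log scale; fits
whose amplitude is negligible against the residual spread are flagged
unidentifiable rather than reported.

Inhibition mode is classified from apparent Michaelis–Menten parameters
per inhibitor level (20% tolerance bands relative to the zero-inhibitor
level): Km constant with Vmax falling → noncompetitive; Vmax constant
with Km rising → competitive; both falling in proportion →
uncompetitive; anything else → mixed. Double-reciprocal slopes and
intercepts are reported as diagnostics only — the classification never
relies on the (noise-fragile) reciprocal transform.

## Chem triage

Descriptors are RDKit's: average-mass MW, Crippen cLogP, Lipinski
donor/acceptor counts, Ertl TPSA. The published LogP values of the lead
compounds differ from Crippen estimates by up to ~0.8 (the originating
tool is unknown), so LogP windows are configurable and LogP is excluded
from exact-value checks; MW, TPSA and donor counts agree exactly after
integer rounding. The virtual-screen funnel windows (MW < 450,
cLogP 1–3, HBA 1–5, HBD 1–3, TPSA < 140) and the tighter lead-profile
thresholds (MW < 350, cLogP < 3.5, HBD ≤ 2, TPSA < 120) ship as presets.
Docking ranks are inputs; the combined score is their minimum, sorted
ascending with ties broken by the first scorer's rank, then id. Diversity
selection is greedy sphere exclusion in combined-rank order: keep a
compound iff its ECFP4 (Morgan radius-2, 2048-bit) Tanimoto similarity
to every kept compound is below 0.52, so each similarity cluster is
represented by its best-ranked member. Tanimoto of two empty
fingerprints is defined as 1.

## Synthetic data: what it emulates and what it does not

The melt simulator reproduces the statistical structure the analysis
assumes: a 10-temperature ladder (36.9–64.0 °C), two conditions × three
replicates plus per-replicate non-denatured references, lognormal
multiplicative noise (intensities are positive and heteroscedastic),
uniform missingness, contaminant entries, single-peptide entries, and a
spiked subset of stabilized proteins. Defaults are the study conditions:
2,000 proteins, 20 spiked with shifts ~|N(4, 1)| °C, noise σ = 0.03,
2% missingness, T\_m drawn from 44–58 °C with transition widths 1–3 °C
and plateaus 0–0.2. Per-run sequencing depth is equal by default
(`depth_sigma = 0` ⇒ unit scaling factors); tests that exercise the
scaling stage raise it explicitly. One seed drives all draws through
spawned generator substreams, and identical seeds give byte-identical
datasets.

Not emulated: correlated (batch) noise across runs, intensity-dependent
missingness, irregular non-sigmoidal melters, protein-inference
ambiguity, or real contaminant abundance profiles. Passing recovery
tests therefore demonstrates correctness of the analytic chain under the
assumed noise model, not robustness to every pathology of real
acquisitions. The screen simulator draws true-hit velocities below the
control-derived cutoff by construction, so hit-calling tests check the
decision rule, not assay realism. The compound library is built
combinatorially from amide/sulfonamide/aminomethyl linkers over small
aromatic and aliphatic fragments — drug-like enough to exercise
descriptor windows and fingerprint clustering, with random rank
permutations standing in for docking scores.

## Problem sizes and determinism

The shipped test-and-reproduction workloads use 2,000-protein melt
simulations, 100-seed titration ensembles, 80-compound plates and
80-compound libraries — sizes at which every check completes in seconds
while estimator variance is still well below the asserted margins. All
stochastic tests are seeded; the reproduction script derives every
substream from its single `--seed` argument.

## Known limitations

- T\_m estimates are quantized to the 0.01 °C evaluation grid and capped
  at the ladder maximum; fallback estimates cluster at 64 °C by design.
- The spline edge-interval error bound (~0.1 °C) applies to transitions
  of ≥ 1.5 °C width; narrower transitions between sparse knots are
  under-resolved by any interpolant at this ladder spacing.
- The CV robustness filter operates on replicate T\_m values; other
  readings (e.g. CV of curve residuals) exist but are not implemented.
- Cooperative (non-hyperbolic) enzyme kinetics and multi-site binding
  are out of scope; the mode classifier assumes Michaelis–Menten form.
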