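# Methods

## The model

quiflux models central carbon metabolism of cultured fibroblasts as a
flux-balanced network at metabolic steady state: pool sizes and fluxes
are constant over the labeling experiment, and only the isotopic
composition of each pool evolves after the switch to a ¹³C-labeled
nutrient. The network covers glycolysis (hexose-P → FBP → triose-P →
3PG → PEP → pyruvate → lactate), the oxidative PPP (hexose-P →
pentose-P + CO₂), the non-oxidative PPP return (3 pentose-P → S7P
intermediate → 2 hexose-P + 1 triose-P), a TCA segment (acetyl-CoA +
OAA → citrate → α-ketoglutarate → succinate → malate → OAA), reductive
carboxylation of α-ketoglutarate back to citrate, ATP-citrate lyase,
fatty-acid synthesis and breakdown through a slow acyl reservoir, and
glutamine entry via glutamate. Oxaloacetate is a zero-pool mixing node
(it is not measurable separately from malate); mitochondrial and
cytosolic compartments are not distinguished.

Free parameters are the eleven fluxes F0–F5, F7, F8, F10–F12 (units
nmol/min/µg protein), the latent hexose-phosphate sub-pool F9, the
latent citrate fraction, and the pool sizes of unmeasured metabolites
(acetyl-CoA, fatty-acyl units). The measured exchange rates A–D and the
steady-state balance of every node determine the remaining quantities:
X (protein-synthesis drain on glutamate), Y (pyruvate carboxylase
anaplerosis), Z (net malate → OAA), citrate synthase F6 = Y + Z, and
non-negative biosynthetic closure drains (nucleotide synthesis from
pentose-P, glycerol-3-P for lipids, hexose-P biosynthesis, fatty-acid
synthesis, malate-derived amino acids). A parameter set whose balance
forces any of these negative is rejected as infeasible.

## Labeled-form bookkeeping

Isotopologues are tracked coarsely as "metabolite + number of ¹³C
atoms", the granularity of triple-quadrupole measurements. Each tracer
experiment has its own state list: 36 labeled-form balances for the
[U-¹³C]-glucose switch and 19 for the [U-¹³C]-glutamine switch, 55 in
total. Reactions carry explicit per-form conversion channels; channel
rates are the reaction flux times the product of the substrate form
fractions (multilinear mass action). Three coarse-graining rules keep
the state space closed and are declared in the network configuration
itself so that an automated audit can verify, channel by channel, that
¹³C atoms and total carbon balance:

- Same-pool co-substrates (the triose pair in the FBP exchange, the
  pentose pair consumed by transketolase) are treated as co-labeled
  ("cohort" channels), making those rules linear.
- A handful of low-abundance product forms (4×-α-ketoglutarate,
  6×-citrate, acetyl-relabeled 2×-citrate under the glutamine tracer)
  are excluded; the producing channels project onto the nearest tracked
  form with the displaced ¹³C recorded as an explicit label write-down.
- The fatty-acyl pool is a quasi-static reservoir: it exchanges label
  at its inflow rate but is exempt from steady-state balance, standing
  in for slow lipid turnover.

Latent sub-pools never label: the citrate latent fraction and the F9
hexose-P pool are constant unlabeled compartments mixed into the
*observed* fractions after integration, exactly as they would dilute a
measured isotopologue distribution.

The ODEs are integrated with LSODA at rtol 1e-8 / atol 1e-10 (pool
turnovers span minutes to days, so the system is stiff); a
tolerance-refinement test guards the choice. Production rates evaluate
the bilinear channels on fractions clamped to [0, 1] so that small
solver excursions outside the simplex cannot amplify; the linear
consumption term restores them. Asymptotic labeling is obtained by
integrating to 50 times the slowest turnover and verifying that a
doubled horizon moves no fraction by more than 1e-4.

## The [1,2-¹³C] convergence ratio

Lactate made by direct glycolysis from [1,2-¹³C]-glucose carries two
labels; lactate made from carbon that took the oxidative-PPP detour
(losing C1 as CO₂) carries one. The expected 1×:2× production ratio is
computed by positional bookkeeping through the canonical transketolase/
transaldolase atom maps. By default the computation is single-pass —
returned hexose-P re-enters glycolysis but not the PPP, and the ratio
follows a closed-form probability chain. With re-entry enabled, the
positional composition of the hexose-P pool is solved by fixed-point
iteration over label-pattern distributions, with cycle co-substrates
drawn independently (well-mixed pools). A Monte-Carlo molecule-tracking
oracle in the test suite checks both modes. The ratio of two forms
filling the same well-mixed lactate pool is time-invariant, so the 2 h
sampling value equals the asymptote under the model's assumptions; both
are exposed. The ratio is invariant under uniform flux scaling and
strictly increasing in the PPP share.

## Cost and identification

A candidate is scored as 1 + the weighted mean of squared σ-scaled
residuals per data block (labeling dynamics, asymptotic labeling, pool
sizes, exchange rates, convergence ratio); the floor of exactly 1 for a
perfect fit makes costs comparable across datasets. σ falls back to 5%
of the observed value with a small absolute floor when a block carries
no measured SD. Infeasible candidates receive an infinite sentinel cost
rather than being repaired.

Fluxes are identified by a tournament genetic algorithm on log₁₀
parameters: population 200, tournament size 3, uniform crossover
p = 0.7, per-gene log-normal mutation (p = 0.1, σ = 0.3 decades),
elitism 2, log-uniform bounds 1e-4–1e2, convergence when the best cost
improves by less than 1e-4 over 30 generations. All defaults are
exposed in `GaConfig`; the elitism guarantee (non-increasing best cost)
and seed-exact reproducibility are tested. Independent restarts whose
converged cost lies within (1 + δ) of the best cost found (δ = 0.05 by
default) form the ensemble of "consistent" solutions; per-restart seeds
derive deterministically from the master seed. Two conditions are
declared different on a parameter only when the two ensembles' observed
[min, max] ranges are disjoint — a deliberately conservative rule; a
quantile-trimmed variant exists but is off by default.

## Synthetic data

The generator emulates the study conditions rather than any particular
measured values. The four presets (proliferating, CI7, CI14, CI14SS7)
encode the qualitative contrasts of the biology: CI14SS7 glycolytic
fluxes and glucose uptake at half the proliferating values; a TCA cycle
truncated at citrate in proliferating cells (F7 ≈ 0, and a near-zero
reverse flux F11, so that the non-latent citrate pool labels almost
completely within 2 h); higher non-oxidative PPP return, pyruvate
anaplerosis and reductive carboxylation under contact inhibition; a
0.40 latent citrate fraction in proliferating cells (0.20–0.25
elsewhere). Absolute flux magnitudes are fixtures in the 1e-4–1e-1
nmol/min/µg range chosen once for feasibility; pool sizes derive from
target turnover times (3–30 min for central pools, ~33 h for the
fatty-acyl reservoir) so that labeling dynamics span the sampling
grids. Sampling mirrors the protocols: dense points in the first 2 h
for both tracers plus 4 h and 8 h points for glutamine; 48 h medium
curves at 6 h spacing with fifteen replicate measurements per point
(three experiments of five replicates); a 2 h convergence-ratio
observation. Noise defaults: additive SD 0.02 on labeling fractions
(clipped to [0, 1]), 10% CV on pools and raw signals, 1% relative SD on
medium concentrations.

What passing tests on these data do and do not show: they demonstrate
that the estimators and the fitter recover the generating truth under
the assumed noise structure (independent Gaussian errors, exact
metabolic steady state, a correctly specified network). Real LC-MS/MS
data add natural-abundance effects, correlated run-to-run drift,
peak-integration error and possible model misspecification, none of
which the generator emulates; recovery here is a necessary, not a
sufficient, condition for accuracy on real data.

## Measurement-side conventions

- Exchange rates divide the amount change in the medium by the time
  integral of plate protein mass; the default estimator regresses
  concentration on the cumulative protein integral over all points and
  replicates (identical to Δamount/∫protein for two points), and an
  endpoint-protein variant is exposed.
- The blank filter keeps a metabolite if *any* sample reaches 5× the
  medium-only blank; zero blanks are floored at the below-detection
  sentinel (100), and sentinel entries are flagged censored, not used
  as measurements.
- The pool-level screen uses Welch's t on log levels against the
  reference condition with Benjamini–Hochberg correction at FDR 0.05.
- The latent-pool estimator is the minimum unlabeled fraction over all
  time points and tracer switches, clipped to [0, 1].
- The glutathione assay reports total glutathione equivalents
  GSH + 2·GSSG, so the redox ratio is (total − 2·GSSG)/GSSG.
- [3-¹³C]-glucose anaplerosis ratios (1× : unlabeled citrate or malate)
  are descriptive only and never enter the cost.

## Problem sizes

GA-heavy properties (ensemble recovery, the deliberately degenerate
parallel-flux pair, noise-widening of ensembles) run on a small
branched toy network where each cost evaluation is milliseconds; the
full 55-state model is exercised by single GA runs on a reduced gene
set and by direct cost evaluations. The analysis scripts fit
scaled-down ensembles (populations of a few dozen, a handful of
consistent restarts) by default and expose a `--full` flag for the
complete gene set with a larger budget.

## Known limitations

- Coarse ¹³C-count granularity cannot represent positional isotopomer
  effects outside the dedicated convergence-ratio computation; no
  EMU/cumomer machinery is included.
- No natural-abundance correction: measurements are assumed corrected
  upstream.
- The non-overlap significance rule depends on ensemble extremes and
  is noisy for small ensembles; verdicts from scaled-down runs are
  illustrative.
- Protein breakdown returning unlabeled glutamate is not modeled, so
  the late-time drop of fully-labeled glutamate seen in quiescent
  cells is outside the generator's repertoire.
- The infeasibility boundary makes the GA search space non-convex;
  initialization retries and restarts mitigate but do not remove the
  risk of dead starts when measured rates pin large parts of
  glycolysis.
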