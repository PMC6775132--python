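# Methods

## Overview

`metscreen` identifies candidate metabolite–transcription-factor (TF)
interactions from paired time-course omics. The reasoning chain is:

1. TF activities are latent. They are inferred from gene expression
   with network component analysis (NCA), using a curated regulatory
   network as a structural prior.
2. Allosteric regulation of a TF by a metabolite follows Hill-type
   kinetics, so a genuine effector's concentration should map onto the
   TF's activity through a sigmoid.
3. Time-course correlation alone produces many false positives
   (co-varying metabolites are ubiquitous in a strong physiological
   perturbation), so candidates must additionally be close to the TF's
   regulon in the metabolic network.

## Activity inference (NCA)

Expression `E` (genes × time points, log10 TPM) is factorized as
`E ≈ A·P` by minimizing `‖E − A·P‖²`, where the zero pattern of `A`
(genes × regulators) is fixed by the known regulatory network and `P`
(regulators × time) is the activity. A *global basal regulator*
connected to every gene absorbs RNA-polymerase baseline expression.

The solver is alternating least squares (ALS): given `A`, `P` is the
global least-squares solution; given `P`, each gene's nonzero
coefficients are re-estimated by least squares on that gene's
regulators only, so the zero pattern is preserved exactly and the
residual is monotone non-increasing. Per-gene subproblems with
condition number above 1e8 fall back to a small ridge penalty (1e−6)
so pathological topologies stay solvable. Iteration stops when the
summed squared residual changes by at most 1% (relative), with a
500-iteration safety cap.

ALS on this problem has genuine local optima: on noiseless synthetic
data some random initializations reach the exact factorization
(residual ~1e−27) while others stall at a plateau. This is why the
method runs an ensemble of randomized restarts (default 100).
Summarizing the ensemble requires two decisions the objective does not
make by itself:

- **Restart pruning.** Restarts whose final residual exceeds 1.5× the
  best restart's residual are treated as trapped in a poor optimum and
  excluded from the summary. Restarts that found the same basin agree
  on the residual to roughly the stopping tolerance; a 50% excess is a
  conservative cut that keeps genuinely equivalent solutions.
- **Scale and sign alignment.** `(A, P)` is only identified up to a
  per-regulator scale (and, through the basal regulator, offset), so
  each kept restart's activity rows are z-scored over time and
  sign-aligned by correlation to the lowest-residual restart. The
  remaining global sign per regulator is anchored to the annotated
  activation/repression signs of the input network by a
  magnitude-weighted vote over all kept restarts' recovered weights;
  without this, activation and inhibition calls downstream would be
  arbitrary. Regulators with no sign annotation keep the reference
  orientation.

The ensemble mean and pointwise 2.5/97.5 percentile band summarize the
activity; the band is widened minimally where percentile rounding on
small ensembles would exclude the mean. The *relative CI width* — mean
band width divided by the regulator's activity range — is the quality
score used by the TF filter ("confidence interval > 100%" means this
ratio exceeds 1). Reported variance explained is
`1 − ‖E − AP‖²/‖E − rowmean(E)‖²`, clamped to [0, 1].

## Hill-kinetics screen

For each metabolite–TF pair, the sign of the Pearson correlation picks
the model form: activation `y = y_max·xʰ/(xʰ + K_Hʰ)` or inhibition
`y = y_max·K_Hʰ/(xʰ + K_Hʰ)`, with `x` the metabolite concentration
(µM), `K_H` the activation constant and `h ∈ (0, 10]` the Hill
coefficient. Exact zero correlation tie-breaks to activation and is
flagged.

Inferred activities are z-scored and can be negative while the Hill
forms are nonnegative, so the output passes through an affine layer:
given `(K_H, h)` the transform `u(x)` is computed and `(y_max,
baseline)` solved by ordinary least squares — a nested formulation that
reduces the nonlinear problem to two parameters. Those are fitted by
L-BFGS-B (bounded, log-scale `K_H`) from 50 random starts (`K_H`
log-uniform over [min positive x/10, 10·max x], `h` uniform on (0,
10]). Each pair is fitted at lag 0 and with the TF activity shifted
back by one time point (expression responds after the metabolite
moves; the lag-(−1) convention pairs activity at t_{i+1} with the
metabolite at t_i); the better R² wins. R² is `1 − SS_res/SS_tot` of
the measured activity against the transformed metabolite levels — this
definition gates the 0.75 screening threshold — and Pearson's squared
correlation is reported alongside.

The two time grids (transcriptome vs denser metabolome) are paired by
nearest-neighbour matching within a 1 h window on the replicate-mean
profiles; unmatched points are dropped and counted, and pairs with
fewer than six common points are skipped with a recorded reason.
Multistart seeds derive from a hash of (master seed, metabolite id, TF
id), so results are deterministic and independent of input row order.

## Metabolic-network distance criterion

From a stoichiometric model, cofactors (explicit list; a default
currency-metabolite list ships with the package) and non-cytosolic
(periplasmic/extracellular) metabolites are pruned from `N`; the
metabolite–gene adjacency is `F = |N|·G` with `G` the boolean
reaction–gene matrix (any gene in a reaction's boolean rule counts —
distances need reachability, not enzyme logic), and `F′ = bool(F)`
defines an undirected bipartite graph. `|N|` is used so substrates
(negative coefficients) and products (positive) both yield adjacency.
Breadth-first search gives all metabolite–gene distances; finite
distances are odd by bipartiteness, and a metabolite–TF distance is
the minimum over the TF's target genes.

A pair passes the criterion if (1) the metabolite is a substrate or
product of an enzyme encoded by a target gene (adjacency, distance 1),
or (2) it shares a metabolic subsystem with such an enzyme — a
distance-free condition. TF subsystems are the union over reactions
encoded by its targets; metabolite subsystems come from a user
annotation table, defaulting to the subsystems of adjacent reactions.
Metabolites absent from the model (and unannotated) yield a
*not-computable* verdict, distinct from a failure.

## TF filters

Before the screen, TFs are excluded when (i) |Pearson correlation|
between the activity profile and the binary growth-phase indicator
(1 in either growth phase, 0 in starvation) is ≥ 0.9 — such "on-off-on"
profiles track the perturbation itself and correlate with every
growth-coupled metabolite; the absolute value is used because an
off-on-off profile is the same trivial coupling with opposite sign —
(ii) the relative CI width exceeds 1 (poorly estimated activity), or
(iii) the TF belongs to a user-supplied two-component-system list
(driven by external signals rather than internal metabolites). The
basal regulator never enters the screen. A candidate interaction must
clear all three gates: R² > 0.75, distance criterion, TF retained.

## Synthetic data generator

The generator emulates the structure of a bioreactor
growth → carbon-starvation → regrowth switch: 29 transcriptome and 35
metabolome time points over 20 h (phases split at ≈5.7 h and ≈17.9 h),
duplicate samples, additive Gaussian noise of 0.065 on log10 expression
(≈16% relative error) and 18% lognormal noise on metabolite
concentrations. The default network is deliberately desk-scale — 150
genes, 12 TFs plus the basal regulator, 20 metabolites with 10 planted
interactions — so that the 100-restart inference and the 50-start Hill
screen run in minutes; the statistical structure, not the size, is
what the recovery tests exercise.

Design choices that matter:

- **Identifiable topology by construction.** Every TF owns one
  exclusive gene no other TF targets; remaining genes draw a primary
  TF plus sparse extras. This guarantees pairwise-distinct target sets
  and non-covered regulators.
- **Distinguishable activity profiles.** Profiles are phase-wise
  exponential relaxations toward random levels. Two constraints keep
  the planted system recoverable: levels span at least 0.5 (the
  perturbation is designed to excite every regulator; a near-constant
  profile is unrecoverable by construction and is the documented
  degenerate case), and each phase's response begins after a random
  delay (up to 45% of the phase length). With only three phases,
  zero-delay profiles would be near-linear combinations of one
  another; staggered response times are also what real regulator
  activities show. The first TF is a fast on-off-on profile that
  tracks the phases (exercising filter i), and one TF is listed as a
  two-component system (filter iii).
- **Exactly invertible metabolite coupling.** For each planted
  interaction the TF's activity profile is mapped affinely into
  [0.05, 0.95] (the Hill branches are asymptotic; hitting 0 or 1 needs
  infinite concentration) and pushed through the inverse Hill
  transform, so the forward fit recovers (mode, K_H, h) exactly in the
  noiseless limit. Decoy metabolites follow smooth random trajectories
  over 1–1000 µM.
- **Toy metabolic model consistent with the truth.** Each planted
  metabolite is a substrate of a reaction encoded by its TF's
  exclusive gene, in a subsystem of its own; decoy metabolites attach
  to transport reactions encoded only by the on-off-on TF's exclusive
  gene, which the screen excludes — so chance correlators among decoys
  cannot pass the criterion. Cofactors participate widely and two
  non-cytosolic species exercise the pruning step.

What the generator does **not** emulate: mechanistic metabolism (no
kinetics/FBA), regulatory feedback from metabolites to expression
beyond the planted Hill couplings, missing values, batch effects, or
the heavy-tailed error structure of real LC-MS and RNA-seq data.
Passing recovery tests therefore demonstrates the statistical
machinery is correct under the stated noise model, not that real-data
screens reach the same precision.

## Numerical choices and degenerate inputs

- Zero TPMs: floored at a configurable pseudocount (default 0.01 TPM)
  before log10; an additive policy is selectable.
- Constant series: mode selection flags them; the fit returns an
  `r_squared = −inf` sentinel instead of failing.
- Saturated Hill transforms (`u` constant over the data): the affine
  fit degenerates to the mean; the objective stays finite.
- Constant activity rows z-score to zero rather than dividing by zero.
- Zero-variance rows in clustering get a flat z-score of 0.
- Hierarchical clustering sorts rows by id before linkage so the
  partition is independent of input order.

## Problem sizes used in checks

The bundled correctness checks run at: 60 genes / 6 TFs (noiseless
factorization, activity recovery), 29-point Hill series (parameter
recovery; the noisy case reports the median over nine noise draws,
since single draws of 5% activity noise can move the K_H estimate by
up to ~20%), random bipartite graphs up to ~50 nodes (distance
oracle), and the default 150-gene scenario at noise 0.05 with 100 NCA
restarts (end-to-end planted recovery; the planted-recovery property
is stated for noise ≤ 0.05). These sizes were chosen so each check
isolates one stage with an exact or planted reference.

## Known limitations

- ALS local optima mean some restarts are wasted; the residual-based
  pruning factor (1.5×) is a heuristic and regulators with few targets
  or weak dynamics can still receive wide confidence bands — the TF
  filter then removes them, trading recall for precision exactly as
  the screen intends.
- Sign anchoring needs sign annotations in the network; with unsigned
  networks, activation/inhibition calls are only consistent within the
  ensemble, not anchored to biology.
- Nearest-neighbour grid pairing introduces resampling error when the
  two grids differ; planted-parameter recovery at the 1% level is only
  expected when the grids coincide.
- The screen is correlational: a passing candidate is a hypothesis for
  in vitro validation, not a demonstrated interaction.
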