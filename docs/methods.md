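# Methods

## Scope and model

`sortbind` implements the analysis layer of a Sort-Seq experiment on a
transcription-factor binding site embedded in a simple-repression promoter:
a library mutagenized from a wild-type (reference) operator drives a
fluorescent reporter; cells are sorted into expression bins by FACS; the
sorted libraries are sequenced; and a linear (additive, single-nucleotide)
energy model is inferred that maps operator sequence to repressor binding
energy. Energies are in kBT throughout (β ≡ 1); a helper reports kBT in
kcal/mol at a user temperature (≈ 0.62 kcal/mol at 37 °C).

The statistical-mechanical backbone is the occupancy model: expression ∝
p_bound, the probability that RNAP occupies the promoter against a repressor
and N_NS ≈ 4.6×10⁶ nonspecific genomic sites. In the weak-promoter regime
((P/N_NS)e^(−Δε_P) ≪ 1, which holds for P ≲ 1000 on a lacUV5-like promoter)
the fold-change reduces to 1/[1 + (2R/N_NS)e^(−Δε_R)]. The "2R" head count
is a parameter (`heads_per_repressor`, default 2 for tetrameric LacI) so
dimeric repressors reuse the model unchanged.

## Linear energy model and gauges

An `EnergyMatrix` is an L×4 table (columns fixed to A,C,G,T; positions
1-based on the printed strand; no reverse-complement handling — one strand
is scored). A linear model is defined only up to a per-position additive
constant and, when fitted against ranked data, an overall scale; matrices
therefore carry a gauge: `reference` (wild-type cells pinned to 0, entries
read as single-mutation effects) or `position_mean` (rows sum to 0, used for
cross-matrix comparison). Gauge fixing preserves all pairwise sequence score
differences; this is asserted to 1e-9 in the tests. Conversion to absolute
units is the affine map Δε_R = α·ε_mat + Δε_wt.

Lowercase input is canonicalized; ambiguity codes are rejected rather than
averaged (a linear matrix scores definite bases). Insertions and deletions
are out of scope: an additive per-position model has no representation for
them.

## Mutual information estimator

Matrix quality is scored by the mutual information I(ε; μ) between energy
predictions and expression bins, estimated from a joint histogram. The
prediction axis is discretized by *rank* into equal-count bins (default
resolution 1000, capped at N/50), making the estimate invariant under any
strictly monotone transform of the predictions — precisely the invariance
class (overall scale and sign, "diffeomorphic modes") that the data cannot
determine. Ties in rank binning are broken by a stable sort over a seeded
shuffle of record order, so results are deterministic but unbiased. Counts
weight the histogram (per-read weighting; a per-unique-sequence analysis can
pass counts of 1). The public estimator subtracts the Miller–Madow
finite-sample bias (K−1)(B−1)/(2N ln 2) and floors at zero, so
label-shuffled data scores ≈ 0 rather than the raw plug-in bias; the
uncorrected plug-in value is available via `bias_correction=False`.

This histogram estimator stands in for an error-model-averaged likelihood
used in the original experimental analyses; it preserves the monotone
invariance the method relies on and is directly testable against brute-force
enumeration on small tables.

## Matrix inference chain

`EnergyMatrixMCMC` is a Metropolis–Hastings sampler over the free
(non-reference) matrix cells with target density p(data|model) ∝ 2^(N·I).
One iteration proposes a Gaussian perturbation of one randomly chosen free
cell and accepts with probability min(1, 2^(N·ΔI)); predictions are updated
incrementally over the records carrying that base. Three numerical choices
matter:

- **Warm start.** The chain is initialized from a least-squares regression
  of the bin index on one-hot mutation indicators. Without it, individual
  positions lock early into conflicting sign orientations (the MI target is
  invariant under a global sign flip but strongly penalizes mixed ones), and
  single-cell moves cannot cross the barrier between orientations — the
  chain freezes far from the optimum.
- **Scale pinning.** The overall scale is MI-flat; every 50 iterations the
  matrix (and predictions) are renormalized to unit rms over free cells,
  which changes nothing the likelihood can see but keeps the chain compact.
- **Step adaptation.** The proposal sd targets a 20–40% acceptance rate
  during burn-in (×0.8 / ×1.25 per 200-iteration window, bounded) and is
  frozen afterwards.

The posterior mean over all post-burn-in chain states is reported, with
per-cell standard deviations. It is then oriented so the reference sequence
is near-optimal (mean single-mutant entry positive — the convention for a
functional site, where most mutations are deleterious) and unit-normalized
(mean free entry = 1 arbitrary unit). Positions where the library shows
fewer than two bases are flagged and their columns zeroed; bases never
observed at a position are likewise not sampled. Chains are bit-for-bit
reproducible given `random_state`.

Default chain length follows the 30000-iteration / 10000-burn-in protocol.
The packaged tests and acceptance runs use 8000+3000: at the default
simulation scale the posterior mean is unchanged beyond ~5000 iterations,
and recovery against ground truth reaches r ≈ 0.95 (Pearson, position-mean
gauge), with replicate-to-replicate correlations of 0.95–0.98 when the data
are split into three disjoint groups (`split_replicates`).

## Scaling-factor inference and its precision

`ScalingFactorMCMC` samples the single parameter α (in log space, reflective
bounds 10⁻³–10³) with the same 2^(N·ΔI) acceptance, where I is now
I(p_bound; μ): each record's ε_mat is mapped through Δε_R = α·ε_mat + Δε_wt
into the occupancy model with a fixed effective RNAP term. Here the
prediction axis is binned by *value* (equal-width bins over the observed
p_bound range), not by rank — rank binning is monotone-invariant and would
make α unidentifiable by construction; it is exactly the nonlinearity of the
ε → p_bound map that carries scale information. The histogram is averaged
over 8 shifted bin grids (the N·I exponent otherwise amplifies
discretization wiggles into spurious posterior peaks) and Miller–Madow
corrected (the occupied-bin count varies with α).

**Precision.** At the default study conditions (one repressor copy number,
10⁴ variants, multiplicative expression noise CV 0.3) this route has an
intrinsic precision of roughly ±25%. The limitation is structural, not a
tuning issue: with zero expression noise the sorted bins are an exactly
monotone function of p_bound, so α is *fundamentally* unidentifiable from
I(p_bound; μ); identifiability arises only from how noise interacts with
fixed-width binning, and the estimate inherits a resolution-dependent bias
(coarse bins high, near-rank-limit bins low). The histogram resolution is
kept at the package-wide default (N/50) rather than chosen to cancel the
bias. When anchor sequences with known energies exist,
`scale_by_least_squares` recovers α and Δε_wt exactly (to rounding) and
should be preferred; `scale_by_theoretical_penalty` sets α so the mean
single-mutant penalty matches a theoretical value, for architectures whose
thermodynamic parameters are unknown. An `identifiable_` flag reports when
the α posterior is prior-wide or the achieved MI never exceeds 5× the
estimator's noise floor (e.g., bins shuffled against sequence).

## Binding-energy measurement and induction phenotypes

`fit_eps_R` / `RepressorTitrationFit` estimate Δε_R by single-parameter
nonlinear least squares of the fold-change curve against (R, fold-change)
titration data. The 95% CI is the linearized asymptotic interval
(t-distribution on n−1 df); a single titration point is inverted
algebraically and reported with a degenerate CI. Fold-change from raw
fluorescence subtracts autofluorescence: (⟨I_R⟩−⟨I_auto⟩)/(⟨I_R0⟩−⟨I_auto⟩).

Induction follows the two-state MWC model with defaults K_A = 139 μM,
K_I = 0.53 μM, Δε_AI = 4.5 kBT, n = 2 (LacI/IPTG). Leakiness and saturation
are the analytic c→0 and c→∞ limits (MWC bracket → 1/(1+e^(−Δε_AI)) and
1/(1+e^(−Δε_AI)(K_A/K_I)^n)); the EC50 is found by bracketed root-finding on
the midpoint equation (verified to 1e-6 relative) rather than a closed form.
K_A = K_I is rejected (the response is flat and the EC50 undefined); R = 0
gives leakiness = saturation = 1 with EC50 reported as NaN. The design
module enumerates point mutants of the reference, predicts each Δε_R from a
kBT matrix, and ranks by root-mean-square distance to target phenotypes
(EC50 compared on a log scale).

## Base-preference statistics

Per replicate matrix, per position, base probabilities follow the Boltzmann
weights prob_N = e^(−ε_N)/Σ_M e^(−ε_M) (shift-invariant, hence
gauge-independent; also the letter weights in the information logo, with
Schneider information content 2 + Σ p log₂ p and no small-sample
correction). A one-way Welch ANOVA across the four bases (p < 0.01) gates a
Games–Howell post-hoc comparison, and a base is declared preferred only if
it is the most probable and beats every other base pairwise at p < 0.05
(statistics via pingouin; tests verify them against hand-coded formulas).
Replicates that are numerically identical have no estimable variance; the
degenerate case is decided on the means alone and reported with p of 0 or 1.

## Synthetic data generator

The generator defines the study conditions every recovery claim refers to:

- reference operator O1 (21 bp); per-base mutation rate 0.10, uniform over
  the three alternatives (mean ≈ 2.1 mutations per variant, matching the
  experimental library design);
- ground-truth matrices in reference gauge with gamma-distributed
  single-mutant penalties (shape 2) of mean 2 kBT and a ~10% beneficial
  fraction, emulating a strong operator where most available mutations
  weaken binding;
- expression = p_bound × log-normal noise. The noise CV defaults to 0.3 — a
  stand-in for unquantified cell-to-cell variability in the real assay, in
  the range typical of flow-cytometry reporter distributions — and is swept
  in tests;
- four sorting gates, each covering 15% of the pooled expression histogram,
  evenly spread over the 5th–95th percentiles with inter-gate cells
  discarded (as in FACS gating); one sorted cell per library variant, one
  read per sorted cell.

What the generator does *not* emulate: transformation/PCR bottlenecks,
regrowth between sorting and sequencing, sequencing errors and
quality-filter loss, copy-number variation of the reporter plasmid, and any
epistasis (the ground truth is exactly additive). Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to these real-data effects — in
particular, real libraries violate additivity for distant mutants, which is
why prediction error grows with mutation count in the packaged benchmark.

## Benchmark fixture

`load_lac_mutant_benchmark()` returns 26 lac operator mutants (9/9/8 with
1/2/3 substitutions relative to O1) with published predicted and measured
binding energies in kBT. The file is checksummed and each row's mutation
count is recomputed from its sequence and validated against its class.
Median absolute prediction errors are 0.41/0.79/1.35 kBT per class and
0.83 kBT overall — the quantitative sense in which additive matrices
"predict binding energies to about 1 kBT".

## Problem sizes and determinism

Default test and acceptance scales: 10⁴ library variants (≈6000 sorted
records), chains of 8000+3000 (matrix) and 2000+800 (scaling) iterations,
10⁵ variants for library statistics. All randomness flows through explicit
integer seeds (`numpy.random.default_rng`); simulation configs derive
per-stage sub-seeds from one master seed, and identical configs produce
byte-identical dataset files.
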