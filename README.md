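# sortbind

Sort-Seq energy-matrix inference and thermodynamic models of bacterial gene
regulation.

`sortbind` is for quantitative biologists and synthetic-biology engineers who
want to map a transcription-factor binding site's DNA sequence to its binding
energy in absolute units (kBT), and then use that map to predict and design
regulatory behavior. It covers the full workflow of a Sort-Seq massively
parallel reporter assay in silico: simulate (or load) a mutagenized operator
library sorted into fluorescence bins, infer an additive sequence→energy
matrix by mutual-information-maximizing MCMC, convert it to absolute energy
units, and feed the predicted energies into statistical-mechanical models of
simple repression and allosteric induction.

## The models

**Occupancy.** Expression is proportional to the probability that RNAP
occupies the promoter, competing with a repressor against N_NS nonspecific
genomic sites (β = 1/kBT ≡ 1 internally):

    p_bound = (P/N_NS) e^(−Δε_P) / [1 + (P/N_NS) e^(−Δε_P) + (2R/N_NS) e^(−Δε_R)]

**Simple repression.** In the weak-promoter regime the fold-change in
expression (repressed over unrepressed) reduces to

    fold-change = 1 / [1 + (2R/N_NS) e^(−Δε_R)]

with R the repressor copy number ("2R" counts the two heads of a LacI
tetramer; the factor is a parameter for dimeric repressors).

**Energy matrices.** The repressor binding energy of an operator variant σ is
additive over positions: Δε_R(σ) = α·ε_mat(σ) + Δε_wt, where ε_mat sums one
L×4 matrix cell per position, Δε_wt is the wild-type (reference) binding
energy, and α converts arbitrary matrix units to kBT. The matrix is inferred
by a Metropolis–Hastings chain targeting p(data|model) ∝ 2^(N·I), with
I(ε; μ) the mutual information between the matrix's energy predictions and
the expression bins μ of N sorted cells; α is inferred by a second,
single-parameter chain maximizing I(p_bound; μ).

**Induction.** An allosteric (MWC, active/inactive) repressor with inducer
dissociation constants K_A, K_I, n binding sites and state energy gap Δε_AI
gives the induction curve fold-change(c), from which the package computes the
design phenotypes leakiness, saturation, dynamic range, and EC50.

## Worked example

```python
import numpy as np
import sortbind as sb

# simulate a Sort-Seq experiment at the default study conditions:
# 21-bp O1 operator, 10% per-base mutagenesis, 10^4 variants, four 15% gates
cfg = sb.SimulationConfig(n_variants=10_000, seed=0)
ds, truth = sb.simulate_experiment(cfg)
print(f"sorted records: {len(ds)}")

# infer the energy matrix from the sorted library
est = sb.EnergyMatrixMCMC(reference_seq=ds.reference_seq,
                          n_iterations=8000, n_burnin=3000,
                          proposal_sd=0.2, random_state=0)
est.fit(ds.codes, ds.bins, sample_weight=ds.counts)
print(f"MI = {est.mutual_information_:.2f} bits, "
      f"r(truth) = {sb.compare_matrices(est.matrix_, truth):.3f}")

# measure a binding energy from a repressor titration
pts = [(R, sb.fold_change_simple(R, -13.9)) for R in (11, 30, 62, 130, 610, 870)]
print(f"eps_R = {sb.fit_eps_R(pts).estimate:.2f} kBT")

# induction phenotypes of an operator with Δε_R = −13.9 kBT at R = 130
ph = sb.phenotypes(sb.AllosteryParams(), R=130, eps_R=-13.9)
print(f"leakiness = {ph.leakiness:.4f}, saturation = {ph.saturation:.3f}, "
      f"EC50 = {ph.ec50:.1f} uM")
```

prints

```
sorted records: 6000
MI = 1.50 bits, r(truth) = 0.949
eps_R = -13.90 kBT
leakiness = 0.0162, saturation = 0.926, EC50 = 49.4 uM
```

The inferred matrix correlates with the generating ground truth at r = 0.949
(Pearson, position-mean gauge over all 84 cells); the titration fit recovers
the binding energy of a noiseless fold-change curve exactly; and the
induction phenotypes say this operator/copy-number pair gives a nearly silent
uninduced state (leakiness 0.016) that can be driven to 93% of full
expression, with half the response reached at ~49 μM inducer.

The package also ships a 26-mutant lac operator benchmark
(`sb.load_lac_mutant_benchmark()`): predicted vs measured binding energies
for 1/2/3-bp mutants of O1, whose median absolute prediction errors are
0.41 / 0.79 / 1.35 kBT per class and 0.83 kBT overall.

## Command line

Each stage is a `sortbind` subcommand operating on TSV files, composing in
pipelines: `simulate`, `infer`, `scale`, `predict`, `fit-energy`,
`design-induction`, `compare-matrices`, `logo`. Logs (version, seed,
effective config, input checksums) go to stderr; results only to named
output files.

```sh
sortbind simulate --n-variants 10000 --seed 0 --out run
sortbind infer run.dataset.tsv --replicates 3 --out fit
sortbind logo fit.mean.tsv --out fit_logo
```

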