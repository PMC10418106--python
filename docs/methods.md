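# Methods

This note documents the models, algorithms and numerical choices behind
`dispersalnet`: what is simulated, what the network computes, how the
baseline works, and what the desk-scale benchmark does and does not show.

## The estimation target

The quantity estimated throughout is σ, the effective per-generation
dispersal distance: the root-mean-square displacement along one axis between
a child and one of its parents chosen at random.  σ absorbs two biological
movements — the mother-offspring displacement (e.g. seed dispersal) and the
father's contribution, which adds the mating distance (e.g. pollination) on
top of dispersal.  When both kernels are Gaussian with a common scale σf,

    Var(child − random parent) = ½·σf² + ½·(σf² + σf²) = 1.5·σf²,

so σ = σf·√(3/2).  The conversion factor is configurable
(`SimParams.sigma_factor`, default √1.5) because it depends on the kernel
equality assumption; no benchmark quantity in this package depends on its
particular value, since the same factor is applied to training targets and
truths.

## The spatial simulator (`dispersalnet.simulate`)

Training data come from a continuous-space, individual-based,
non-overlapping-generations forward simulation of diploid hermaphrodites on
a square habitat of width W:

- **Initialization.** ⌈K·W²⌉ individuals are placed uniformly at random
  (K = carrying capacity, individuals per square map unit).  Standing
  genetic variation is seeded from a neutral coalescent sample (msprime)
  with population size equal to the census, binary mutation model, and a
  reduced founder recombination map (default 0.2 Morgan); the deep
  panmictic genealogy carries no spatial signal, so the founder map length
  is purely a speed choice.  Forward generations use the full map.
- **One generation.** Every individual acts as a mother.  She chooses a
  mate among neighbours within 3σf with probability ∝ exp(−d²/2σf²)
  (self excluded; no candidate in range → no offspring that generation).
  Her expected offspring number is regulated by local density,
  λ = λmax / (1 + (λmax−1)·ρ/K) with λmax = 2, which equals 1 exactly at
  ρ = K (Beverton–Holt-style logistic regulation); realized counts are
  Poisson.  Local density ρ is the truncated-Gaussian kernel sum over
  neighbours, normalized by 2πσf²·(1−e^{−4.5}) and corrected for kernel
  mass lost outside the habitat edge (product of 1-D Gaussian interval
  masses), so that density is not underestimated near borders.
- **Offspring.** Each offspring lands at the mother's position plus an
  isotropic Gaussian displacement of scale σf, reflected at habitat edges;
  displacements are recorded *before* reflection, which is what the kernel
  calibration check measures.  Gametes recombine with
  Poisson(recomb_rate·L) crossovers uniform on the base-pair map and
  mutate at rate mut_rate per bp.  Sites fixed or lost are pruned each
  generation.
- **Sampling.** After `n_generations` forward generations, `draws`
  independent samples of n individuals are taken uniformly at random
  without replacement; each yields one dataset sharing the simulation's
  true σ.  Genotypes are emitted as minor-allele counts for m SNPs
  segregating in the sample, ordered by genomic position, with an evenly
  spaced (by rank) subset when more sites are available.

Neighbour search uses a uniform cell grid (cell width ≥ 3σf) with pair
weights computed once per generation and cached in compressed sparse rows —
this keeps the cost near-linear when 3σf is small and an honest O(N²) sweep
when the truncation circle covers the habitat.  All randomness flows from a
single seed through numpy `SeedSequence` spawning; a fixed seed reproduces
every dataset bit-exactly.

### Scaled-down benchmark conditions

The reference model this simulator emulates runs on a 50×50 habitat with a
10⁸ bp genome (recombination 10⁻⁸/bp; one crossover per meiosis) and
~12,500 individuals, which is far outside a single-CPU budget.  The
desk-scale conditions used by the tests and the acceptance script are:

| parameter | desk value | rationale |
|---|---|---|
| habitat width | 15 (10 for calibration checks) | ~1,125 individuals at K=5 |
| carrying capacity K | 5 / map unit² | as in the reference model |
| σf prior | U(0.2, 3) | as in the reference model |
| genome | 10⁶ bp, recomb 10⁻⁶/bp | preserves total map length (1 Morgan), not per-bp rate |
| mutation rate | 2.5×10⁻⁸/bp | yields ≈400 sample-segregating SNPs at n=10, twice the m=200 needed |
| forward generations | 100 | enough for local isolation-by-distance structure to equilibrate at the sampling scale |
| training set | 300 simulations × 10 draws, n=10, m=200 | desk-scale counterpart of 1,000 × 50 at n=100, m=5,000 |

Preserving map length rather than per-bp recombination matters: a 10⁶ bp
genome at 10⁻⁸/bp would be a single linkage block, leaving only a handful of
effectively independent genealogies and far less information about σ.

### What the simulator does not model

No demographic perturbations, heterogeneous habitat, selection, sex
structure, overlapping generations, or age structure.  Mate search
truncation at 3σf and edge reflection are concrete stand-ins for choices the
reference model leaves unstated.  Passing benchmarks here therefore show
that the estimator recovers σ *under the model that generated the data* —
the best-case framing — not that it is robust to misspecification in real
data.

## The pairwise network (`dispersalnet.network`)

Inputs per dataset: a genotype matrix (m SNPs × n individuals, minor-allele
counts 0/1/2 unphased, or 0/1 per haplotype phased) and a location table.
For each of the C(n,2) pairs, in lexicographic order:

1. the pair's genotype rows are stacked (2 rows unphased, 4 phased;
   individual i above j);
2. repeated blocks of [convolution (kernel spanning 2 SNPs, stride 1, no
   padding) → ReLU → average pooling (window 10, non-overlapping, remainder
   dropped)] run along the SNP axis;
3. the flattened output is concatenated with the pair's distance feature:
   the Euclidean distance divided by `distance_scale` (the width of the
   training point cloud), passed through a natural log by default (floored
   at 10⁻³ of the scale).  Under two-dimensional isolation by distance,
   differentiation is linear in ln d — the same transform the Rousset
   regression uses — so the log feature hands the dense layer the
   theoretically relevant axis instead of asking it to approximate a
   logarithm; `distance_transform="linear"` restores the raw scaled
   distance;
4. a fully connected ReLU layer of `pair_dense_units` gives the pair's
   feature vector.  Weights are shared across all pairs, so the extractor's
   parameter count is independent of n.

The head concatenates all pairs' features and applies a single linear unit
to produce the normalized prediction; targets are z-scores of log σ over
the training split, and predictions are back-transformed.  Training uses
mean squared error, the Adam optimizer, and learning rate 10⁻⁴ by default.

All layers, the backward pass, and Adam are implemented directly in numpy
(float64), which keeps gradient flow fully inspectable and lets the test
suite validate every parameter's gradient against central finite
differences.

### Gradient gating (k_extract)

With large n the number of pairs grows quadratically.  Rather than dropping
pairs, optimization can *gate* them: each batch, a fresh uniform random
subset of `k_extract` pairs carries gradients into the shared extractor
weights, while the forward pass — and the head's gradients — always use
every pair.  Gating therefore never changes the loss value at a given
parameter state, only the gradient flow; at k_extract = C(n,2) it is
exactly ungated backpropagation.  Both identities are asserted numerically
in the tests.

### Desk-scale training configuration

The architecture defaults (two blocks of 32/64 filters, 128 dense units)
are sized for m ≈ 5,000 inputs.  For the m=200, n=10 benchmark the package
uses a deliberately small extractor — one block of 4 filters, 16 dense
units, learning rate 2×10⁻³, batches of 8 datasets, ≤50 epochs, an ensemble
of three seeds — because with 3,000 training datasets a larger model
memorizes dataset-specific noise long before it learns transferable
structure; configuration among the small variants was selected by grouped
validation loss.  A member whose validation loss never improves on the
trivial constant predictor (a rare optimization failure at this scale) is
rejected and retrained from a fresh initialization, keeping the best of a
bounded number of attempts.  Two further choices control the memorization
failure mode:

- **Permutation augmentation** (`augment_permute`): each batch, every
  dataset's individuals are randomly relabelled.  σ is invariant to sample
  order but the stacked pair features are not; training over orderings
  teaches the head that pair slots are exchangeable.  At prediction time
  the estimate is averaged over `predict_permutations` (default 8) random
  orderings, removing the arbitrary-labelling component of variance (the
  average is taken on the normalized log scale).
- **Grouped validation**: datasets drawn from one simulation share a true
  σ, so the early-stopping split is made at simulation level when group
  labels are provided; otherwise a validation set that shares simulations
  with training flatters the loss and stops at the wrong point.

## The Rousset baseline (`dispersalnet.rousset`)

Under two-dimensional isolation by distance the regression of an
individual-pair genetic differentiation statistic â on ln(geographic
distance) has slope 1/Nb where Nb = 4πDσ² is Wright's neighborhood size.
Given the density D, σ̂ = √(1/(4πD·b)).  The statistic used is the
individual-level analogue of F_ST/(1−F_ST):

    â(i,j) = Σ_l (Q̂w_l − Q̂b_l(i,j)) / Σ_l (1 − Q̂w_l),

with Q̂b the probability of allele identity between one gene from i and one
from j, and Q̂w the within-individual identity averaged over the sample
(ratio-of-sums over loci).  Pairs at identical locations are excluded from
the regression (ln 0) and counted.  A non-positive slope leaves σ̂
undefined — returned as NaN, never an exception — and such datasets are
excluded from the baseline's error metrics with their count reported.  The
benchmark supplies the baseline its true density K, the best-case framing.

## Metrics (`dispersalnet.metrics`)

MRAE (mean of |σ̂−σ|/σ), RMSE on the natural σ scale, and r² (squared
Pearson correlation of true and predicted — not the regression coefficient
of determination).  The no-information reference is the constant prior-mean
predictor, whose MRAE under σ ~ U(a,b) is computed by numerical
integration.  Method comparisons are summarized as relative MRAE
reductions, (MRAE_ref − MRAE_new)/MRAE_ref.

## Numerical and edge-case conventions

- Minor-allele ties (frequency exactly 0.5): the currently counted allele
  is kept — the only deterministic rule under which re-coding a coded
  matrix is a no-op.
- Convolution valid-padded, stride 1; pooling windows non-overlapping with
  the remainder dropped: with m=5,000, the first block maps 5,000 → 4,999 →
  499.
- Geographic projection: equirectangular about the sample centroid on a
  spherical Earth (R = 6,371 km); adequate below regional scale (distance
  ratios preserved to <1% inside a 2° cluster).
- Sampling-scheme matching: empirical localities are mapped onto the
  simulated habitat by centroid + bounding-box-width alignment, then each
  locality greedily takes its nearest unchosen simulated individual
  (Euclidean, input order, without replacement).
- Missing genotypes are rejected, never imputed; multiallelic and
  monomorphic sites are excluded.
- Divergent training (non-finite loss) aborts with a diagnostic rather
  than returning weights.

## Known limitations

- The desk-scale benchmark shows parameter recovery under matched
  training/test conditions with a single unknown (σ); accuracy on real
  data additionally depends on how well the simulation matches the study
  system (density, habitat shape, demography).
- Desk-scale comparisons against the Rousset baseline are noisier than the
  headline full-scale picture suggests: the baseline's error is computed
  only over the test sets where its fitted slope is positive (its strongest
  cases, typically low σ), while the network answers every test set
  including the weakly identified high-σ cases where σ approaches the
  habitat scale.  With 50 held-out simulations the method ordering can
  depend on the seed; the network's advantage grows with the amount of
  training data and with m and n, which is where the full-scale protocol
  operates.
- The network's published depth/filter counts are not public; the defaults
  here are declared stand-ins sized by input length, and everything is
  configurable through `ModelSpec`.
- Predictions are in the map units of the training simulations; users must
  keep the empirical projection and the simulated habitat on a consistent
  scale (the `match_sampling` width alignment handles the benchmark case).
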