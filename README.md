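# dispersalnet

Estimate the mean per-generation dispersal distance **σ** of a population
from georeferenced SNP data.

σ — the root-mean-square displacement along one axis between a child and a
randomly chosen parent — controls how fast genes move across a landscape.
It matters for managing endangered and invasive species, predicting range
shifts, and modelling disease vectors, yet it is hard to measure directly.
Under restricted dispersal, nearby individuals end up genetically more
similar than distant ones (isolation by distance), so σ leaves a footprint
in ordinary polymorphism data.  `dispersalnet` recovers it with a neural
network that looks at *pairs* of individuals — each pair's genotypes
together with the geographic distance separating them — trained on
continuous-space individual-based simulations.  Because the input is
unphased SNPs plus sampling coordinates, the approach works for non-model
organisms without identity-by-descent tracts or inferred genealogies.

The package contains, as testable components:

- a **spatial forward simulator** (`dispersalnet.simulate`): diploids on a
  square habitat; Gaussian dispersal, mating and competition kernels
  sharing one scale σf drawn from U(0.2, 3); logistic local-density
  regulation around carrying capacity K; recombining genomes seeded from a
  neutral coalescent (msprime).  Effective σ = σf·√(3/2);
- a **pairwise convolutional network** (`dispersalnet.network` /
  `PairwiseDispersalRegressor`): per-pair feature extraction with shared
  weights (conv kernel spanning 2 SNPs, average pooling over 10), the
  pair's Euclidean distance concatenated before a dense layer, all pairs'
  features stacked into a single linear output unit — implemented in plain
  numpy with hand-written backpropagation, including the `k_extract`
  gradient-gating strategy that lets only a random subset of pairs optimize
  the shared extractor while every pair feeds the forward pass;
- **Rousset's regression baseline** (`dispersalnet.rousset`): the
  individual-pair statistic â regressed on ln(distance); slope b converts
  to σ̂ = √(1/(4πD·b)) given density D, undefined when b ≤ 0;
- an **evaluation harness** (`dispersalnet.metrics`): MRAE, RMSE and r²
  over held-out simulations, with undefined baseline fits excluded and
  counted;
- a **CLI** wiring the workflow:
  `dispersalnet simulate | preprocess | train | predict | baseline | validate`.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

Simulate a small training set, train, and validate — all from Python:

```python
import numpy as np
from dispersalnet import PairwiseDispersalRegressor, RoussetDispersal
from dispersalnet.simulate import simulate_training_data
from dispersalnet.metrics import run_benchmark

train = simulate_training_data(n_sims=100, draws_per_sim=10, sample_n=10,
                               m_snps=200, seed=100)      # ~3 min
test = simulate_training_data(30, 1, 10, 200, seed=900)

net = PairwiseDispersalRegressor(filters_per_block=(4,), pair_dense_units=16,
                                 learning_rate=2e-3, epochs=50, batch_size=8,
                                 random_state=0)
net.fit(train, groups=np.repeat(np.arange(100), 10))

report = run_benchmark(
    {"pairwise_network": net, "rousset": RoussetDispersal(density=5.0).fit()},
    test,
)
print(report[["mrae", "r2", "n_undefined_excluded"]])
```

Output from this exact run:

```
                      mrae        r2  n_undefined_excluded
method
pairwise_network  0.556854  0.481185                     0
rousset           0.310201  0.256637                     7
```

With only 100 training simulations the network already tracks σ
(r² ≈ 0.48 across a 15-fold range) and always returns an answer.  The
Rousset row is computed only over the 23 of 30 test sets where its fitted
slope was positive — the 7 undefined fits, a failure mode that grows with
σ, are excluded from its error.  At the full benchmark scale (300 training
simulations, a 3-seed ensemble; `scripts/acceptance.py` below) the network
reaches MRAE ≈ 0.37 with r² ≈ 0.53 on all 50 held-out simulations, against
MRAE ≈ 0.45 for the baseline on the 70% of test sets it can answer at all.

The same workflow from the shell:

```bash
dispersalnet simulate --out cache/ --n-sims 100 --draws 10 --seed 100
dispersalnet train --cache cache/ --filters 4 --pair-dense 8 \
    --learning-rate 1e-3 --epochs 50 --seed 0 --out model/
dispersalnet predict --weights model/weights.npz \
    --vcf mydata.vcf --coords mycoords.csv --out sigma.tsv
dispersalnet baseline --vcf mydata.vcf --coords mycoords.csv \
    --density 5 --out rousset.tsv
```

`predict` reports σ̂ in the map units of the training simulations; empirical
latitude/longitude are projected to km about the sample centroid, and
`match_sampling` aligns simulated sampling with empirical localities.

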