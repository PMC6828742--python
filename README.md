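# netbite

Network-biased tree ensembles for drug-sensitivity regression and
biomarker screening.

## The problem

Predicting a drug's half-maximal inhibitory concentration (IC50) across
cancer cell lines from basal gene-expression profiles is a
small-n / large-m regression problem: hundreds of cell lines, tens of
thousands of genes. Random forests handle the dimensionality but treat
every gene as equally likely to matter. Yet for most compounds we *know*
something a priori — the reported target genes — and we know how those
targets sit inside the protein–protein interaction (PPI) network.

`netbite` implements **biased tree ensembles (BiTE)**: CART regression
trees in which the candidate-feature subset drawn at every split node is
sampled *without replacement with probabilities proportional to a
per-gene bias weight* instead of uniformly. Uniform weights recover the
random-forest sampling scheme exactly, so RF is the special case
`bias_weights=None` of the same estimator.

**NetBiTE** adds a second layer of prior knowledge: the initial weight
vector `W0` (high weight `W` on the drug targets, a small floor
`ε = 1e-5` everywhere else) is smoothed over a weighted PPI network
(e.g. STRING) by random walk with restart,

```
W_{t+1} = α · A′ W_t + (1 − α) · W0,      A′ = D^{−1/2} A D^{−1/2},
```

iterated to its fixed point `(1 − α)(I − α A′)^{−1} W0` under an ∞-norm
convergence rule of 1e-6. The diffusion depth `α ∈ (0, 1)` (default
0.7, the value reported as optimal for STRING) controls how far target
weight spreads into the targets' "neighborhood of influence". Accuracy
is the cross-validated `ρ = √R²` between predicted and observed
min-max-scaled IC50, averaged over 10 repeats.

Because biasing toward a gene set either helps or hurts accuracy, the
method doubles as a transparent test of whether that gene set is an
informative biomarker of sensitivity to a given drug.

## Worked example

No downloads needed: the package generates its own benchmark — a
200 × 200 standardized expression matrix with two planted target genes
and an exact fifth-degree response
`IC50 = aXi⁵ + bXj⁵ + cXi³Xj² + dXi²Xj³`.

```python
import netbite as nb

bench = nb.make_benchmark(n_samples=200, n_genes=200, seed=1)
y = nb.scale_ic50(bench.response).values          # min-max to [0, 1]

bias = nb.build_initial_weights(
    set(bench.targets), list(bench.expression.columns),
    high_weight=0.6, epsilon=1e-5,
)
bite = nb.BiasedTreeEnsembleRegressor(n_tree=10, mtry=2, bias_weights=bias)
rf = nb.BiasedTreeEnsembleRegressor(n_tree=10, mtry=2, bias_weights=None)

rep_bite = nb.crossval_rho(bench.expression, y, bite, repeats=10, seed=0)
rep_rf = nb.crossval_rho(bench.expression, y, rf, repeats=10, seed=0)
print(f"BiTE  mean rho = {rep_bite.mean_rho:.3f}")
print(f"RF    mean rho = {rep_rf.mean_rho:.3f}")
```

prints

```
BiTE  mean rho = 0.843
RF    mean rho = 0.000
```

With only 10 trees and 2 candidate features per split, the biased
ensemble almost always draws the two informative genes and recovers the
planted signal (ρ ≈ 0.84–0.86 depending on the fold shuffles, near the
ρ ≈ 0.9 ceiling of this data); an RF restricted to the same tiny
`mtry` picks informative splits so rarely that its pooled out-of-fold
R² is negative, which clamps to ρ = 0. The network layer:

```python
fix = nb.make_ppi_fixture(list(bench.expression.columns),
                          list(bench.targets),
                          effectors_per_target=2, seed=7)
w0 = nb.build_initial_weights(set(bench.targets),
                              list(bench.expression.columns))
ws = nb.propagate_weights(w0, fix.graph)           # alpha = 0.7
print(nb.neighborhood_of_influence(ws, 5))
```

prints `['G0022', 'G0068', 'G0125', 'G0137', 'G0180']` — the two
targets followed by their wired interaction partners, i.e. the planted
neighborhood of influence.

The same pipeline runs from the shell:

```bash
netbite make-fixtures --out-dir fx --seed 3
netbite propagate --ppi fx/ppi.tsv --targets fx/targets.txt \
    --expression fx/expression.tsv --out weights.tsv
netbite fit-predict --expression fx/expression.tsv \
    --response fx/response.tsv --weights weights.tsv \
    --n-tree 100 --mtry 2 --out-dir run/
netbite benchmark --n-tree-grid 10,100 --mtry-grid 2,200 --out sweep.tsv
```

For real data, point `--expression`/`--response` at GDSC-style TSV
exports, `--ppi` at a STRING detail-format edge list
(`protein1 protein2 combined_score`; scores on the [0, 1000] scale are
auto-detected and divided by 1000) and `--targets` at the drug's
reported target genes.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline benchmark figure from scratch: it generates the
pinned 200 × 200 benchmark, fits the biased ensemble (weight 0.6 on the
two planted targets, ε elsewhere, `mtry=2`, `n_tree=10`, `TPS=1`),
cross-validates it with the 30–40-fold protocol and writes the
mean-of-10-repeats ρ as JSON. `--seed` drives all evaluation-time
randomness.

See `docs/methods.md` for the model, its assumptions, parameter
semantics and the limits of the synthetic benchmark.
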