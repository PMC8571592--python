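# arbormap

Inference of substrate-preference evolution (arboreal / semi-arboreal /
nonarboreal) on time-calibrated phylogenies, built around the question of
how the Cretaceous–Paleogene (K–Pg) mass extinction, ca. 66.02 Ma, reshaped
mammalian ecology. The package is aimed at phylogenetic comparative
biologists who want a scriptable, fully reproducible version of this
workflow: discrete-trait model selection, ancestral state reconstruction,
Bayesian stochastic character mapping over posterior tree samples, and a
transition-rate-through-time statistic.

## The models

A three-state character evolves along a rooted chronogram (branch lengths
in Myr) as a continuous-time Markov chain with generator Q (rates in
1/Myr). With states ordered (A, S, N) = (arboreal, semi-arboreal,
nonarboreal), the package implements six nested parameterizations:

| model | k | structure |
|---|---|---|
| `two_rate` | 2 | transitions touching S share q₁; direct A↔N share q₂ |
| `four_rate` | 4 | ordered A↔S↔N with separate forward/reverse rates; direct A↔N forbidden (structural zeros) |
| `ard` | 6 | all rates different |
| `hmm_ard_plus_four_rate_2class` | 11 | two hidden rate classes (ARD + four-rate templates) |
| `hmm_ard_2class` | 13 | two ARD classes |
| `hmm_ard_3class` | 19 | three ARD classes |

Hidden-rate-class (HMM) variants expand the state space to (observed state,
class) pairs; a single symmetric switch rate connects the same observed
state across classes, and tips are ambiguous over classes. Likelihoods are
computed by Felsenstein pruning, maximized over log-rates with restarts,
and compared by AIC = 2k − 2 log L. Ancestral states come from marginal
(inside–outside) probabilities and Sankoff parsimony; full character
histories are drawn by stochastic mapping (backward node-state sampling
plus endpoint-conditioned path sampling by uniformization) and summarized
across maps — and across phylogenetically equivalent nodes of a posterior
tree sample — as per-node state frequencies. The rate-through-time
statistic splits the tree into B equal time bins (default 50) and reports,
per ordered transition type, mean mapped events per Myr of lineage in each
bin.

## Worked example

```python
import arbormap as am
from arbormap import mk

fix = am.make_study_fixture(seed=0, n_posterior=0)   # 164 tips, root 90 Ma
df = am.model_selection_table(
    fix.tree, fix.table, ["two_rate", "four_rate", "ard"],
    config=mk.OptimizerConfig(n_restarts=3, seed=1),
)
print(df[["model", "k", "logL", "AIC", "dAIC"]].to_string(index=False))

fit = df.attrs["fits"]["four_rate"]
maps = am.generate_maps(fix.tree, fix.table, fit.spec, fit.params,
                        1000, seed=1)
summary = am.summarize_maps(maps, fix.tree)
n, edges = am.count_post_boundary_arboreal_origins(
    fix.tree, summary.modal_states(0.5), 66.02)
print("post-K-Pg origins of arboreality:", n)
```

Output:

```
    model  k       logL        AIC      dAIC
four_rate  4 -86.969814 181.939629  0.000000
      ard  6 -85.473028 182.946056  1.006427
 two_rate  2 -95.347502 194.695004 12.755375
post-K-Pg origins of arboreality: 1
```

The table says the ordered four-rate model (the generating model of the
fixture) beats the two-rate and all-rates-different alternatives on
penalized fit. The origin count applies the audit rule — edges whose child
is modally arboreal, whose parent is not, and whose child node is younger
than 66.02 Ma, with nested re-origins inside an already-counted arboreal
clade excluded — to the stochastic-mapping summary. For this seed most
arboreal tips descend from deep arboreal ancestry, leaving one
post-boundary re-origin; the list of subtending edges comes back alongside
the count for inspection, and other seeds (and the real mammal data) give
larger counts.

A command-line interface wraps the same stages for file-based runs:
`arbormap fit|asr|simmap|rtt|simulate|report --config run.cfg`, with a flat
`key = value` config naming the tree, character table, optional posterior
sample, and run sizes.

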