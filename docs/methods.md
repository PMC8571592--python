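# Methods

## Model family

The character is a three-state continuous-time Markov chain on a rooted
tree with branch lengths in Myr. States are ordered (arboreal,
semi-arboreal, nonarboreal) = (A, S, N) everywhere; generators Q have
nonnegative off-diagonal rates in 1/Myr and rows summing to zero.

The two-rate model groups the six transitions into "via semi-arboreality"
(q₁) and "direct A↔N" (q₂). The four-rate model is the ordered chain
A↔S↔N with separate forward and reverse rates and exact structural zeros
for direct A↔N moves, encoding the idea that a lineage cannot move between
obligate arboreality and nonarboreality without passing through the
facultative intermediate. The ARD model frees all six rates.

The hidden-rate-class variants expand the state space to (observed state,
class) with index `class * 3 + observed`. Within-class blocks repeat a
named template (ARD and/or four-rate); between classes only the same
observed state is connected, through **one shared symmetric switch rate**.
That is the smallest parameterization consistent with symmetric switching,
giving k = 11, 13 and 19 for the three variants. Other conventions (one
switch rate per class pair, or per state) are plausible; because k enters
AIC as a constant, any comparison against software using a different
convention must align k first. The parameter count is exposed on every
`ModelSpec` and printed in all outputs.

Tips under hidden-class models are ambiguous over classes: a tip observed
in state X has conditional likelihood 1 for (X, j) for every class j.

## Likelihood and fitting

Felsenstein pruning with per-node rescaling (log-scalers accumulated, so
trees of hundreds of tips with small rates do not underflow). Per-edge
transition matrices are produced in one batch from an eigendecomposition
of Q, with a `scipy.linalg.expm` fallback whenever the eigenvector
condition number exceeds 1e8; the batch path and `expm` agree to 1e-9 in
tests. Entries are clipped to [0, 1] and rows renormalized to remove
O(machine-eps) eigendecomposition noise.

Root collapsing supports three priors: `equal` (uniform over the expanded
state space — under hidden classes this is uniform over (state, class)
pairs), `fitzjohn` (weights proportional to the root conditionals), and a
fixed vector. Model selection defaults to the equal prior; both code paths
are exercised by the oracle tests.

Optimization is L-BFGS-B on log-rates, bounds [1e-8, 100] per Myr, ftol
1e-8, one deterministic start at 0.05/Myr plus log-uniform random restarts
(default 10 total; heavy simulation tests use 2–3, which in practice agree
with the deterministic start to <0.01 log-units). The convergence flag
requires a second restart to agree with the best within 0.01 log-units.
AIC = 2k − 2logL; AICc is available behind a flag but never the default.

## Ancestral states and mapping

Marginal node probabilities come from the inside–outside computation
(equivalent to re-rooting at every node); hidden classes are summed into
observed states, with expanded marginals retained for hidden-class models.
Parsimony uses the two-pass Sankoff algorithm; ties are kept as state
sets. Unordered (all changes cost 1) costs are the default, with the
ordered A–S–N matrix (direct A↔N costs 2) available to mirror the
four-rate likelihood structure.

Stochastic maps are drawn in two steps. Node states: the root from
prior-weighted conditionals, then each child from its conditional given
the sampled parent (backward sampling). Edge paths: endpoint-conditioned
CTMC bridges by uniformization — the candidate-jump count N is drawn from
its exact conditional distribution (Poisson mixed with powers of
R = I + Q/Ω at the dominating rate Ω = max exit rate), intermediate states
by the forward–backward rule over R powers, jump times as sorted uniforms,
virtual jumps thinned. R powers and per-edge P(t) are cached per Q. The
Poisson tail is truncated at mean + 12 sd + 30 candidates, far beyond any
representable mass. Correctness is checked distributionally against an
independent oracle: a generator augmented with a jump-counting register,
exponentiated once (chi-square on 20,000 draws).

Zero-length edges make endpoint conditioning degenerate and are rejected
by the mapping stage; collapse them upstream. Under hidden-class models a
segment boundary that changes class but not observed state is a "class
switch": excluded from all 3×3 observed counts and from all six
rate-through-time series, tallied separately.

Summaries follow the describe.simmap convention. Across a posterior tree
sample, each reference internal node is matched to the node with the
identical descendant leaf set in each posterior tree; state frequencies
average over (map, matched node) pairs **restricted to trees containing
the clade**, and the clade frequency is always reported alongside so a
consumer can renormalize or filter differently. Mean Q across trees is the
element-wise arithmetic mean of per-tree MLEs (geometric mean behind a
flag).

## Rate through time

The tree is cut into B equal-width bins spanning [root age, 0]; B defaults
to 50. Bins are half-open [older, younger) and an event exactly on an
interior edge belongs to the older bin (the convention is arbitrary; it is
fixed and documented rather than configurable). Events are timestamped at
segment boundaries using node ages. The per-type series is (mean event
count over maps per bin) / (branch length in the bin); bins containing no
lineage are undefined (NaN), never zero. The conservation identity
Σ_b value_b × length_b = mean per-map count per type holds to 1e-9 and is
asserted in tests. Cross-tree aggregation re-expresses each per-tree
series on a common absolute-age axis spanning the oldest root (piecewise-
constant evaluation at common bin midpoints, NaN above a tree's own root);
per-tree curves are retained, with a pointwise median available.

The oldest bins contain very little lineage length, so normalized values
there are high-variance; with a single map one early event can dominate
the whole series. Statements about peak location should therefore be made
from many maps (or many simulated histories), as the acceptance checks do.

## Synthetic data

The generator emulates the shape of the real study: an ultrametric
birth–death tree of 164 tips (pure-birth by default) rescaled to root age
90 Ma, so the root comfortably predates the 66.02 Ma boundary; three-state
characters simulated exactly (Gillespie) down the tree; and a
pseudo-posterior of trees derived by log-normal jitter of internal node
ages (root age and ultrametricity preserved) plus random rooted NNIs.
Tip-count conditioning and the birth–death process itself are delegated to
dendropy; because growth stops exactly at the n-th birth, the tree is
extended by the waiting time to the next event before rescaling so no
terminal edge has zero length.

Default study conditions, frozen after a single calibration pass of the
generator: arboreal root state; four-rate generator with pre-boundary
rates (A→S, S→A, S→N, N→S) = (0.015, 0.015, 0.005, 0.012)/Myr; after
66.02 Ma the S→N rate rises to 0.06 with mild rises in S→A (0.018) and
N→S (0.02). These values give a default-seed tip mix of roughly 54% A /
15% S / 31% N — all three states well represented, as in the real
family-level sample — and a true S→N signature that peaks after the
boundary in every calibration replicate. Epoch schedules exist **only** in
the generator; all inference models remain time-homogeneous, deliberately
reproducing the misspecification the real analysis faces. Consequently
passing tests show qualitative signature recovery under misspecification,
not consistency of a correctly specified estimator.

What the generator does not emulate: trait-dependent diversification,
fossil/extinct sampling, calibration uncertainty in node ages, and the
phylogenetic autocorrelation of ecological scoring errors. Results on
synthetic data therefore validate the machinery, not the biological
conclusions.

## Problem sizes in the test and acceptance runs

Oracle equivalence uses 100 (tests) / 60 (script) random trees of 2–6
tips across all six models; mapping consistency uses 5,000 maps on a
20-tip fixture; the bridge check 20,000 draws on one branch; parameter
recovery 20 replicates of 800 tips; model selection one 500-tip dataset;
signature recovery 20 replicates × 200 true histories at full study scale
(164 tips). These sizes make each check sharp at desk scale while keeping
a complete run in minutes on one CPU.

## Known limitations

* Time-heterogeneous (epoch) inference models, correlated characters, and
  MCMC over Q are out of scope; Q is fixed at per-tree MLEs for mapping.
* The posterior-summary rule for clades missing from some trees
  (restrict-and-report) is one of several defensible conventions.
* Parallel execution is by per-tree RNG substreams; results are identical
  to serial execution by construction, but no multiprocessing pool is
  bundled.
* The origin-counting audit rule (modal threshold 0.5, ties never count,
  nested origins suppressed) is an explicit operationalization of a count
  that, in the original figures, was read from node pies; the returned
  edge list exists so real-data counts can be reconciled against any other
  rule.
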