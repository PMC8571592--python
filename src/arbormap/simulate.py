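"""Synthetic trees, characters with known histories, and pseudo-posterior
tree sets.

The generator exists so that every pipeline stage can be exercised against
known truth at the scale of the real study: an ultrametric tree of ~164
tips whose root predates the K-Pg boundary (66.02 Ma), three-state tip
characters evolved under a known generator (including the ordered four-rate
structure), an optional epoch schedule that raises the semi-arboreal ->
nonarboreal rate after the boundary, and a set of branch-jittered /
NNI-perturbed trees standing in for a Bayesian posterior sample.

Epoch schedules exist only here: the inference models stay
time-homogeneous, so fitting them to shifted data reproduces the kind of
model misspecification the real analysis faces.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import numpy as np

from . import mk
from .simmap import N_OBS, StochasticMap, count_transitions
from .treeio import STATES, TaxonCharacterTable, Tree

__all__ = [
    "SyntheticScenario",
    "SimulationTruth",
    "simulate_birth_death_tree",
    "simulate_character_history",
    "perturb_tree_set",
    "make_study_fixture",
    "StudyFixture",
]

#: age of the Cretaceous-Paleogene boundary, Myr
KPG_BOUNDARY = 66.02


def tree_from_parent_ages(parent, ages, labels, root) -> Tree:
    """Assemble a Tree from parent pointers and node ages."""
    parent = np.asarray(parent, dtype=np.int64)
    ages = np.asarray(ages, dtype=float)
    n = len(parent)
    children = [[] for _ in range(n)]
    for v in range(n):
        if parent[v] >= 0:
            children[parent[v]].append(v)
    elen = np.zeros(n)
    for v in range(n):
        if parent[v] >= 0:
            elen[v] = ages[parent[v]] - ages[v]
            if elen[v] < 0:
                raise ValueError("child older than parent")
    post = []
    stack = [(root, False)]
    while stack:
        v, done = stack.pop()
        if done:
            post.append(v)
        else:
            stack.append((v, True))
            for c in children[v]:
                stack.append((c, False))
    return Tree(
        parent=parent,
        edge_length=elen,
        children=tuple(tuple(c) for c in children),
        labels=tuple(labels),
        root=int(root),
        postorder=np.array(post, dtype=np.int64),
    )


def simulate_birth_death_tree(n_tips: int, root_age: float, birth: float = 1.0,
                              death: float = 0.0, seed: int = 0,
                              max_retries: int = 10000) -> Tree:
    """Ultrametric birth-death tree conditioned on the extant tip count,
    rescaled so the root sits at ``root_age`` Myr.

    Tips are relabeled ``t1..tn`` deterministically.  The conditioned
    simulation itself is delegated to dendropy.
    """
    from dendropy.simulate import treesim

    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth <= 0:
        raise ValueError("birth rate must be positive")
    from .treeio import _from_dendropy

    rng = random.Random(int(seed))
    last_exc = None
    for _ in range(max_retries):
        try:
            dtree = treesim.birth_death_tree(
                birth_rate=birth, death_rate=death, num_extant_tips=n_tips,
                rng=rng, is_retain_extinct_tips=False,
            )
            break
        except Exception as exc:  # all-extinct replicate; retry
            last_exc = exc
    else:
        raise RuntimeError(f"birth-death retry budget exhausted: {last_exc}")
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon = None
        leaf.label = f"tmp{i}"
    tree = _from_dendropy(dtree, require_lengths=False)

    # rescale to the requested root age and snap tiny float drift so the
    # tree is exactly ultrametric
    # growth stops exactly at the n-th birth, leaving that cherry with
    # zero-length tip edges; observe the tree after the waiting time to the
    # next event instead, which keeps every terminal edge strictly positive
    extension = np.random.default_rng(int(seed) + 1).exponential(
        1.0 / (n_tips * (birth + death))
    )
    depths = tree.depths()
    depths[tree.tip_indices] += extension
    scale = root_age / depths.max()
    ages = (depths.max() - depths) * scale
    ages[tree.tip_indices] = 0.0
    labels = list(tree.labels)
    for i, v in enumerate(tree.tip_indices):
        labels[int(v)] = f"t{i + 1}"
    return tree_from_parent_ages(tree.parent, ages, labels, tree.root)


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic dataset."""

    n_tips: int = 164
    root_age: float = 90.0
    birth: float = 1.0
    death: float = 0.0
    model: str = "four_rate"
    params: tuple = (0.015, 0.015, 0.005, 0.012)
    root_state: int = 0  # arboreal
    #: optional (boundary age, per-epoch params) schedule; None = homogeneous
    shift_age: float | None = None
    shift_params: tuple | None = None
    seed: int = 0


@dataclass(frozen=True)
class SimulationTruth:
    """Generated tree, tip states, and the full true history."""

    tree: Tree
    table: TaxonCharacterTable
    history: StochasticMap
    transition_counts: np.ndarray  # 3x3 observed
    event_ages: tuple  # (from, to, age) tuples


def _epoch_q(spec, scenario):
    """(age_older_bound, Q) epochs, newest last; ages decrease downward."""
    q0 = mk.assemble_q(spec, np.asarray(scenario.params, float))
    if scenario.shift_age is None:
        return [(0.0, q0)]
    q1 = mk.assemble_q(spec, np.asarray(scenario.shift_params, float))
    return [(scenario.shift_age, q0), (0.0, q1)]


def simulate_character_history(tree: Tree, spec, params, root_state=0,
                               schedule=None, seed=0, rng=None) -> SimulationTruth:
    """Exact forward (Gillespie) simulation of the CTMC down the tree.

    ``schedule`` is an optional list of ``(min_age, Q)`` epochs ordered from
    oldest to newest: epoch Q applies while the current age is above
    ``min_age``.  Q changes at epoch boundaries occur mid-edge without
    creating an event.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = [(0.0, mk.assemble_q(spec, np.asarray(params, float)))]
    ages = tree.node_ages()

    def q_at(age):
        for min_age, q in schedule:
            if age > min_age + 1e-12:
                return min_age, q
        return schedule[-1]

    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_states[tree.root] = int(root_state)
    segments = [()] * tree.n_nodes
    for v in tree.preorder:
        v = int(v)
        if v == tree.root:
            continue
        state = int(node_states[tree.parent[v]])
        age = float(ages[tree.parent[v]])
        end_age = float(ages[v])
        segs = []
        seg_start = age
        while True:
            epoch_floor, q = q_at(age)
            boundary = max(epoch_floor, end_age)
            rate = -q[state, state]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if age - wait <= boundary:
                age = boundary
                if boundary <= end_age + 1e-15:
                    break
                continue  # crossed an epoch boundary; switch Q, no event
            age -= wait
            probs = np.clip(q[state].copy(), 0.0, None)
            probs[state] = 0.0
            probs /= probs.sum()
            new_state = int(rng.choice(len(probs), p=probs))
            segs.append((state, float(seg_start - age)))
            state = new_state
            seg_start = age
        segs.append((state, float(seg_start - end_age)))
        segments[v] = tuple(segs)
        node_states[v] = state

    history = StochasticMap(tree=tree, node_states=node_states,
                           segments=tuple(segments))
    states = {}
    for v in tree.tip_indices:
        states[tree.labels[int(v)]] = STATES[int(node_states[int(v)]) % N_OBS]
    table = TaxonCharacterTable(states=states)
    tc = count_transitions(history)
    return SimulationTruth(
        tree=tree,
        table=table,
        history=history,
        transition_counts=tc.counts,
        event_ages=tuple(history.event_ages()),
    )


# ---------------------------------------------------------------------------
# pseudo-posterior tree sets
# ---------------------------------------------------------------------------


def _one_nni(parent, children, ages, root, rng, max_tries=50):
    """In-place rooted NNI: swap a child of an internal node v with one of
    v's siblings, subject to age validity. Returns True on success."""
    internal = [v for v in range(len(parent))
                if children[v] and parent[v] >= 0]
    if not internal:
        return False
    for _ in range(max_tries):
        v = int(rng.choice(internal))
        u = parent[v]
        sibs = [s for s in children[u] if s != v]
        if not sibs:
            continue
        s = int(rng.choice(sibs))
        c = int(rng.choice(children[v]))
        if ages[s] >= ages[v]:
            continue  # s would be older than its new parent v
        children[u][children[u].index(s)] = c
        children[v][children[v].index(c)] = s
        parent[s], parent[c] = v, u
        return True
    return False


def perturb_tree_set(ref: Tree, n: int, branch_jitter_sd: float = 0.1,
                     n_nni: int = 1, seed: int = 0) -> list:
    """Pseudo-posterior sample: log-normal jitter of internal node ages
    (root age preserved, ultrametricity preserved) plus random rooted NNIs.
    """
    if branch_jitter_sd < 0 or n_nni < 0:
        raise ValueError("jitter sd and NNI count must be nonnegative")
    rng = np.random.default_rng(seed)
    ref_ages = ref.node_ages()
    out = []
    for _ in range(n):
        parent = ref.parent.copy()
        children = [list(c) for c in ref.children]
        ages = ref_ages.copy()
        if branch_jitter_sd > 0:
            for v in range(ref.n_nodes):
                if ref.children[v] and v != ref.root:
                    ages[v] *= np.exp(rng.normal(0.0, branch_jitter_sd))
        for _ in range(n_nni):
            _one_nni(parent, children, ages, ref.root, rng)
        # restore parent > child ordering broken by jitter or NNI
        order = _preorder(children, ref.root)
        for v in order:
            if parent[v] >= 0:
                ages[v] = min(ages[v], ages[parent[v]] * (1 - 1e-9))
        out.append(tree_from_parent_ages(parent, ages, ref.labels, ref.root))
    return out


def _preorder(children, root):
    order, stack = [], [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children[v])
    return order


# ---------------------------------------------------------------------------
# the study fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyFixture:
    """Full synthetic stand-in for the study's inputs, with truth retained."""

    scenario: SyntheticScenario
    tree: Tree
    posterior: list
    table: TaxonCharacterTable
    truth: SimulationTruth

    def manifest(self) -> dict:
        return {
            "seed": self.scenario.seed,
            "n_tips": self.scenario.n_tips,
            "root_age": self.scenario.root_age,
            "model": self.scenario.model,
            "params": list(self.scenario.params),
            "shift_age": self.scenario.shift_age,
            "shift_params": list(self.scenario.shift_params or ()),
            "n_posterior": len(self.posterior),
        }


#: default study conditions: root-age-90 tree of 164 lineages, ordered
#: four-rate generator from an arboreal root, with the semi-arboreal ->
#: nonarboreal rate raised after the K-Pg boundary.
DEFAULT_SCENARIO = SyntheticScenario(
    n_tips=164,
    root_age=90.0,
    birth=1.0,
    death=0.0,
    model="four_rate",
    params=(0.015, 0.015, 0.005, 0.012),
    root_state=0,
    shift_age=KPG_BOUNDARY,
    shift_params=(0.015, 0.018, 0.06, 0.02),
    seed=0,
)


def make_study_fixture(seed: int = 0, scenario: SyntheticScenario | None = None,
                       n_posterior: int = 1000, branch_jitter_sd: float = 0.05,
                       n_nni: int = 2) -> StudyFixture:
    """Deterministic synthetic study bundle for a given seed."""
    if scenario is None:
        scenario = SyntheticScenario(
            **{**DEFAULT_SCENARIO.__dict__, "seed": int(seed)}
        )
    ss = np.random.SeedSequence(scenario.seed)
    s_tree, s_hist, s_post = [int(c.generate_state(1)[0] >> 1) for c in ss.spawn(3)]
    tree = simulate_birth_death_tree(
        scenario.n_tips, scenario.root_age, scenario.birth, scenario.death,
        seed=s_tree,
    )
    spec = mk.build_model_spec(scenario.model)
    schedule = [(ma, q) for ma, q in _epoch_q(spec, scenario)]
    truth = simulate_character_history(
        tree, spec, scenario.params, root_state=scenario.root_state,
        schedule=schedule, seed=s_hist,
    )
    posterior = perturb_tree_set(
        tree, n_posterior, branch_jitter_sd=branch_jitter_sd, n_nni=n_nni,
        seed=s_post,
    )
    return StudyFixture(scenario=scenario, tree=tree, posterior=posterior,
                        table=truth.table, truth=truth)


def write_fixture(fix: StudyFixture, outdir) -> None:
    """Serialize a fixture bundle (tree.nwk, posterior.nwk, characters.tsv,
    truth_segments.tsv, manifest.json)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(fix.tree.to_newick() + "\n")
    with open(os.path.join(outdir, "posterior.nwk"), "w") as fh:
        for t in fix.posterior:
            fh.write(t.to_newick() + "\n")
    fix.table.to_frame().to_csv(
        os.path.join(outdir, "characters.tsv"), sep="\t", index=False
    )
    ages = fix.tree.node_ages()
    with open(os.path.join(outdir, "truth_segments.tsv"), "w") as fh:
        fh.write("node\tparent_age\tstate\tduration\n")
        for v in range(fix.tree.n_nodes):
            for st, dur in fix.truth.history.segments[v]:
                fh.write(f"{v}\t{ages[fix.tree.parent[v]]:.9g}\t{STATES[st % N_OBS]}\t{dur:.9g}\n")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(fix.manifest(), fh, indent=2)
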