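"""Bayesian stochastic character mapping.

A stochastic map is a full character history: a sampled state at every node
plus a piecewise-constant state path along every edge, drawn conditional on
the tip data and a generator Q.  Node states are drawn by backward sampling
from the pruning conditionals; edge paths are endpoint-conditioned CTMC
bridges sampled by uniformization (a Poisson number of candidate jumps at a
dominating rate, virtual jumps thinned).

Summaries follow the describe.simmap convention: per-node state frequencies
across maps, optionally projected onto a reference tree through clade
matching, and mean transition-count matrices.  Under hidden-rate models the
observed state is ``expanded_state % 3``; pure class switches are tallied
separately and never appear in the 3x3 observed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mk
from .treeio import NodeMatchTable, Tree

__all__ = [
    "StochasticMap",
    "TransitionCountMatrix",
    "SimmapSummary",
    "BridgeSampler",
    "sample_joint_node_states",
    "sample_branch_history",
    "generate_maps",
    "generate_maps_over_trees",
    "count_transitions",
    "summarize_maps",
]

N_OBS = mk.N_OBS


@dataclass(frozen=True)
class StochasticMap:
    """One sampled character history on a tree.

    ``node_states[v]`` is the expanded-state index sampled at node v;
    ``segments[v]`` lists ``(state, duration)`` pairs along the edge above
    v, ordered from the parent end to the child end (empty at the root).
    """

    tree: Tree
    node_states: np.ndarray
    segments: tuple

    def observed_node_states(self) -> np.ndarray:
        return self.node_states % N_OBS

    def event_ages(self):
        """(from_state, to_state, age) for every state change, in expanded
        states, using node ages of the map's tree."""
        ages = self.tree.node_ages()
        out = []
        for v in range(self.tree.n_nodes):
            if v == self.tree.root:
                continue
            top = ages[self.tree.parent[v]]
            t = 0.0
            segs = self.segments[v]
            for i in range(len(segs) - 1):
                t += segs[i][1]
                out.append((segs[i][0], segs[i + 1][0], top - t))
        return out


@dataclass(frozen=True)
class TransitionCountMatrix:
    """3x3 observed-state change counts plus the pure class-switch tally."""

    counts: np.ndarray
    class_switches: int = 0

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def count_transitions(smap: StochasticMap) -> TransitionCountMatrix:
    counts = np.zeros((N_OBS, N_OBS))
    switches = 0
    for v in range(smap.tree.n_nodes):
        segs = smap.segments[v]
        for i in range(len(segs) - 1):
            a, b = segs[i][0] % N_OBS, segs[i + 1][0] % N_OBS
            if a == b:
                switches += 1
            else:
                counts[a, b] += 1
    return TransitionCountMatrix(counts=counts, class_switches=switches)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def sample_joint_node_states(tree, data, spec, params, root_prior, rng) -> np.ndarray:
    """Draw a joint assignment of expanded states at all nodes from the
    posterior given the tip data (root from the prior-weighted conditionals,
    then each child given its sampled parent)."""
    q = mk.assemble_q(spec, params)
    pmats = mk._edge_pmats(tree, q)
    tp = mk.tip_partials(tree, data, spec)
    down, _ = mk._downward_pass(tree, tp, pmats)
    return _sample_nodes_given_partials(tree, spec, pmats, down, root_prior, rng)


def _sample_nodes_given_partials(tree, spec, pmats, down, root_prior, rng):
    m = spec.n_states
    pi = mk._materialize_root_prior(root_prior, down[tree.root], m)
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    w = pi * down[tree.root]
    states[tree.root] = rng.choice(m, p=w / w.sum())
    for v in tree.preorder:
        v = int(v)
        for c in tree.children[v]:
            w = pmats[c][states[v]] * down[c]
            tot = w.sum()
            if tot <= 0:
                raise ValueError(f"zero conditional probability at node {c}")
            states[c] = rng.choice(m, p=w / tot)
    return states


class BridgeSampler:
    """Endpoint-conditioned CTMC path sampler by uniformization for one Q.

    Caches powers of the uniformized transition matrix R = I + Q/omega and
    per-duration transition matrices, so repeated draws along the same tree
    are cheap.
    """

    #: Poisson-tail cap multiplier; the candidate-jump count is truncated at
    #: mean + 12 sd + 30, far beyond any non-negligible mass.
    _TAIL_SD = 12.0

    def __init__(self, q: np.ndarray):
        self.q = np.asarray(q, float)
        self.m = q.shape[0]
        self.omega = float(max(np.max(-np.diag(self.q)), 0.0))
        if self.omega > 0:
            self.r = np.eye(self.m) + self.q / self.omega
        else:
            self.r = np.eye(self.m)
        self._rpow = [np.eye(self.m), self.r.copy()]
        self._pt = {}

    def _rpower(self, n: int) -> np.ndarray:
        while len(self._rpow) <= n:
            self._rpow.append(self._rpow[-1] @ self.r)
        return self._rpow[n]

    def p_t(self, t: float) -> np.ndarray:
        key = float(t)
        if key not in self._pt:
            self._pt[key] = mk.transition_probabilities(self.q, t)
        return self._pt[key]

    def sample_jump_count(self, a: int, b: int, t: float, rng) -> int:
        """Number of candidate (uniformization) jumps given endpoints."""
        lam = self.omega * t
        if lam == 0:
            if a != b:
                raise ValueError("endpoints differ but the chain cannot move")
            return 0
        pab = self.p_t(t)[a, b]
        if pab <= 0:
            raise ValueError(
                f"endpoint pair {a}->{b} has probability 0 (structural zero)"
            )
        u = rng.random() * pab
        nmax = int(lam + self._TAIL_SD * np.sqrt(lam) + 30)
        logpois = -lam
        acc = 0.0
        n = 0
        while True:
            acc += np.exp(logpois) * self._rpower(n)[a, b]
            if acc >= u or n >= nmax:
                return n
            n += 1
            logpois += np.log(lam) - np.log(n)

    def sample_path(self, a: int, b: int, t: float, rng):
        """One bridge from state a to state b over duration t.

        Returns ``(state, duration)`` segments from the a-end; adjacent
        segments always differ in state.
        """
        if t < 0:
            raise ValueError("duration must be nonnegative")
        if t == 0 or self.omega == 0:
            if a != b:
                raise ValueError("endpoints differ on a zero-motion branch")
            return [(int(a), float(t))]
        n = self.sample_jump_count(a, b, t, rng)
        if n == 0:
            return [(int(a), float(t))]
        times = np.sort(rng.random(n)) * t
        states = np.empty(n + 1, dtype=np.int64)
        states[0] = a
        states[n] = b
        for kk in range(1, n):
            back = self._rpower(n - kk)[:, b]
            w = self.r[states[kk - 1]] * back
            tot = w.sum()
            states[kk] = rng.choice(self.m, p=w / tot)
        # thin virtual jumps -> segments
        segs = []
        seg_state = int(states[0])
        seg_start = 0.0
        for kk in range(1, n + 1):
            if int(states[kk]) != seg_state:
                segs.append((seg_state, float(times[kk - 1] - seg_start)))
                seg_state = int(states[kk])
                seg_start = float(times[kk - 1])
        segs.append((seg_state, float(t - seg_start)))
        return segs


def sample_branch_history(start_state, end_state, t, q, rng, sampler=None):
    """Endpoint-conditioned path on a single branch (see BridgeSampler)."""
    sampler = sampler or BridgeSampler(np.asarray(q, float))
    return sampler.sample_path(int(start_state), int(end_state), float(t), rng)


def generate_maps(tree, data, spec, params, n_maps, root_prior="equal",
                  rng=None, seed=None) -> list:
    """Draw ``n_maps`` stochastic maps on one tree under a fixed Q.

    Edges of length 0 would make endpoint conditioning degenerate; they are
    rejected here (collapse them upstream).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_maps == 0:
        return []
    nonroot = [v for v in range(tree.n_nodes) if v != tree.root]
    if any(tree.edge_length[v] <= 0 for v in nonroot):
        raise ValueError("stochastic mapping requires strictly positive edge lengths")
    q = mk.assemble_q(spec, params)
    pmats = mk._edge_pmats(tree, q)
    tp = mk.tip_partials(tree, data, spec)
    down, _ = mk._downward_pass(tree, tp, pmats)
    bridge = BridgeSampler(q)
    for v in nonroot:
        bridge._pt[float(tree.edge_length[v])] = pmats[v]
    maps = []
    for _ in range(n_maps):
        states = _sample_nodes_given_partials(tree, spec, pmats, down, root_prior, rng)
        segments = [()] * tree.n_nodes
        for v in nonroot:
            segs = bridge.sample_path(
                int(states[tree.parent[v]]), int(states[v]),
                float(tree.edge_length[v]), rng,
            )
            segments[v] = tuple(segs)
        maps.append(StochasticMap(tree=tree, node_states=states,
                                  segments=tuple(segments)))
    return maps


@dataclass
class MappingRun:
    """Maps drawn across a set of trees, with per-tree Q bookkeeping."""

    maps_by_tree: list  # list of (tree index, list of StochasticMap)
    q_by_tree: dict  # tree index -> Q used
    params_by_tree: dict
    skipped: list = field(default_factory=list)  # (tree index, reason)


def generate_maps_over_trees(trees, data, spec, n_maps, root_prior="equal",
                             seed=0, q_source="refit", params=None,
                             optimizer=None) -> MappingRun:
    """Maps over a posterior tree sample.

    ``q_source='refit'`` refits the model by ML on every tree (the workflow
    used for posterior summaries); ``q_source='fixed'`` reuses ``params``.
    Per-tree RNG substreams are spawned from ``seed`` so results do not
    depend on execution order.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(trees))
    run = MappingRun(maps_by_tree=[], q_by_tree={}, params_by_tree={})
    for ti, tree in enumerate(trees):
        rng = np.random.default_rng(children[ti])
        if q_source == "refit":
            try:
                fit = mk.fit_ml(tree, data, spec, root_prior=root_prior,
                                config=optimizer)
            except Exception as exc:
                run.skipped.append((ti, str(exc)))
                continue
            p = fit.params
        elif q_source == "fixed":
            if params is None:
                raise ValueError("q_source='fixed' requires params")
            p = np.asarray(params, float)
        else:
            raise ValueError("q_source must be 'refit' or 'fixed'")
        maps = generate_maps(tree, data, spec, p, n_maps,
                             root_prior=root_prior, rng=rng)
        run.maps_by_tree.append((ti, maps))
        run.q_by_tree[ti] = mk.assemble_q(spec, p)
        run.params_by_tree[ti] = p
    return run


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimmapSummary:
    """Per-reference-node observed-state frequencies across maps.

    Node probabilities average over (map, matched node) pairs; nodes absent
    from a posterior tree contribute nothing there, and the clade frequency
    is reported alongside so consumers can filter.
    """

    ref_tree: Tree
    node_freqs: np.ndarray  # (n_nodes, 3); rows of tips are degenerate
    clade_freq: np.ndarray  # (n_nodes,)
    mean_counts: np.ndarray  # mean 3x3 transition counts per map
    mean_class_switches: float
    n_maps: int
    mean_q: np.ndarray | None = None

    def modal_states(self, threshold: float = 0.0) -> np.ndarray:
        best = self.node_freqs.argmax(axis=1)
        pmax = self.node_freqs.max(axis=1)
        ties = np.isclose(self.node_freqs, pmax[:, None]).sum(axis=1) > 1
        out = best.copy()
        out[(pmax < threshold) | ties] = -1
        return out


def summarize_maps(maps_by_tree, ref_tree: Tree, match: NodeMatchTable | None = None,
                   trees=None, q_by_tree=None) -> SimmapSummary:
    """describe.simmap-style summary projected onto a reference tree.

    ``maps_by_tree`` may be a plain list of maps (all on the reference tree)
    or a list of ``(tree index, maps)`` pairs with a NodeMatchTable mapping
    reference nodes into each tree.
    """
    if maps_by_tree and isinstance(maps_by_tree[0], StochasticMap):
        maps_by_tree = [(0, list(maps_by_tree))]
        identity = True
    else:
        identity = match is None
    total_maps = sum(len(m) for _, m in maps_by_tree)
    if total_maps == 0:
        raise ValueError("no maps to summarize")

    n = ref_tree.n_nodes
    freq = np.zeros((n, N_OBS))
    denom = np.zeros(n)
    counts = np.zeros((N_OBS, N_OBS))
    switches = 0.0

    if identity:
        node_of = {v: {ti: v for ti, _ in maps_by_tree} for v in range(n)}
        present_trees = {v: {ti for ti, _ in maps_by_tree} for v in range(n)}
    else:
        node_of = {}
        present_trees = {}
        for v in match.ref_nodes:
            node_of[v] = {ti: mi for ti, mi in match.matches[v]}
            present_trees[v] = set(node_of[v])
        if trees is not None:
            tip_idx = {
                ti: {trees[ti].labels[int(u)]: int(u) for u in trees[ti].tip_indices}
                for ti, _ in maps_by_tree
            }
        else:
            tip_idx = {}
        for v in ref_tree.tip_indices:
            v = int(v)
            lab = ref_tree.labels[v]
            node_of[v] = {ti: idx[lab] for ti, idx in tip_idx.items()}
            present_trees[v] = set(node_of[v])

    for ti, maps in maps_by_tree:
        for smap in maps:
            obs = smap.observed_node_states()
            for v in range(n):
                mi = node_of.get(v, {}).get(ti)
                if mi is not None:
                    freq[v, obs[mi]] += 1
                    denom[v] += 1
            tc = count_transitions(smap)
            counts += tc.counts
            switches += tc.class_switches

    with np.errstate(invalid="ignore"):
        node_freqs = freq / denom[:, None]
    node_freqs[denom == 0] = np.nan
    n_trees = len(maps_by_tree)
    clade_freq = np.array(
        [len(present_trees.get(v, ())) / n_trees if n_trees else 0.0 for v in range(n)]
    )
    mean_q = None
    if q_by_tree:
        mean_q = np.mean([q_by_tree[ti] for ti, _ in maps_by_tree], axis=0)
    return SimmapSummary(
        ref_tree=ref_tree,
        node_freqs=node_freqs,
        clade_freq=clade_freq,
        mean_counts=counts / total_maps,
        mean_class_switches=switches / total_maps,
        n_maps=total_maps,
        mean_q=mean_q,
    )


def write_maps_tsv(maps_by_tree, trees, path) -> None:
    """Serialize maps as one row per edge segment: tree id, map id, parent
    and child clade hashes, state, start age, end age.  Compact, diffable.
    """
    import hashlib

    if maps_by_tree and isinstance(maps_by_tree[0], StochasticMap):
        maps_by_tree = [(0, list(maps_by_tree))]
        trees = {0: maps_by_tree[0][1][0].tree}
    with open(path, "w") as fh:
        fh.write("tree\tmap\tparent_clade\tchild_clade\tstate\tstart_age\tend_age\n")
        for ti, maps in maps_by_tree:
            tree = trees[ti] if not isinstance(trees, list) else trees[ti]
            keys = tree.clade_keys()
            hashes = {
                v: hashlib.sha1(";".join(sorted(k)).encode()).hexdigest()[:12]
                for v, k in keys.items()
            }
            ages = tree.node_ages()
            for mi, smap in enumerate(maps):
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    age = ages[tree.parent[v]]
                    for state, dur in smap.segments[v]:
                        fh.write(
                            f"{ti}\t{mi}\t{hashes[tree.parent[v]]}\t{hashes[v]}"
                            f"\t{state}\t{age:.9g}\t{age - dur:.9g}\n"
                        )
                        age -= dur
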