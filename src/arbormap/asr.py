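"""Ancestral state reconstruction: marginal likelihood and parsimony.

Marginal probabilities come from the standard inside-outside computation
(equivalent to re-rooting at every node); parsimony reconstructions use the
two-pass Sankoff algorithm with ties kept as state sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mk
from .treeio import STATES, TaxonCharacterTable, Tree

__all__ = [
    "NodeStateProbabilities",
    "ParsimonyReconstruction",
    "marginal_asr",
    "parsimony_asr",
    "unordered_costs",
    "ordered_costs",
]

N_OBS = mk.N_OBS


@dataclass(frozen=True)
class NodeStateProbabilities:
    """Per-node marginal probabilities over the three observed states.

    ``probs[v]`` is the probability vector for node index ``v`` (tips are
    degenerate unit vectors); hidden classes are already summed out.
    ``expanded`` optionally keeps the per-(state, class) marginals.
    """

    probs: np.ndarray
    expanded: np.ndarray | None = None

    def modal_states(self, threshold: float = 0.0) -> np.ndarray:
        """Index of the most probable state per node, -1 where the maximum
        does not exceed ``threshold`` or is tied."""
        best = self.probs.argmax(axis=1)
        pmax = self.probs.max(axis=1)
        ties = (np.isclose(self.probs, pmax[:, None]).sum(axis=1)) > 1
        out = best.copy()
        out[(pmax < threshold) | ties] = -1
        return out


def marginal_asr(tree: Tree, data: TaxonCharacterTable, spec, params,
                 root_prior="equal") -> NodeStateProbabilities:
    """Marginal probability of each state at each node given all tip data."""
    q = mk.assemble_q(spec, params)
    m = spec.n_states
    pmats = mk._edge_pmats(tree, q)
    tp = mk.tip_partials(tree, data, spec)
    down, _ = mk._downward_pass(tree, tp, pmats)
    pi = mk._materialize_root_prior(root_prior, down[tree.root], m)

    # messages from child c to its parent: P_c @ down[c]
    msg = np.zeros((tree.n_nodes, m))
    for v in tree.postorder:
        v = int(v)
        if v != tree.root:
            msg[v] = pmats[v] @ down[v]

    out = np.zeros((tree.n_nodes, m))
    out[tree.root] = pi
    for v in tree.preorder:
        v = int(v)
        for c in tree.children[v]:
            sib = out[v].copy()
            for b in tree.children[v]:
                if b != c:
                    sib *= msg[b]
            vec = sib @ pmats[c]
            s = vec.sum()
            out[c] = vec / s if s > 0 else vec

    marg = down * out
    tot = marg.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("zero marginal likelihood at some node")
    marg /= tot
    obs = marg.reshape(tree.n_nodes, spec.n_classes, N_OBS).sum(axis=1)
    return NodeStateProbabilities(probs=obs, expanded=marg if spec.n_classes > 1 else None)


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

_INF = 1e18


def unordered_costs() -> np.ndarray:
    """Fitch-style costs: any change costs 1."""
    c = np.ones((N_OBS, N_OBS)) - np.eye(N_OBS)
    return c

def ordered_costs() -> np.ndarray:
    """Linear A - S - N ordering: the direct A<->N step costs 2."""
    idx = np.arange(N_OBS)
    return np.abs(idx[:, None] - idx[None, :]).astype(float)


@dataclass(frozen=True)
class ParsimonyReconstruction:
    """Most-parsimonious state sets per node and the minimum change count."""

    state_sets: tuple  # per node: frozenset of state indices
    length: float

    def states_at(self, v: int):
        return {STATES[i] for i in self.state_sets[v]}


def parsimony_asr(tree: Tree, data: TaxonCharacterTable,
                  costs: np.ndarray | None = None) -> ParsimonyReconstruction:
    """Sankoff dynamic program; MPR sets contain every state that appears
    in at least one globally minimum-cost assignment."""
    costs = unordered_costs() if costs is None else np.asarray(costs, float)
    n = tree.n_nodes
    g = np.zeros((n, N_OBS))  # min cost of subtree below v given state at v
    for v in tree.postorder:
        v = int(v)
        if not tree.children[v]:
            lab = tree.labels[v]
            if lab not in data.states:
                raise ValueError(f"tip {lab!r} has no character state")
            s = STATES.index(data.states[lab])
            g[v] = _INF
            g[v, s] = 0.0
        else:
            for c in tree.children[v]:
                g[v] += np.min(costs + g[c][None, :], axis=1)
    length = float(g[tree.root].min())

    # outside costs: h[v, s] = min cost of the rest of the tree given v = s
    h = np.zeros((n, N_OBS))
    for v in tree.preorder:
        v = int(v)
        for c in tree.children[v]:
            contrib = np.min(costs + g[c][None, :], axis=1)  # per parent state
            base = h[v] + g[v] - contrib  # total at v excluding subtree c
            h[c] = np.min(base[:, None] + costs, axis=0)

    sets = []
    for v in range(n):
        total = g[v] + h[v]
        best = total.min()
        sets.append(frozenset(int(s) for s in np.flatnonzero(total <= best + 1e-9)))
    return ParsimonyReconstruction(state_sets=tuple(sets), length=length)


def to_annotated_newick(tree: Tree, probs: NodeStateProbabilities) -> str:
    """Newick with per-node probability comments for plotting tools.

    Each node carries a ``[&p_<state>=...]`` comment block with its three
    observed-state marginals.
    """
    def comment(v):
        body = ",".join(
            f"p_{s.replace('-', '_')}={probs.probs[v, i]:.6g}"
            for i, s in enumerate(STATES)
        )
        return f"[&{body}]"

    def rec(v):
        if not tree.children[v]:
            lab = tree.labels[v] or ""
        else:
            lab = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return lab + comment(v)
        return f"{lab}{comment(v)}:{tree.edge_length[v]:.12g}"

    return rec(tree.root) + ";"
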