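"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's pruning/sampling code paths: the
likelihood oracle enumerates internal-state assignments, the parsimony
oracle enumerates full assignments, and the jump-count oracle augments the
generator with a counting register and takes one matrix exponential.
"""

import itertools

import numpy as np
import scipy.linalg

from arbormap import mk


def enumeration_loglik(tree, data, spec, params, root_prior="equal"):
    """Likelihood by exhaustive summation over internal-state assignments."""
    m = spec.n_states
    q = mk.assemble_q(spec, params)
    pmats = [mk.transition_probabilities(q, float(t)) for t in tree.edge_length]
    tp = mk.tip_partials(tree, data, spec)
    tipmap = {int(v): i for i, v in enumerate(tree.tip_indices)}
    internals = [int(v) for v in tree.postorder if tree.children[v]]
    nonroot = [v for v in range(tree.n_nodes) if v != tree.root]

    def assignment_weight(amap):
        p = 1.0
        for v in nonroot:
            pv = amap[tree.parent[v]]
            if v in amap:
                p *= pmats[v][pv, amap[v]]
            else:
                p *= float(pmats[v][pv] @ tp[tipmap[v]])
        return p

    if not internals:  # single-tip tree
        tipvec = tp[0]
        if root_prior == "equal":
            return float(np.log(np.mean(tipvec)))
        w = tipvec / tipvec.sum()
        return float(np.log(w @ tipvec))

    per_root = np.zeros(m)
    for assign in itertools.product(range(m), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        per_root[amap[tree.root]] += assignment_weight(amap)
    if root_prior == "equal":
        lik = per_root.mean()
    elif root_prior == "fitzjohn":
        lik = float(per_root @ per_root) / per_root.sum()
    else:
        lik = float(np.asarray(root_prior) @ per_root)
    return float(np.log(lik))


def enumeration_marginals(tree, data, spec, params, root_prior="equal"):
    """Observed-state node marginals by the same exhaustive sum."""
    m = spec.n_states
    q = mk.assemble_q(spec, params)
    pmats = [mk.transition_probabilities(q, float(t)) for t in tree.edge_length]
    tp = mk.tip_partials(tree, data, spec)
    tipmap = {int(v): i for i, v in enumerate(tree.tip_indices)}
    internals = [int(v) for v in tree.postorder if tree.children[v]]
    nonroot = [v for v in range(tree.n_nodes) if v != tree.root]
    tips = [int(v) for v in tree.tip_indices]

    # enumerate tip expanded states too, so every node has a state
    post = np.zeros((tree.n_nodes, m))
    nodes = internals + tips
    per_root_total = None
    for assign in itertools.product(range(m), repeat=len(nodes)):
        amap = dict(zip(nodes, assign))
        p = 1.0
        for v in tips:
            p *= tp[tipmap[v]][amap[v]]
        if p == 0:
            continue
        for v in nonroot:
            p *= pmats[v][amap[tree.parent[v]], amap[v]]
        if root_prior == "equal":
            p /= m
        for v in nodes:
            post[v, amap[v]] += p
    if root_prior != "equal":
        raise NotImplementedError
    tot = post[tree.root].sum()
    post /= tot
    return post.reshape(tree.n_nodes, spec.n_classes, 3).sum(axis=1)


def parsimony_bruteforce(tree, data, costs):
    """Minimum change count and MPR sets by enumerating full assignments."""
    from arbormap.treeio import STATES

    internals = [int(v) for v in tree.postorder if tree.children[v]]
    tips = {int(v): STATES.index(data.states[tree.labels[int(v)]])
            for v in tree.tip_indices}
    nonroot = [v for v in range(tree.n_nodes) if v != tree.root]
    best = np.inf
    sets = {v: set() for v in range(tree.n_nodes)}
    for assign in itertools.product(range(3), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        amap.update(tips)
        cost = sum(costs[amap[tree.parent[v]], amap[v]] for v in nonroot)
        if cost < best - 1e-9:
            best = cost
            sets = {v: {amap[v]} for v in amap}
        elif abs(cost - best) <= 1e-9:
            for v in amap:
                sets[v].add(amap[v])
    return best, {v: frozenset(s) for v, s in sets.items()}


def jump_count_distribution(q, a, b, t, max_jumps=60):
    """P(number of state changes = k | X(0)=a, X(t)=b) via a counting
    register appended to the generator and one expm."""
    m = q.shape[0]
    big = np.zeros((m * max_jumps, m * max_jumps))
    for k in range(max_jumps):
        for i in range(m):
            big[k * m + i, k * m + i] = q[i, i]
            if k + 1 < max_jumps:
                for j in range(m):
                    if j != i:
                        big[k * m + i, (k + 1) * m + j] = q[i, j]
    p = scipy.linalg.expm(big * t)
    probs = np.array([p[a, k * m + b] for k in range(max_jumps)])
    return probs / probs.sum()


def random_tree_newick(rng, n_tips, max_bl=2.0):
    """Random topology with uniform branch lengths, as Newick text."""
    parts = [f"s{i}:{rng.uniform(0.1, max_bl):.6f}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = rng.choice(len(parts), size=2, replace=False)
        merged = f"({parts[i]},{parts[j]}):{rng.uniform(0.1, max_bl):.6f}"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parts[0].rsplit(":", 1)[0] + ";"


def enumeration_loglik_fast(tree, data, spec, params, root_prior="equal"):
    """Vectorized exhaustive enumeration over internal-state assignments.

    Same sum as :func:`enumeration_loglik`, evaluated with array indexing so
    hidden-rate models on 6-tip trees stay fast.
    """
    m = spec.n_states
    q = mk.assemble_q(spec, params)
    pmats = [mk.transition_probabilities(q, float(t)) for t in tree.edge_length]
    tp = mk.tip_partials(tree, data, spec)
    tipmap = {int(v): i for i, v in enumerate(tree.tip_indices)}
    internals = [int(v) for v in tree.postorder if tree.children[v]]
    col = {v: i for i, v in enumerate(internals)}

    if not internals:
        tipvec = tp[0]
        w = np.full(m, 1.0 / m) if root_prior == "equal" else tipvec / tipvec.sum()
        return float(np.log(w @ tipvec))

    n_assign = m ** len(internals)
    assign = np.indices((m,) * len(internals)).reshape(len(internals), n_assign).T
    weight = np.ones(n_assign)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        pv = assign[:, col[tree.parent[v]]]
        if v in col:
            weight *= pmats[v][pv, assign[:, col[v]]]
        else:
            weight *= (pmats[v] @ tp[tipmap[v]])[pv]
    per_root = np.bincount(assign[:, col[tree.root]], weights=weight, minlength=m)
    if root_prior == "equal":
        lik = per_root.mean()
    elif root_prior == "fitzjohn":
        lik = float(per_root @ per_root) / per_root.sum()
    else:
        lik = float(np.asarray(root_prior) @ per_root)
    return float(np.log(lik))
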