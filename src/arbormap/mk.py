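"""Mk and hidden-rate-class transition models for the three substrate states.

The observed character has three states in fixed order
``arboreal (A) = 0, semi-arboreal (S) = 1, nonarboreal (N) = 2``.
Hidden-rate-class (HMM) variants expand the state space to
``(observed state, rate class)`` pairs, indexed ``class * 3 + observed``,
with one shared symmetric switch rate connecting the same observed state
across classes.

Model family:

``two_rate``
    all six transitions allowed; those entering or leaving semi-arboreality
    share one rate, the direct A<->N pair shares a second (k = 2).
``four_rate``
    ordered model: A<->S and S<->N each get separate forward and reverse
    rates; direct A<->N transitions are structural zeros (k = 4).
``ard``
    all rates different (k = 6).
``hmm_ard_plus_four_rate_2class`` (k = 11), ``hmm_ard_2class`` (k = 13),
``hmm_ard_3class`` (k = 19)
    hidden-rate expansions with the within-class templates named.

Likelihoods use Felsenstein pruning with per-node rescaling; per-edge
transition probabilities are computed in a batch from one eigendecomposition
of Q, with a ``scipy.linalg.expm`` fallback for ill-conditioned cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .treeio import STATES, TaxonCharacterTable, Tree

__all__ = [
    "ModelSpec",
    "FitResult",
    "OptimizerConfig",
    "MODEL_NAMES",
    "build_model_spec",
    "assemble_q",
    "transition_probabilities",
    "edge_probabilities",
    "tip_partials",
    "pruning_loglik",
    "fitzjohn_root_weights",
    "fit_ml",
    "aic_score",
    "model_selection_table",
]

N_OBS = 3


@dataclass(frozen=True, eq=False)
class ModelSpec:
    """Parameter-sharing template over the (possibly expanded) state space.

    ``index_matrix[i, j]`` is 0 for a structural zero and otherwise the
    1-based index of the free parameter filling entry ``i -> j``; entries
    sharing an index share a rate.  ``k`` is the number of free parameters.
    """

    name: str
    n_classes: int
    index_matrix: np.ndarray
    param_names: tuple

    @property
    def k(self) -> int:
        return len(self.param_names)

    @property
    def n_states(self) -> int:
        return N_OBS * self.n_classes


_OBS_TEMPLATES = {
    # off-diagonal index templates over (A, S, N); 0 = structural zero
    "two_rate": np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]]),
    "four_rate": np.array([[0, 1, 0], [2, 0, 3], [0, 4, 0]]),
    "ard": np.array([[0, 1, 2], [3, 0, 4], [5, 0, 6]]),
}
# fix ard: fill all six distinctly
_OBS_TEMPLATES["ard"] = np.array([[0, 1, 2], [3, 0, 4], [5, 6, 0]])

_OBS_PARAM_NAMES = {
    "two_rate": ("via_semi", "direct"),
    "four_rate": ("A->S", "S->A", "S->N", "N->S"),
    "ard": ("A->S", "A->N", "S->A", "S->N", "N->A", "N->S"),
}

MODEL_NAMES = (
    "two_rate",
    "four_rate",
    "ard",
    "hmm_ard_plus_four_rate_2class",
    "hmm_ard_2class",
    "hmm_ard_3class",
)

_HMM_CLASS_TEMPLATES = {
    "hmm_ard_plus_four_rate_2class": ("ard", "four_rate"),
    "hmm_ard_2class": ("ard", "ard"),
    "hmm_ard_3class": ("ard", "ard", "ard"),
}


def build_model_spec(name: str) -> ModelSpec:
    """Construct one of the six named model templates."""
    if name in _OBS_TEMPLATES:
        tmpl = _OBS_TEMPLATES[name]
        return ModelSpec(
            name=name,
            n_classes=1,
            index_matrix=tmpl.copy(),
            param_names=_OBS_PARAM_NAMES[name],
        )
    if name not in _HMM_CLASS_TEMPLATES:
        raise ValueError(f"unknown model {name!r}; valid names: {MODEL_NAMES}")
    classes = _HMM_CLASS_TEMPLATES[name]
    c = len(classes)
    m = N_OBS * c
    idx = np.zeros((m, m), dtype=int)
    names = []
    offset = 0
    for ci, tname in enumerate(classes):
        tmpl = _OBS_TEMPLATES[tname]
        block = tmpl.copy()
        block[block > 0] += offset
        idx[ci * N_OBS : (ci + 1) * N_OBS, ci * N_OBS : (ci + 1) * N_OBS] = block
        names.extend(f"c{ci + 1}:{p}" for p in _OBS_PARAM_NAMES[tname])
        offset += len(_OBS_PARAM_NAMES[tname])
    # one shared symmetric class-switch rate, same observed state only
    switch = offset + 1
    for ci in range(c):
        for cj in range(c):
            if ci != cj:
                for s in range(N_OBS):
                    idx[ci * N_OBS + s, cj * N_OBS + s] = switch
    names.append("class_switch")
    return ModelSpec(name=name, n_classes=c, index_matrix=idx, param_names=tuple(names))


def assemble_q(spec: ModelSpec, params) -> np.ndarray:
    """Fill the generator from a parameter vector; rows sum to zero."""
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.k,):
        raise ValueError(f"expected {spec.k} rates for {spec.name}, got {params.shape}")
    if np.any(params < 0):
        raise ValueError("rates must be nonnegative")
    m = spec.n_states
    q = np.zeros((m, m))
    nz = spec.index_matrix > 0
    q[nz] = params[spec.index_matrix[nz] - 1]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def transition_probabilities(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) for a single duration t >= 0."""
    if t < 0:
        raise ValueError("duration must be nonnegative")
    if t == 0:
        return np.eye(q.shape[0])
    return scipy.linalg.expm(q * t)


def edge_probabilities(q: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """Batch of P(t) for many durations from one eigendecomposition of Q.

    Falls back to per-edge ``expm`` when the eigenvector matrix is
    ill-conditioned (defective or near-defective Q).
    """
    durations = np.asarray(durations, dtype=float)
    m = q.shape[0]
    try:
        lam, vec = np.linalg.eig(q)
        vinv = np.linalg.inv(vec)
        cond = np.linalg.cond(vec)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        e = np.exp(np.multiply.outer(durations, lam))  # (E, m)
        p = np.einsum("ij,ej,jk->eik", vec, e, vinv)
        p = np.ascontiguousarray(p.real)
    else:
        p = np.stack([scipy.linalg.expm(q * t) for t in durations])
    np.clip(p, 0.0, 1.0, out=p)
    p /= p.sum(axis=2, keepdims=True)
    return p


def tip_partials(tree: Tree, data: TaxonCharacterTable, spec: ModelSpec) -> np.ndarray:
    """Conditional likelihood vectors at the tips.

    A tip observed in state X gets likelihood 1 for (X, class j) for every
    hidden class j, 0 elsewhere.
    """
    m = spec.n_states
    tips = tree.tip_indices
    out = np.zeros((len(tips), m))
    for row, v in enumerate(tips):
        lab = tree.labels[v]
        if lab not in data.states:
            raise ValueError(f"tip {lab!r} has no character state")
        s = STATES.index(data.states[lab])
        out[row, s::N_OBS] = 1.0
    return out


def _downward_pass(tree, partials_tips, pmats):
    """Scaled postorder conditionals.

    Returns (down, logscale) where ``down[v]`` is the rescaled conditional
    likelihood vector of the subtree below v and ``logscale`` accumulates
    the logs of the per-node scalers.
    """
    m = partials_tips.shape[1]
    down = np.zeros((tree.n_nodes, m))
    tipmap = {int(v): i for i, v in enumerate(tree.tip_indices)}
    logscale = 0.0
    for v in tree.postorder:
        v = int(v)
        if not tree.children[v]:
            down[v] = partials_tips[tipmap[v]]
            continue
        w = np.ones(m)
        for c in tree.children[v]:
            w = w * (pmats[c] @ down[c])
        s = w.max()
        if s <= 0 or not np.isfinite(s):
            raise ValueError(f"zero likelihood at clade of node {v}")
        down[v] = w / s
        logscale += np.log(s)
    return down, logscale


def _edge_pmats(tree, q):
    p = edge_probabilities(q, tree.edge_length)
    p[tree.root] = np.eye(q.shape[0])
    return p


def fitzjohn_root_weights(root_conditionals) -> np.ndarray:
    """Root weights proportional to the root conditional likelihoods."""
    v = np.asarray(root_conditionals, dtype=float)
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("root conditionals must be nonnegative and not all zero")
    return v / v.sum()


def _materialize_root_prior(root_prior, root_cond, m):
    if isinstance(root_prior, str):
        if root_prior == "equal":
            return np.full(m, 1.0 / m)
        if root_prior == "fitzjohn":
            return fitzjohn_root_weights(root_cond)
        raise ValueError(f"unknown root prior {root_prior!r}")
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (m,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-9:
        raise ValueError("fixed root prior must be a probability vector over states")
    return pi


def pruning_loglik(tree, data, spec, params, root_prior="equal") -> float:
    """Log-likelihood of the tip data by Felsenstein pruning.

    Hidden classes are marginalized; the root is collapsed with the given
    prior ('equal' over expanded states, 'fitzjohn', or a fixed vector).
    """
    q = assemble_q(spec, params)
    pmats = _edge_pmats(tree, q)
    tp = tip_partials(tree, data, spec)
    down, logscale = _downward_pass(tree, tp, pmats)
    rc = down[tree.root]
    pi = _materialize_root_prior(root_prior, rc, spec.n_states)
    lik = float(pi @ rc)
    if lik <= 0:
        raise ValueError("non-positive likelihood at root")
    return float(np.log(lik) + logscale)


def aic_score(logl: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * logl


def aicc_score(logl: float, k: int, n: int) -> float:
    """Small-sample corrected AIC (optional; n = number of tips)."""
    if n - k - 1 <= 0:
        return np.inf
    return aic_score(logl, k) + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class OptimizerConfig:
    """Bounds and restart policy for the rate optimizer (log scale)."""

    lower: float = 1e-8
    upper: float = 1e2
    n_restarts: int = 10
    tol: float = 1e-8
    seed: int = 0
    # log-uniform window the restart draws come from
    start_low: float = 1e-3
    start_high: float = 1.0


@dataclass(frozen=True, eq=False)
class FitResult:
    spec: ModelSpec
    params: np.ndarray
    q: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_restarts: int
    root_prior: str = "equal"

    @property
    def k(self) -> int:
        return self.spec.k


def fit_ml(tree, data, spec, root_prior="equal", config: OptimizerConfig | None = None) -> FitResult:
    """Maximum-likelihood rates by L-BFGS-B on log-rates with restarts.

    The convergence flag is true when at least one other restart agrees
    with the best within 0.01 log-units (always true for a single restart
    that the optimizer reports as successful).
    """
    config = config or OptimizerConfig()
    q0 = assemble_q(spec, np.ones(spec.k))  # validates spec
    del q0
    tp = tip_partials(tree, data, spec)
    lo, hi = np.log(config.lower), np.log(config.upper)

    def negll(logp):
        q = assemble_q(spec, np.exp(logp))
        pmats = _edge_pmats(tree, q)
        try:
            down, logscale = _downward_pass(tree, tp, pmats)
        except ValueError:
            return 1e300
        rc = down[tree.root]
        pi = _materialize_root_prior(root_prior, rc, spec.n_states)
        lik = float(pi @ rc)
        if lik <= 0 or not np.isfinite(lik):
            return 1e300
        return -(np.log(lik) + logscale)

    rng = np.random.default_rng(config.seed)
    # deterministic first start at the empirical rate scale
    starts = [np.full(spec.k, np.log(0.05))]
    for _ in range(max(config.n_restarts - 1, 0)):
        starts.append(
            rng.uniform(np.log(config.start_low), np.log(config.start_high), spec.k)
        )
    results = []
    for x0 in starts:
        res = scipy.optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * spec.k,
            options={"ftol": config.tol, "maxiter": 500},
        )
        results.append(res)
    best = min(results, key=lambda r: r.fun)
    if best.fun >= 1e299:
        raise RuntimeError(f"optimizer failed on all restarts for {spec.name}")
    others = sorted(r.fun for r in results if r is not best)
    if len(results) == 1:
        converged = bool(best.success)
    else:
        converged = bool(others and (others[0] - best.fun) <= 0.01)
    params = np.exp(best.x)
    logl = -float(best.fun)
    return FitResult(
        spec=spec,
        params=params,
        q=assemble_q(spec, params),
        loglik=logl,
        aic=aic_score(logl, spec.k),
        converged=converged,
        n_restarts=len(results),
        root_prior=root_prior if isinstance(root_prior, str) else "fixed",
    )


def model_selection_table(tree, data, specs, root_prior="equal", config=None) -> pd.DataFrame:
    """Fit every spec and rank by AIC (ascending); fit failures become
    flagged rows rather than aborting the comparison."""
    if len(specs) < 2:
        raise ValueError("need at least two models to compare")
    rows = []
    fits = {}
    for spec in specs:
        if isinstance(spec, str):
            spec = build_model_spec(spec)
        try:
            fit = fit_ml(tree, data, spec, root_prior=root_prior, config=config)
            fits[spec.name] = fit
            rows.append(
                dict(model=spec.name, k=spec.k, logL=fit.loglik, AIC=fit.aic,
                     converged=fit.converged, error="")
            )
        except Exception as exc:  # keep the comparison alive
            rows.append(
                dict(model=spec.name, k=spec.k, logL=np.nan, AIC=np.nan,
                     converged=False, error=str(exc))
            )
    df = pd.DataFrame(rows)
    best = df["AIC"].min()
    df["dAIC"] = df["AIC"] - best
    df = df.sort_values("AIC", na_position="last").reset_index(drop=True)
    df.attrs["fits"] = fits
    return df


def write_q_tsv(q: np.ndarray, path, n_classes: int = 1) -> None:
    """Write a generator as a labeled TSV (state rows/columns)."""
    if n_classes == 1:
        labels = list(STATES)
    else:
        labels = [f"{s}|c{c + 1}" for c in range(n_classes) for s in STATES]
    pd.DataFrame(q, index=labels, columns=labels).to_csv(path, sep="\t")
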