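"""Config-driven end-to-end analysis: model selection, reconstructions,
stochastic-map summaries, transition-rate-through-time curves, and the
count of post-boundary origins of arboreality.

The configuration is a flat ``key = value`` text file; every run writes a
JSON manifest (seed, config hash, package version) before computing, and
identical manifests reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, asr, mk, rtt, simmap
from .simulate import KPG_BOUNDARY
from .treeio import (STATES, Tree, match_nodes, parse_tree, parse_trees,
                     read_character_table, read_rename_map)

__all__ = [
    "AnalysisConfig",
    "load_config",
    "run_model_selection",
    "run_asr",
    "run_rtt",
    "count_post_boundary_arboreal_origins",
    "write_report",
]


@dataclass
class AnalysisConfig:
    tree_path: str = ""
    posterior_path: str = ""
    characters_path: str = ""
    rename_map_path: str = ""
    models: tuple = mk.MODEL_NAMES
    root_prior: str = "equal"
    n_maps: int = 5000
    n_maps_posterior: int = 500
    n_posterior: int = 1000
    n_bins: int = 50
    boundary_age: float = KPG_BOUNDARY
    modal_threshold: float = 0.5
    seed: int = 0
    n_restarts: int = 10
    outdir: str = "arbormap_out"

    def optimizer(self) -> mk.OptimizerConfig:
        return mk.OptimizerConfig(n_restarts=self.n_restarts, seed=self.seed)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_INT_KEYS = {"n_maps", "n_maps_posterior", "n_posterior", "n_bins", "seed",
             "n_restarts"}
_FLOAT_KEYS = {"boundary_age", "modal_threshold"}


def load_config(path) -> AnalysisConfig:
    """Read a flat ``key = value`` config file (``#`` comments allowed)."""
    cfg = AnalysisConfig()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if not hasattr(cfg, key):
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            if key == "models":
                setattr(cfg, key, tuple(m.strip() for m in val.split(",")))
            elif key in _INT_KEYS:
                setattr(cfg, key, int(val))
            elif key in _FLOAT_KEYS:
                setattr(cfg, key, float(val))
            else:
                setattr(cfg, key, val)
    return cfg


def _load_inputs(config):
    rename = None
    if config.rename_map_path:
        rename = read_rename_map(config.rename_map_path)
    with open(config.tree_path) as fh:
        tree = parse_tree(fh.read())
    with open(config.characters_path) as fh:
        table = read_character_table(fh, rename_map=rename)
    posterior = []
    if config.posterior_path and os.path.exists(config.posterior_path):
        with open(config.posterior_path) as fh:
            posterior = parse_trees(fh.read())[: config.n_posterior]
    return tree, table, posterior


def _write_manifest(config, outdir, stage):
    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(os.path.join(outdir, f"manifest_{stage}.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def run_model_selection(config: AnalysisConfig, tree=None, table=None) -> pd.DataFrame:
    """Fit every configured model on the consensus tree and rank by AIC."""
    if tree is None:
        tree, table, _ = _load_inputs(config)
    _write_manifest(config, config.outdir, "fit")
    df = mk.model_selection_table(
        tree, table, list(config.models), root_prior=config.root_prior,
        config=config.optimizer(),
    )
    df.to_csv(os.path.join(config.outdir, "model_selection.tsv"),
              sep="\t", index=False)
    return df


def chosen_model(df: pd.DataFrame) -> str:
    ok = df[df["converged"] & df["AIC"].notna()]
    if ok.empty:
        ok = df[df["AIC"].notna()]
    return str(ok.sort_values("AIC").iloc[0]["model"])


def run_asr(config: AnalysisConfig, tree=None, table=None, posterior=None,
            fit=None):
    """Marginal ASR, parsimony ASR, and stochastic-map summaries.

    Returns a dict with the consensus-tree results and, when a posterior
    sample is available, the per-tree refit mapping summary projected onto
    the consensus tree by clade matching.
    """
    if tree is None:
        tree, table, posterior = _load_inputs(config)
    _write_manifest(config, config.outdir, "asr")
    if fit is None:
        spec = mk.build_model_spec(config.models[0] if len(config.models) == 1
                                   else "four_rate")
        fit = mk.fit_ml(tree, table, spec, root_prior=config.root_prior,
                        config=config.optimizer())
    marginal = asr.marginal_asr(tree, table, fit.spec, fit.params,
                                root_prior=config.root_prior)
    pars = asr.parsimony_asr(tree, table)
    maps = simmap.generate_maps(tree, table, fit.spec, fit.params,
                                config.n_maps, root_prior=config.root_prior,
                                seed=config.seed)
    summary = simmap.summarize_maps(maps, tree)
    out = {
        "fit": fit,
        "marginal": marginal,
        "parsimony": pars,
        "consensus_maps": maps,
        "consensus_summary": summary,
        "posterior_summary": None,
        "posterior_run": None,
    }
    if posterior:
        run = simmap.generate_maps_over_trees(
            posterior, table, fit.spec, config.n_maps_posterior,
            root_prior=config.root_prior, seed=config.seed, q_source="refit",
            optimizer=config.optimizer(),
        )
        kept = [ti for ti, _ in run.maps_by_tree]
        match = match_nodes(tree, [posterior[ti] for ti in kept])
        remap = [(i, maps_i) for i, (_, maps_i) in enumerate(run.maps_by_tree)]
        out["posterior_summary"] = simmap.summarize_maps(
            remap, tree, match=match, trees=[posterior[ti] for ti in kept],
            q_by_tree={i: run.q_by_tree[ti] for i, ti in enumerate(kept)},
        )
        out["posterior_run"] = run
    _write_node_table(tree, marginal, summary,
                      os.path.join(config.outdir, "node_states.tsv"))
    mk.write_q_tsv(fit.q, os.path.join(config.outdir, f"q_{fit.spec.name}.tsv"),
                   n_classes=fit.spec.n_classes)
    with open(os.path.join(config.outdir, "asr_annotated.nwk"), "w") as fh:
        fh.write(asr.to_annotated_newick(tree, marginal) + "\n")
    return out


def _write_node_table(tree, marginal, summary, path):
    keys = tree.clade_keys()
    ages = tree.node_ages()
    rows = []
    for v in range(tree.n_nodes):
        key = ";".join(sorted(keys[v]))
        h = hashlib.sha1(key.encode()).hexdigest()[:12]
        row = dict(node=v, age=ages[v], clade_hash=h,
                   is_tip=not tree.children[v])
        for i, s in enumerate(STATES):
            row[f"p_marginal_{s}"] = marginal.probs[v, i]
            row[f"p_simmap_{s}"] = summary.node_freqs[v, i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def count_post_boundary_arboreal_origins(tree: Tree, modal_states,
                                         boundary: float = KPG_BOUNDARY):
    """Count independent origins of arboreality younger than the boundary.

    An origin is an edge whose child's modal state is arboreal, whose
    parent's is not (ties, coded -1, never count), with the child node age
    below the boundary.  Once an origin is counted the entire arboreal
    subtree below it is covered, so nested re-origins after a reversal
    inside it are not double-counted.  Returns ``(count, edge list)``.
    """
    ages = tree.node_ages()
    arboreal = STATES.index("arboreal")
    modal = np.asarray(modal_states)
    count = 0
    edges = []
    covered = np.zeros(tree.n_nodes, bool)
    for v in tree.preorder:
        v = int(v)
        p = tree.parent[v]
        if p < 0:
            continue
        if covered[p]:
            covered[v] = True
            continue
        if (modal[v] == arboreal and modal[p] != arboreal
                and modal[p] != -1 and ages[v] < boundary):
            count += 1
            edges.append((int(p), v))
            covered[v] = True
    return count, edges


def run_rtt(config: AnalysisConfig, tree=None, table=None, posterior=None,
            asr_out=None):
    """Rate-through-time series for the consensus run and, when posterior
    maps exist, per-tree curves aligned on a common age axis."""
    if tree is None:
        tree, table, posterior = _load_inputs(config)
    _write_manifest(config, config.outdir, "rtt")
    if asr_out is None:
        asr_out = run_asr(config, tree=tree, table=table, posterior=posterior)
    series = rtt.normalized_transition_series(
        asr_out["consensus_maps"], tree, n_bins=config.n_bins
    )
    _write_series(series, "consensus", os.path.join(config.outdir, "rtt_consensus.tsv"))
    bundle = None
    if asr_out.get("posterior_run") is not None and posterior:
        per_tree = []
        for ti, maps in asr_out["posterior_run"].maps_by_tree:
            per_tree.append(
                rtt.normalized_transition_series(maps, posterior[ti],
                                                 n_bins=config.n_bins)
            )
        bundle = rtt.aggregate_over_posterior(per_tree)
    return {"consensus_series": series, "posterior_bundle": bundle}


def _write_series(series, tree_id, path):
    edges = series.grid.edges
    rows = []
    for i, (a, b) in enumerate(rtt.TRANSITION_TYPES):
        for bi in range(series.grid.n_bins):
            rows.append(dict(
                tree=tree_id, type=f"{STATES[a]}->{STATES[b]}",
                bin_older=edges[bi], bin_younger=edges[bi + 1],
                value=series.values[i, bi],
                branch_length=series.branch_lengths[bi],
            ))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(config: AnalysisConfig, selection=None, asr_out=None,
                 rtt_out=None) -> dict:
    """Machine-readable report over whichever stages completed."""
    report = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "complete": all(x is not None for x in (selection, asr_out, rtt_out)),
        "stages": {},
    }
    if selection is not None:
        report["stages"]["model_selection"] = {
            "table": selection.drop(columns=["error"]).to_dict("records"),
            "chosen_model": chosen_model(selection),
        }
    if asr_out is not None:
        tree = asr_out["consensus_summary"].ref_tree
        modal = asr_out["consensus_summary"].modal_states(config.modal_threshold)
        n_origins, edges = count_post_boundary_arboreal_origins(
            tree, modal, config.boundary_age
        )
        report["stages"]["asr"] = {
            "n_maps": asr_out["consensus_summary"].n_maps,
            "mean_transitions_per_map":
                float(asr_out["consensus_summary"].mean_counts.sum()),
            "post_boundary_arboreal_origins": n_origins,
            "origin_edges": edges,
            "parsimony_length": asr_out["parsimony"].length,
        }
    if rtt_out is not None:
        s = rtt_out["consensus_series"]
        report["stages"]["rtt"] = {
            "n_bins": s.grid.n_bins,
            "bin_width_myr": s.grid.width,
            "total_mean_transitions": float(np.nansum(s.mean_counts)),
        }
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
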