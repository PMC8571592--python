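"""Tree and character-table I/O, node ages, and clade matching.

Trees are stored in a flat array representation (parent pointers, edge
lengths, postorder) built once at parse time; all likelihood and mapping
code indexes into these arrays.  Newick/NEXUS parsing and writing is
delegated to dendropy.

Conventions used throughout the package:

* node indices ``0 .. n_nodes-1``; tips come first (``0 .. n_tips-1``);
* edge lengths in millions of years (Myr);
* node ages measured backward from the present, ``age = root_age - depth``,
  so tips of an ultrametric chronogram sit at age 0 and the root at its
  height in Myr.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "TaxonCharacterTable",
    "NodeMatchTable",
    "NewickParseError",
    "CharacterTableError",
    "parse_tree",
    "parse_trees",
    "read_character_table",
    "match_nodes",
]

#: relative tolerance (fraction of root age) for declaring a tree ultrametric
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a tree string cannot be parsed or lacks branch lengths."""


class CharacterTableError(ValueError):
    """Raised for malformed taxon-state tables."""


@dataclass(frozen=True)
class Tree:
    """Rooted tree with branch lengths, flat-array encoded.

    ``parent[i]`` is the parent index of node ``i`` (-1 for the root),
    ``edge_length[i]`` is the length of the edge above node ``i`` (0 at the
    root).  ``labels[i]`` is the taxon label for tips, ``None`` for internal
    nodes.  ``postorder`` lists every node with children before parents.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    children: tuple
    labels: tuple
    root: int
    postorder: np.ndarray

    # ---- derived structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return sum(1 for c in self.children if not c)

    @property
    def tip_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.children) if not c])

    @property
    def tip_labels(self) -> tuple:
        return tuple(self.labels[i] for i in self.tip_indices)

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    @property
    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, bool)
        mask[self.root] = False
        return float(self.edge_length[mask].sum())

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.edge_length[v]
        return d

    def node_ages(self) -> np.ndarray:
        """Age (Myr before present) of every node: root age minus depth.

        Defined for any tree; tips land at exactly 0 only when the tree is
        ultrametric.
        """
        if np.any(self.edge_length[np.arange(self.n_nodes) != self.root] < 0):
            raise ValueError("negative edge length")
        d = self.depths()
        return d.max() - d

    @property
    def root_age(self) -> float:
        return float(self.depths().max())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        ages = self.node_ages()
        tol = rtol * max(self.root_age, 1.0e-300)
        return bool(np.all(ages[self.tip_indices] <= tol))

    def clade_keys(self) -> dict:
        """Map node index -> frozenset of descendant tip labels."""
        keys = {}
        for v in self.postorder:
            if not self.children[v]:
                keys[v] = frozenset([self.labels[v]])
            else:
                s = frozenset()
                for c in self.children[v]:
                    s = s | keys[c]
                keys[v] = s
        return keys

    # ---- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def rec(v):
            if not self.children[v]:
                lab = self.labels[v] or ""
            else:
                lab = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return lab
            return f"{lab}:{self.edge_length[v]:.12g}"

        return rec(self.root) + ";"

    def _to_dendropy(self, tns=None):
        tns = tns or dendropy.TaxonNamespace()
        dt = dendropy.Tree(taxon_namespace=tns)
        nodes = {self.root: dt.seed_node}
        for v in self.preorder:
            if v != self.root:
                nd = nodes[self.parent[v]].new_child(edge_length=float(self.edge_length[v]))
                nodes[v] = nd
            if not self.children[v]:
                nodes[v].taxon = tns.require_taxon(label=self.labels[v])
        return dt


def _from_dendropy(dtree: dendropy.Tree, require_lengths: bool = True) -> Tree:
    dnodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in dnodes if nd.is_leaf()]
    internals = [nd for nd in dnodes if not nd.is_leaf()]
    index = {}
    for i, nd in enumerate(tips):
        index[id(nd)] = i
    for j, nd in enumerate(internals):
        index[id(nd)] = len(tips) + j

    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    elen = np.zeros(n)
    children = [[] for _ in range(n)]
    labels = [None] * n
    root = index[id(dtree.seed_node)]
    for nd in dnodes:
        v = index[id(nd)]
        if nd.taxon is not None:
            labels[v] = nd.taxon.label
        elif nd.is_leaf() and nd.label is not None:
            labels[v] = nd.label
        if nd.parent_node is not None:
            parent[v] = index[id(nd.parent_node)]
            children[parent[v]].append(v)
            if nd.edge.length is None:
                if require_lengths:
                    raise NewickParseError(
                        f"missing branch length on edge above {labels[v] or 'an internal node'}"
                    )
                elen[v] = 0.0
            else:
                elen[v] = float(nd.edge.length)

    post = [index[id(nd)] for nd in dtree.postorder_node_iter()]
    tip_labels = [labels[i] for i in range(len(tips))]
    if any(l is None for l in tip_labels):
        raise NewickParseError("unlabeled tip in tree")
    if len(set(tip_labels)) != len(tip_labels):
        dup = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
        raise NewickParseError(f"duplicate tip labels: {dup}")
    return Tree(
        parent=parent,
        edge_length=elen,
        children=tuple(tuple(c) for c in children),
        labels=tuple(labels),
        root=root,
        postorder=np.array(post, dtype=np.int64),
    )


def parse_tree(text: str, schema: str = "newick") -> Tree:
    """Parse a single rooted tree with branch lengths from Newick/NEXUS text."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema=schema, suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy error messages carry line/column info
        raise NewickParseError(f"cannot parse {schema} tree: {exc}") from exc
    return _from_dendropy(dtree)


def parse_trees(text: str, schema: str = "newick") -> list:
    """Parse a multi-tree file (e.g. a posterior sample)."""
    try:
        tl = dendropy.TreeList.get(data=text, schema=schema)
    except Exception as exc:
        raise NewickParseError(f"cannot parse {schema} tree list: {exc}") from exc
    return [_from_dendropy(t) for t in tl]


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# ---------------------------------------------------------------------------
# character tables
# ---------------------------------------------------------------------------

#: canonical state vocabulary, in fixed matrix order
STATES = ("arboreal", "semi-arboreal", "nonarboreal")

_STATE_ALIASES = {
    "arboreal": "arboreal",
    "a": "arboreal",
    "semi-arboreal": "semi-arboreal",
    "semiarboreal": "semi-arboreal",
    "semi_arboreal": "semi-arboreal",
    "semi arboreal": "semi-arboreal",
    "s": "semi-arboreal",
    "sa": "semi-arboreal",
    "nonarboreal": "nonarboreal",
    "non-arboreal": "nonarboreal",
    "non_arboreal": "nonarboreal",
    "non arboreal": "nonarboreal",
    "n": "nonarboreal",
}


@dataclass(frozen=True)
class TaxonCharacterTable:
    """Taxon -> substrate-preference state assignments."""

    states: dict  # taxon label -> canonical state string
    notes: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.states)

    def state_index(self, taxon: str) -> int:
        return STATES.index(self.states[taxon])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon": list(self.states), "state": list(self.states.values())}
        )


def normalize_state(raw: str):
    return _STATE_ALIASES.get(str(raw).strip().lower())


def read_character_table(source, rename_map=None) -> TaxonCharacterTable:
    """Read a taxon/state table from a CSV/TSV path, text, or file object.

    The header must name a taxon column and a state column (matched
    case-insensitively; first two columns used as fallback).  States are
    normalized case-insensitively against the three-state vocabulary;
    anything else is rejected with the offending row numbers.
    """
    if isinstance(source, str) and ("\n" in source or "," in source or "\t" in source):
        buf = io.StringIO(source)
    else:
        buf = source
    df = pd.read_csv(buf, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    taxon_col = cols.get("taxon", df.columns[0])
    state_col = cols.get("state", df.columns[1])
    note_col = cols.get("note") or cols.get("source")

    taxa = df[taxon_col].astype(str).str.strip()
    if rename_map:
        taxa = taxa.map(lambda t: rename_map.get(t, t))
    dups = taxa[taxa.duplicated()].unique().tolist()
    if dups:
        raise CharacterTableError(f"duplicate taxa: {dups}")

    states, notes, bad = {}, {}, []
    for i, (taxon, raw) in enumerate(zip(taxa, df[state_col])):
        st = normalize_state(raw)
        if st is None:
            bad.append((i + 2, taxon, raw))  # +2: header line + 1-based
            continue
        states[taxon] = st
        if note_col is not None and pd.notna(df[note_col].iloc[i]):
            notes[taxon] = str(df[note_col].iloc[i])
    if bad:
        msg = "; ".join(f"line {ln}: {t!r} has unknown state {s!r}" for ln, t, s in bad)
        raise CharacterTableError(f"unrecognized character states: {msg}")
    return TaxonCharacterTable(states=states, notes=notes)


def read_rename_map(source) -> dict:
    """Two-column CSV mapping input taxon labels to harmonized labels."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=None, engine="python", header=None)
    return dict(zip(df[0].astype(str).str.strip(), df[1].astype(str).str.strip()))


# ---------------------------------------------------------------------------
# clade matching across trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeMatchTable:
    """Matches of reference internal nodes to phylogenetically equivalent
    nodes (identical descendant leaf sets) in a set of posterior trees."""

    ref_nodes: tuple  # internal node indices of the reference tree
    keys: dict  # ref node -> frozenset of tip labels
    matches: dict  # ref node -> list of (tree index, node index)
    n_trees: int

    def clade_frequency(self, node: int) -> float:
        if self.n_trees == 0:
            return 1.0
        return len(self.matches[node]) / self.n_trees


def match_nodes(ref: Tree, trees) -> NodeMatchTable:
    """Locate, in every posterior tree, the node with the same descendant
    leaf set as each internal node of ``ref``, and report clade frequencies."""
    ref_tips = set(ref.tip_labels)
    ref_keys = ref.clade_keys()
    internal = tuple(int(v) for v in ref.postorder if ref.children[v])
    matches = {v: [] for v in internal}
    for ti, t in enumerate(trees):
        other = set(t.tip_labels)
        if other != ref_tips:
            diff = sorted(other.symmetric_difference(ref_tips))
            raise ValueError(f"tip set mismatch with tree {ti}: {diff}")
        lookup = {}
        for v, key in t.clade_keys().items():
            if t.children[v]:
                lookup[key] = v
        for v in internal:
            m = lookup.get(ref_keys[v])
            if m is not None:
                matches[v].append((ti, m))
    return NodeMatchTable(
        ref_nodes=internal,
        keys={v: ref_keys[v] for v in internal},
        matches=matches,
        n_trees=len(trees),
    )
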