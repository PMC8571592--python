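"""Transition-rate-through-time curves from stochastic maps.

The tree is partitioned into B equal-width time bins spanning
[root age, 0] (ages in Myr before present).  For each of the six ordered
observed-state transition types, the mean number of events per map falling
in a bin is divided by the total branch length present in that bin, giving
events per Myr of lineage.  Bins are half-open ``[older, younger)`` and an
event falling exactly on an interior bin edge belongs to the older bin.

Pure hidden-class switches never enter the six observed-type series; they
are tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simmap import N_OBS, StochasticMap
from .treeio import Tree

__all__ = [
    "TimeBinGrid",
    "TransitionTimeSeries",
    "TRANSITION_TYPES",
    "make_time_bins",
    "branch_length_per_bin",
    "transitions_per_bin",
    "normalized_transition_series",
    "aggregate_over_posterior",
]

#: the six ordered observed-state pairs, indexed (from, to)
TRANSITION_TYPES = tuple(
    (i, j) for i in range(N_OBS) for j in range(N_OBS) if i != j
)


@dataclass(frozen=True)
class TimeBinGrid:
    """B equal-width bins from the root age down to the present."""

    root_age: float
    n_bins: int

    @property
    def width(self) -> float:
        return self.root_age / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        """Bin edges in Myr before present, strictly decreasing."""
        return np.linspace(self.root_age, 0.0, self.n_bins + 1)

    def bin_of(self, age: float) -> int:
        """Bin index for an event age; interior edges go to the older bin."""
        if age < -1e-9 or age > self.root_age * (1 + 1e-9):
            raise ValueError(f"event age {age} outside [0, root age]")
        idx = int(np.ceil((self.root_age - age) / self.width)) - 1
        return min(max(idx, 0), self.n_bins - 1)


def make_time_bins(tree: Tree, n_bins: int, force: bool = False) -> TimeBinGrid:
    """Equal-width grid over the tree's root age.

    Non-ultrametric trees are rejected unless ``force`` is set (ages are
    then measured from the maximum tip depth as usual).
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if not force and not tree.is_ultrametric():
        raise ValueError("tree is not ultrametric; pass force=True to bin anyway")
    return TimeBinGrid(root_age=tree.root_age, n_bins=n_bins)


def branch_length_per_bin(tree: Tree, grid: TimeBinGrid) -> np.ndarray:
    """Myr of lineage present in each bin (edge/bin interval overlaps)."""
    ages = tree.node_ages()
    edges = grid.edges
    older, younger = edges[:-1], edges[1:]
    out = np.zeros(grid.n_bins)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        lo, hi = ages[v], ages[tree.parent[v]]
        out += np.clip(np.minimum(hi, older) - np.maximum(lo, younger), 0.0, None)
    return out


def transitions_per_bin(maps, grid: TimeBinGrid, by_type: bool = True) -> np.ndarray:
    """Mean event counts per bin over maps.

    Returns shape ``(6, B)`` when ``by_type`` (ordered as
    ``TRANSITION_TYPES``) or ``(B,)`` for the all-types total.  Class
    switches are excluded.
    """
    if not maps:
        raise ValueError("no maps")
    type_index = {pair: i for i, pair in enumerate(TRANSITION_TYPES)}
    counts = np.zeros((len(TRANSITION_TYPES), grid.n_bins))
    for smap in maps:
        for a, b, age in smap.event_ages():
            ao, bo = a % N_OBS, b % N_OBS
            if ao == bo:
                continue
            counts[type_index[(ao, bo)], grid.bin_of(age)] += 1
    counts /= len(maps)
    return counts if by_type else counts.sum(axis=0)


@dataclass(frozen=True)
class TransitionTimeSeries:
    """Normalized per-type transition frequencies (events / Myr of lineage).

    ``values[i, b]`` is the series for ``TRANSITION_TYPES[i]`` in bin b;
    bins with zero branch length are NaN (undefined), flagged in
    ``undefined``.  ``total`` sums the six types.
    """

    grid: TimeBinGrid
    values: np.ndarray
    total: np.ndarray
    branch_lengths: np.ndarray
    undefined: np.ndarray
    n_maps: int
    mean_counts: np.ndarray  # (6, B) mean raw counts, for conservation checks


def normalized_transition_series(maps, tree: Tree, n_bins: int = 50,
                                 grid: TimeBinGrid | None = None,
                                 force: bool = False) -> TransitionTimeSeries:
    grid = grid or make_time_bins(tree, n_bins, force=force)
    bl = branch_length_per_bin(tree, grid)
    counts = transitions_per_bin(maps, grid, by_type=True)
    undefined = bl <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = counts / bl[None, :]
    values[:, undefined] = np.nan
    total = values.sum(axis=0)
    return TransitionTimeSeries(
        grid=grid, values=values, total=total, branch_lengths=bl,
        undefined=undefined, n_maps=len(maps), mean_counts=counts,
    )


@dataclass(frozen=True)
class AlignedSeriesBundle:
    """Per-tree curves re-expressed on one absolute-age axis.

    The common grid has the same bin count as the inputs and spans the
    oldest root age; each curve is the piecewise-constant evaluation of its
    own series at the common bin midpoints, NaN beyond the tree's root.
    """

    grid: TimeBinGrid
    curves: np.ndarray  # (n_trees, 6, B)
    totals: np.ndarray  # (n_trees, B)

    def median_curve(self) -> np.ndarray:
        return np.nanmedian(self.curves, axis=0)


def aggregate_over_posterior(series_list) -> AlignedSeriesBundle:
    if not series_list:
        raise ValueError("no series to aggregate")
    bs = {s.grid.n_bins for s in series_list}
    if len(bs) != 1:
        raise ValueError(f"mixed bin counts across trees: {sorted(bs)}")
    b = bs.pop()
    oldest = max(s.grid.root_age for s in series_list)
    common = TimeBinGrid(root_age=oldest, n_bins=b)
    mids = (common.edges[:-1] + common.edges[1:]) / 2.0
    curves = np.full((len(series_list), len(TRANSITION_TYPES), b), np.nan)
    for si, s in enumerate(series_list):
        for bi, mid in enumerate(mids):
            if mid > s.grid.root_age:
                continue
            curves[si, :, bi] = s.values[:, s.grid.bin_of(mid)]
    totals = curves.sum(axis=1)
    return AlignedSeriesBundle(grid=common, curves=curves, totals=totals)
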