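"""Reference-free linkage-group formation.

All Pt markers are clustered at once (r^2 adjacency, TOM distance, average
linkage).  Because the right dendrogram cut is not known a priori, a grid
of static cut heights x minimum cluster sizes is swept on the *same* tree;
the selected grid point is the one producing at least two linkage groups
per chromosome (>= 2 x n_chrom, i.e. one per parent) while maximising the
fraction of markers assigned.  Mis-assigned markers are then removed with
the squared-correlation ``diff`` filter (groups = LGs), and each surviving
LG is phased with a smaller minimum phase size than the synteny path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import (
    AGREE, UNASSIGNED,
    ClusterParams, binary_correlation_matrix, cut_tree_static, diff_filter,
    linkage_tree, phase_linkage_group, tom_distance,
)
from .types import BinaryMarkerMatrix, LinkageGroup

#: static cut heights swept by default
DEFAULT_HEIGHTS = (0.95, 0.9375, 0.925, 0.9125, 0.9, 0.8875, 0.875, 0.8625, 0.85)
#: minimum cluster sizes swept by default
DEFAULT_MIN_SIZES = (50, 100, 150, 200, 250, 300)


@dataclass
class SweepResult:
    grid: pd.DataFrame                  # cut_height, min_cluster_size, n_lgs, fraction_assigned
    selected_height: float | None
    selected_min_size: int | None
    qualified: bool                     # False when no grid point reached 2*n_chrom LGs
    tree: np.ndarray = field(repr=False, default=None)
    marker_ids: list[str] = field(default_factory=list)

    @property
    def selected(self) -> tuple[float, int] | None:
        if self.selected_height is None:
            return None
        return (self.selected_height, self.selected_min_size)


def sweep_and_select(binary: BinaryMarkerMatrix,
                     heights=DEFAULT_HEIGHTS, min_sizes=DEFAULT_MIN_SIZES,
                     n_chrom: int = 19, min_pairs: int = 20) -> SweepResult:
    """Cut one global TOM dendrogram over the parameter grid and select.

    Selection: among points with n_lgs >= 2*n_chrom, maximise the assigned
    fraction; ties prefer the larger minimum size, then the lower height.
    If no point qualifies, the best-effort point (largest n_lgs, then
    assigned fraction) is reported with ``qualified=False``.
    """
    if binary.n_markers < 2:
        raise ValueError("need at least two markers")
    heights, min_sizes = list(heights), list(min_sizes)
    if not heights or not min_sizes:
        raise ValueError("grid must be non-empty")
    corr = binary_correlation_matrix(binary, min_pairs=min_pairs)
    adj = np.nan_to_num(corr.squared(), nan=0.0)
    tree = linkage_tree(tom_distance(adj))

    rows = []
    for h in heights:
        for s in min_sizes:
            labels = cut_tree_static(tree, h, s)
            assigned = labels != UNASSIGNED
            n_lgs = len(set(labels[assigned]))
            rows.append({"cut_height": float(h), "min_cluster_size": int(s),
                         "n_lgs": n_lgs,
                         "fraction_assigned": float(assigned.mean())})
    grid = pd.DataFrame(rows)

    ok = grid[grid["n_lgs"] >= 2 * n_chrom]
    if len(ok):
        pick = ok.sort_values(
            ["fraction_assigned", "min_cluster_size", "cut_height"],
            ascending=[False, False, True]).iloc[0]
        qualified = True
    else:
        warnings.warn("no grid point produced the expected number of linkage groups; "
                      "reporting best effort", stacklevel=2)
        pick = grid.sort_values(["n_lgs", "fraction_assigned"],
                                ascending=[False, False]).iloc[0]
        qualified = False
    return SweepResult(grid=grid, selected_height=float(pick["cut_height"]),
                       selected_min_size=int(pick["min_cluster_size"]),
                       qualified=qualified, tree=tree,
                       marker_ids=binary.marker_ids())


@dataclass
class DenovoResult:
    linkage_groups: list[LinkageGroup]
    sweep: SweepResult
    verdicts: pd.DataFrame
    atypical_lgs: list[str] = field(default_factory=list)   # flagged for manual exclusion
    unphased_lgs: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)        # disagree/unresolved markers


def build_denovo_lgs(binary: BinaryMarkerMatrix, sweep: SweepResult,
                     params: ClusterParams | None = None,
                     min_pairs: int = 20,
                     atypical_r2_floor: float = 0.02) -> DenovoResult:
    """Cut at the selected point, filter mis-assignments, phase each LG.

    LGs whose phasing fails or whose mean within-LG r^2 falls below
    ``atypical_r2_floor`` are reported as atypical (candidates for manual
    exclusion) but still returned.
    """
    if sweep.selected is None:
        raise ValueError("sweep has no selected parameters")
    params = params or ClusterParams(min_phase_size=10)
    labels = cut_tree_static(sweep.tree, sweep.selected_height, sweep.selected_min_size)
    ids = sweep.marker_ids

    groups: dict[str, list[str]] = {}
    assigned: dict[str, str] = {}
    for m, l in zip(ids, labels):
        if l == UNASSIGNED:
            continue
        g = f"LG{l}"
        groups.setdefault(g, []).append(m)
        assigned[m] = g

    member_ids = [m for g in groups.values() for m in g]
    sub = binary.subset_ids(member_ids)
    corr = binary_correlation_matrix(sub, min_pairs=min_pairs)
    verdicts = diff_filter(assigned, groups, corr, diff=params.diff, mode="squared")
    vdf = pd.DataFrame([{"marker": m, "lg": assigned[m], "verdict": v["verdict"]}
                        for m, v in verdicts.items()])
    removed = sorted(vdf.loc[vdf["verdict"] != AGREE, "marker"])

    idx = {m: i for i, m in enumerate(corr.markers)}
    lgs: list[LinkageGroup] = []
    atypical: list[str] = []
    unphased: list[str] = []
    for g, members in groups.items():
        keep = [m for m in members if verdicts[m]["verdict"] == AGREE]
        if len(keep) < 2:
            continue
        lg = LinkageGroup(lg_id=g, markers=keep, provenance="denovo")
        gi = np.array([idx[m] for m in keep])
        block = corr.values[np.ix_(gi, gi)] ** 2
        off = block[~np.eye(len(gi), dtype=bool)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_r2 = float(np.nanmean(off)) if off.size else 0.0
        phase = phase_linkage_group(keep, binary, params, min_pairs=min_pairs)
        if phase is None:
            unphased.append(g)
            atypical.append(g)
        else:
            lg.phase = phase
            if mean_r2 < atypical_r2_floor:
                atypical.append(g)
        lgs.append(lg)
    return DenovoResult(linkage_groups=lgs, sweep=sweep, verdicts=vdf,
                        atypical_lgs=sorted(set(atypical)), unphased_lgs=unphased,
                        removed=removed)
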