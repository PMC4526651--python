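"""Linkage-group machinery shared by the reference-guided and de novo paths.

Markers segregating from the same parent on the same chromosome are
correlated in progeny through their shared meiosis: positively within a
phase (coupling), negatively across phases (repulsion).  Squaring the
correlation makes both appear as adjacency; the topological overlap measure
(TOM) then rewards markers that share neighbours, and average-linkage
hierarchical clustering of 1 - TOM with a static dendrogram cut yields
linkage groups.  Phasing repeats the procedure inside each group with the
signed correlation truncated at zero, so only coupling-phase markers
attract each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import MISSING, BinaryMarkerMatrix

UNASSIGNED = -1


@dataclass
class ClusterParams:
    """Static-cut clustering parameters (average linkage throughout)."""

    cut_height: float = 0.9
    min_cluster_size: int = 30
    diff: float = 2.0            # best/second mean-correlation ratio to accept
    phase_cut_height: float = 0.9
    min_phase_size: int = 30     # 30 for the reference-guided path, 10 de novo

    def __post_init__(self) -> None:
        if not 0 < self.cut_height < 1:
            raise ValueError("cut_height must be in (0, 1)")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r over pairwise-complete progeny, with pair counts."""

    markers: list[str]
    values: np.ndarray   # symmetric, diagonal 1, NaN where undefined/too few pairs
    n_obs: np.ndarray

    def squared(self) -> np.ndarray:
        return self.values ** 2


def binary_correlation_matrix(binary: BinaryMarkerMatrix, min_pairs: int = 20
                              ) -> CorrelationMatrix:
    """Pearson correlation between 0/1 marker rows, pairwise-complete.

    Entries backed by fewer than ``min_pairs`` complete pairs, or involving
    a constant vector, are NaN.  The diagonal is 1 wherever defined.
    """
    if binary.n_markers < 2:
        raise ValueError("need at least two markers")
    V = binary.values.astype(float)
    M = (binary.values != MISSING).astype(float)
    X = np.where(binary.values == MISSING, 0.0, V)

    n = M @ M.T
    sx = X @ M.T          # sum of x over pairwise-complete, rows=x
    sy = sx.T
    sxy = X @ X.T
    sxx = (X * X) @ M.T   # = sx for 0/1 data, kept general
    syy = sxx.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx ** 2
        vary = n * syy - sy ** 2
        r = cov / np.sqrt(varx * vary)
    r[(varx <= 0) | (vary <= 0)] = np.nan
    r[n < min_pairs] = np.nan
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(r, np.where(np.diag(n) >= min_pairs, 1.0, np.nan))
    return CorrelationMatrix(markers=binary.marker_ids(), values=r,
                             n_obs=n.astype(int))


def tom_distance(adjacency: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity 1 - TOM of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    connectivity k_i = sum_{u != i} a_iu; self-adjacency is excluded.  The
    result is symmetric with a zero diagonal.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if np.nanmin(A) < -1e-12 or np.nanmax(A) > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    A = np.clip(np.nan_to_num(A, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    return dist


def linkage_tree(distance: np.ndarray) -> np.ndarray:
    """Average-linkage tree of a symmetric distance matrix."""
    D = np.asarray(distance, dtype=float)
    return linkage(squareform(D, checks=False), method="average")


def cut_tree_static(tree: np.ndarray, cut_height: float, min_cluster_size: int
                    ) -> np.ndarray:
    """Static dendrogram cut; groups below the minimum size become UNASSIGNED.

    Surviving clusters are renumbered 0.. in order of first appearance so
    labels are deterministic given the input order.
    """
    raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = np.full(raw.shape, UNASSIGNED, dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    counts = np.bincount(raw)
    for i, c in enumerate(raw):
        if counts[c] < min_cluster_size:
            continue
        if c not in seen:
            seen[c] = next_id
            next_id += 1
        labels[i] = seen[c]
    return labels


def cluster_static_cut(distance: np.ndarray, params: ClusterParams) -> np.ndarray:
    """Average-linkage clustering with a static cut (labels, -1 = unassigned)."""
    labels = cut_tree_static(linkage_tree(distance), params.cut_height,
                             params.min_cluster_size)
    if (labels == UNASSIGNED).all():
        warnings.warn("static cut left every marker unassigned", stacklevel=2)
    return labels


# ---------------------------------------------------------------------------
# "diff" mis-assignment filter

AGREE, DISAGREE, UNRESOLVED = "agree", "disagree", "unresolved"


def diff_filter(assigned: dict[str, str], groups: dict[str, list[str]],
                correlation: CorrelationMatrix, diff: float = 2.0,
                mode: str = "squared") -> dict[str, dict]:
    """Rank each query marker's mean correlation against candidate groups.

    Verdicts: ``agree`` if the assigned group ranks first and its mean is at
    least ``diff`` times the runner-up mean; ``disagree`` if the assigned
    group does not rank first; ``unresolved`` otherwise.  ``mode`` selects
    r^2 ("squared", used for group assignment) or signed r ("signed").
    Empty groups are excluded from the ranking.
    """
    if mode not in ("squared", "signed"):
        raise ValueError("mode must be 'squared' or 'signed'")
    vals = correlation.squared() if mode == "squared" else correlation.values
    index = {m: i for i, m in enumerate(correlation.markers)}
    group_idx = {g: np.array([index[m] for m in members], dtype=int)
                 for g, members in groups.items() if members}

    out: dict[str, dict] = {}
    for marker, own in assigned.items():
        qi = index[marker]
        means: dict[str, float] = {}
        for g, gi in group_idx.items():
            gi_not_self = gi[gi != qi]
            if gi_not_self.size == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                m = np.nanmean(vals[qi, gi_not_self])
            if np.isfinite(m):
                means[g] = float(m)
        if own not in means or len(means) == 0:
            out[marker] = {"verdict": UNRESOLVED, "means": means,
                           "best": None, "second": None}
            continue
        ranked = sorted(means.items(), key=lambda kv: -kv[1])
        best_g, best_v = ranked[0]
        second_v = ranked[1][1] if len(ranked) > 1 else 0.0
        if best_g != own:
            verdict = DISAGREE
        elif best_v >= diff * second_v:
            verdict = AGREE
        else:
            verdict = UNRESOLVED
        out[marker] = {"verdict": verdict, "means": means,
                       "best": best_v, "second": second_v}
    return out


# ---------------------------------------------------------------------------
# phasing


def phase_linkage_group(lg_markers: list[str], binary: BinaryMarkerMatrix,
                        params: ClusterParams, min_pairs: int = 20
                        ) -> dict[str, int] | None:
    """Split a linkage group into its two coupling phases.

    Adjacency is the signed marker correlation truncated at zero (markers of
    the same phase are positively correlated, opposite phases negatively),
    then TOM distance + static cut.  The two largest clusters become phases
    0 and 1; any extra clustered markers are left out with a warning.
    Returns ``None`` (unphased) when fewer than two clusters emerge.
    """
    sub = binary.subset_ids(lg_markers)
    corr = binary_correlation_matrix(sub, min_pairs=min_pairs)
    adj = np.clip(np.nan_to_num(corr.values, nan=0.0), 0.0, 1.0)
    dist = tom_distance(adj)
    labels = cut_tree_static(linkage_tree(dist), params.phase_cut_height,
                             params.min_phase_size)
    uniq = [c for c in dict.fromkeys(labels[labels != UNASSIGNED])]
    if len(uniq) < 2:
        return None
    sizes = {c: int((labels == c).sum()) for c in uniq}
    top2 = sorted(uniq, key=lambda c: (-sizes[c], c))[:2]
    if len(uniq) > 2:
        warnings.warn(
            f"{len(uniq)} phase clusters found; keeping the two largest", stacklevel=2)
    phase: dict[str, int] = {}
    for m, c in zip(lg_markers, labels):
        if c == top2[0]:
            phase[m] = 0
        elif c == top2[1]:
            phase[m] = 1
    return phase
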