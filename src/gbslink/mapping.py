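"""Map assembly: LG standardisation, split-LG joining, MST marker ordering,
redundancy/double-crossover filtering, Kosambi distances.

Once a linkage group is phased, complementing the binary rows of phase-1
markers makes every row measure inheritance of the *same* parental
haplotype, so the F1 data behave exactly like a backcross/DH population:
the recombination fraction between two markers is simply the discordance
rate among progeny informative for both.  Ordering builds a minimum
spanning tree of the rf-weighted complete graph, takes its longest path as
a backbone, inserts the remaining markers where they least inflate the
map, and polishes with an exhaustive sliding-window permutation search
minimising obligate crossovers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .types import MISSING, BinaryMarkerMatrix, GeneticMap, LinkageGroup

# ---------------------------------------------------------------------------
# Kosambi map function


def kosambi(rf, max_cM: float = 50.0):
    """Kosambi distance d = 25 ln((1+2r)/(1-2r)) in cM.

    rf >= 0.5 is capped at ``max_cM`` with a warning; negative rf raises.
    """
    r = np.asarray(rf, dtype=float)
    if (r < 0).any():
        raise ValueError("recombination fractions must be >= 0")
    capped = r >= 0.5
    if capped.any():
        warnings.warn("rf >= 0.5 capped at max_cM", stacklevel=2)
    rr = np.where(capped, 0.0, r)
    d = 25.0 * np.log((1.0 + 2.0 * rr) / (1.0 - 2.0 * rr))
    d = np.where(capped, max_cM, d)
    return float(d) if np.isscalar(rf) else d


def kosambi_inverse(d):
    """Inverse of the Kosambi function: r = tanh(d/50) / 2."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# phase encoding and two-point statistics


def phase_encode(lg: LinkageGroup, binary: BinaryMarkerMatrix) -> np.ndarray:
    """Rows of the LG's markers recoded so 1 = phase-0 haplotype inherited.

    Phase-1 markers are complemented; markers without a phase are dropped
    by callers beforehand (raises here if encountered).
    """
    sub = binary.subset_ids(lg.markers)
    X = sub.values.copy()
    for i, m in enumerate(lg.markers):
        if m not in lg.phase:
            raise ValueError(f"marker {m} has no phase in LG {lg.lg_id}")
        if lg.phase[m] == 1:
            row = X[i]
            X[i] = np.where(row == MISSING, MISSING, 1 - row)
    return X


@dataclass
class TwoPointStats:
    """Pairwise recombination fractions, LODs and informative counts."""

    markers: list[str]
    rf: np.ndarray          # in [0, 0.5], NaN when too few informative pairs
    lod: np.ndarray
    n_informative: np.ndarray
    discordant: np.ndarray  # raw discordance counts (ripple objective)


def pairwise_rf(X: np.ndarray, markers: list[str] | None = None,
                min_pairs: int = 20) -> TwoPointStats:
    """Backcross two-point estimates from phase-encoded rows.

    rf = discordant / informative (capped at 0.5); the two-point LOD is
    R log10(2 rf) + (n-R) log10(2 (1-rf)), which reduces to n log10 2 at
    rf = 0 and to 0 at rf = 0.5.
    """
    M = (X != MISSING)
    A = ((X == 1) & M).astype(float)
    B = ((X == 0) & M).astype(float)
    Mf = M.astype(float)
    n = Mf @ Mf.T
    R = A @ B.T + B @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        rf = np.where(n > 0, R / n, np.nan)
    rf = np.minimum(rf, 0.5)
    rhat = np.clip(rf, 1e-12, 0.5)
    with np.errstate(invalid="ignore", divide="ignore"):
        lod = np.where(rf >= 0.5, 0.0,
                       np.where(R > 0, R * np.log10(2 * rhat), 0.0)
                       + (n - R) * np.log10(2 * (1 - rhat)))
    lod = np.maximum(lod, 0.0)
    rf[n < min_pairs] = np.nan
    lod[n < min_pairs] = np.nan
    np.fill_diagonal(rf, 0.0)
    ids = markers if markers is not None else [str(i) for i in range(X.shape[0])]
    return TwoPointStats(markers=list(ids), rf=rf, lod=lod,
                         n_informative=n.astype(int), discordant=R.astype(int))


# ---------------------------------------------------------------------------
# ordering


def _tree_longest_path(T: nx.Graph) -> list:
    """Weighted longest (heaviest) path through a tree via two sweeps."""
    start = next(iter(T.nodes))
    dist = nx.single_source_dijkstra_path_length(T, start)
    a = max(dist, key=dist.get)
    dist, paths = nx.single_source_dijkstra(T, a)
    b = max(dist, key=dist.get)
    return paths[b]


def _order_cost(order: list[int], D: np.ndarray) -> float:
    o = np.asarray(order)
    return float(D[o[:-1], o[1:]].sum())


def _relocation_pass(order: list[int], D: np.ndarray) -> bool:
    """Move single markers to their globally best position (Or-opt).

    Catches misplacements beyond the reach of the sliding window.  Returns
    True when any move improved the objective.
    """
    n = len(order)
    improved = False
    for _ in range(n):
        moved = False
        for i in range(n):
            u = order[i]
            rest = order[:i] + order[i + 1:]
            gain = 0.0                      # cost removed with u's adjacencies
            if i > 0:
                gain += D[order[i - 1], u]
            if i < n - 1:
                gain += D[u, order[i + 1]]
            if 0 < i < n - 1:
                gain -= D[order[i - 1], order[i + 1]]
            best_pos, best_cost = None, np.inf
            for pos in range(len(rest) + 1):
                left = rest[pos - 1] if pos > 0 else None
                right = rest[pos] if pos < len(rest) else None
                cost = 0.0
                if left is not None:
                    cost += D[left, u]
                if right is not None:
                    cost += D[u, right]
                if left is not None and right is not None:
                    cost -= D[left, right]
                if cost < best_cost:
                    best_pos, best_cost = pos, cost
            if best_cost < gain - 1e-9 and best_pos != i:
                rest.insert(best_pos, u)
                order[:] = rest
                moved = improved = True
                break
        if not moved:
            break
    return improved


def polish_order(order: list[int], D: np.ndarray, window: int = 5,
                 max_passes: int = 8) -> list[int]:
    """Sliding-window exhaustive permutation minimising obligate crossovers.

    D is the pairwise discordance-count matrix; the objective is the sum of
    D over adjacent pairs.  Each pass sweeps every window position trying
    all permutations of the window, then relocates single markers to their
    globally best position; ties keep the incumbent order (deterministic)
    and passes repeat until nothing improves.
    """
    order = list(order)
    n = len(order)
    if n <= 2:
        return order
    w = min(window, n)
    perms = list(itertools.permutations(range(w)))
    for _ in range(max_passes):
        improved = False
        for start in range(0, n - w + 1):
            seg = order[start:start + w]
            left = order[start - 1] if start > 0 else None
            right = order[start + w] if start + w < n else None

            def seg_cost(p):
                c = sum(D[seg[p[i]], seg[p[i + 1]]] for i in range(w - 1))
                if left is not None:
                    c += D[left, seg[p[0]]]
                if right is not None:
                    c += D[seg[p[-1]], right]
                return c

            base = seg_cost(tuple(range(w)))
            best_p, best_c = tuple(range(w)), base
            for p in perms:
                c = seg_cost(p)
                if c < best_c - 1e-12:
                    best_p, best_c = p, c
            if best_p != tuple(range(w)):
                order[start:start + w] = [seg[i] for i in best_p]
                improved = True
        if _relocation_pass(order, D):
            improved = True
        if not improved:
            break
    return order


def order_markers_mst(stats: TwoPointStats, window: int = 5,
                      missing_threshold: float = 0.5,
                      fragment_max_rf: float = 0.4, fragment_min_size: int = 5
                      ) -> tuple[list[str], list[str]]:
    """MST backbone + greedy insertion + windowed polish.

    Returns (ordered marker ids, set-aside marker ids).  Markers in graph
    components (edges with rf < ``fragment_max_rf``) smaller than
    ``fragment_min_size`` are split off as unlinked fragments; missing rf
    entries count as 0.5 (unlinked).  Orientation of the result is
    arbitrary.
    """
    m = len(stats.markers)
    if m < 3:
        return list(stats.markers), []
    rf = np.where(np.isnan(stats.rf), 0.5, stats.rf)

    linked = nx.Graph()
    linked.add_nodes_from(range(m))
    ii, jj = np.where(np.triu(rf < fragment_max_rf, k=1))
    linked.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = sorted(nx.connected_components(linked), key=len, reverse=True)
    keep = sorted(comps[0])
    dropped = sorted(set(range(m)) - set(keep))
    if dropped:
        n_big = sum(1 for c in comps[1:] if len(c) >= fragment_min_size)
        msg = (f"{len(dropped)} marker(s) split off"
               + (f" ({n_big} secondary linked component(s))" if n_big else
                  " as unlinked fragments"))
        warnings.warn(msg, stacklevel=2)

    idx = np.array(keep)
    sub_rf = rf[np.ix_(idx, idx)]
    G = nx.Graph()
    k = len(idx)
    for i in range(k):
        for j in range(i + 1, k):
            G.add_edge(i, j, weight=float(sub_rf[i, j]))
    T = nx.minimum_spanning_tree(G, weight="weight")
    backbone = _tree_longest_path(T)

    order = list(backbone)
    remaining = [i for i in range(k) if i not in set(backbone)]
    # closest to the current order first, then cheapest-insertion
    remaining.sort(key=lambda u: float(np.min(sub_rf[u, order])))
    for u in remaining:
        best_pos, best_delta = 0, np.inf
        for pos in range(len(order) + 1):
            left = order[pos - 1] if pos > 0 else None
            right = order[pos] if pos < len(order) else None
            delta = 0.0
            if left is not None:
                delta += sub_rf[left, u]
            if right is not None:
                delta += sub_rf[u, right]
            if left is not None and right is not None:
                delta -= sub_rf[left, right]
            if delta < best_delta - 1e-12:
                best_pos, best_delta = pos, delta
        order.insert(best_pos, u)

    D = np.asarray(stats.discordant, dtype=float)[np.ix_(idx, idx)]
    order = polish_order(order, D, window=window)
    ordered = [stats.markers[idx[i]] for i in order]
    set_aside = [stats.markers[i] for i in dropped]
    return ordered, set_aside


# ---------------------------------------------------------------------------
# post-ordering marker filter


def filter_ordered_markers(ordered: list[str], X: np.ndarray, markers: list[str],
                           min_pairs: int = 20, dxo_max: float = 0.2
                           ) -> tuple[list[str], pd.DataFrame]:
    """Collapse co-segregating bins and drop double-crossover markers.

    Within a run of adjacent markers with zero observed recombination the
    marker with the fewest missing calls is kept.  A marker whose flanking
    neighbours agree with each other while it disagrees, in more than
    ``dxo_max`` of the progeny informative for all three, is removed.
    """
    pos = {m: i for i, m in enumerate(markers)}
    rows = X[[pos[m] for m in ordered]]
    n_missing = (rows == MISSING).sum(axis=1)

    removals = []
    # 1. redundancy bins (adjacent discordance 0 over pairwise-complete progeny)
    keep_idx = []
    bin_start = 0
    i = 0
    nm = len(ordered)

    def discord(a, b):
        ok = (rows[a] != MISSING) & (rows[b] != MISSING)
        return int((rows[a][ok] != rows[b][ok]).sum()), int(ok.sum())

    while i < nm:
        j = i
        while j + 1 < nm:
            d, n = discord(j, j + 1)
            if n > 0 and d == 0:
                j += 1
            else:
                break
        group = list(range(i, j + 1))
        best = min(group, key=lambda g: (n_missing[g], g))
        keep_idx.append(best)
        for g in group:
            if g != best:
                removals.append({"marker": ordered[g], "reason": "redundant",
                                 "kept": ordered[best]})
        i = j + 1

    # 2. double-crossover filter on the collapsed order
    surviving = []
    for t, g in enumerate(keep_idx):
        if t == 0 or t == len(keep_idx) - 1:
            surviving.append(g)
            continue
        l, r = keep_idx[t - 1], keep_idx[t + 1]
        ok = (rows[l] != MISSING) & (rows[g] != MISSING) & (rows[r] != MISSING)
        n = int(ok.sum())
        if n == 0:
            surviving.append(g)
            continue
        dxo = int(((rows[l][ok] == rows[r][ok]) & (rows[g][ok] != rows[l][ok])).sum())
        if dxo / n > dxo_max:
            removals.append({"marker": ordered[g], "reason": "double_crossover",
                             "kept": ""})
        else:
            surviving.append(g)
    retained = [ordered[g] for g in surviving]
    return retained, pd.DataFrame(removals, columns=["marker", "reason", "kept"])


# ---------------------------------------------------------------------------
# parent assignment, naming, split-LG joining


def assign_parent_and_name(lgs: list[LinkageGroup],
                           progenitors: pd.DataFrame | None,
                           sites: pd.DataFrame) -> list[LinkageGroup]:
    """Attribute each LG to a parent and rename to community standards.

    With parental genotypes: the LG belongs to the parent whose high-quality
    calls at the LG's markers are majority-heterozygous (ties -> unknown).
    Without: parents are labelled unknown-A / unknown-B, consistently within
    each chromosome label.  Female LGs are numbered 1..19 and male LGs
    20..38 when chromosome labels are numeric.
    """
    site_chrom = dict(zip(sites["site_id"], sites["chrom"].astype(str)))
    have_parents = (progenitors is not None and len(progenitors.columns) >= 2
                    and {"mother", "father"} <= set(progenitors.columns))

    out: list[LinkageGroup] = []
    per_chrom_counter: dict[str, int] = {}
    for lg in lgs:
        chroms = pd.Series([site_chrom.get(m, "") for m in lg.markers])
        chrom_label = lg.chrom_label or (chroms.mode().iloc[0] if len(chroms) else "")
        parent = "unknown"
        if have_parents:
            sub = progenitors.reindex(lg.markers)
            het_m = (sub["mother"] == "AB").sum()
            hom_m = (sub["mother"] == "AA").sum() + (sub["mother"] == "BB").sum()
            het_f = (sub["father"] == "AB").sum()
            hom_f = (sub["father"] == "AA").sum() + (sub["father"] == "BB").sum()
            mother_het = het_m > hom_m
            father_het = het_f > hom_f
            if mother_het and not father_het:
                parent = "female"
            elif father_het and not mother_het:
                parent = "male"
            else:
                warnings.warn(f"LG {lg.lg_id}: parent assignment tie; left unknown",
                              stacklevel=2)
        else:
            k = per_chrom_counter.get(chrom_label, 0)
            parent = "unknown-A" if k % 2 == 0 else "unknown-B"
            per_chrom_counter[chrom_label] = k + 1
        new = LinkageGroup(lg_id=lg.lg_id, markers=list(lg.markers),
                           phase=dict(lg.phase), parent=parent,
                           chrom_label=str(chrom_label), provenance=lg.provenance)
        out.append(new)

    for lg in out:
        try:
            c = int(lg.chrom_label)
        except (TypeError, ValueError):
            continue
        if lg.parent == "female":
            lg.lg_id = str(c)
        elif lg.parent == "male":
            lg.lg_id = str(c + 19)
    return out


def _ordered_length(lg: LinkageGroup, binary: BinaryMarkerMatrix,
                    min_pairs: int = 20) -> tuple[float, list[str]]:
    # no fragment pruning: a candidate merge must be measured over its full
    # marker set, otherwise a repulsion-phase junction (rf ~ 0.5) would let
    # half the markers drop and the wrong orientation look artificially short
    X = phase_encode(lg, binary)
    stats = pairwise_rf(X, lg.markers, min_pairs=min_pairs)
    ordered, _ = order_markers_mst(stats, fragment_max_rf=2.0)
    idx = {m: i for i, m in enumerate(lg.markers)}
    rf = np.where(np.isnan(stats.rf), 0.5, stats.rf)
    adj = [rf[idx[a], idx[b]] for a, b in zip(ordered[:-1], ordered[1:])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        length = float(np.sum(kosambi(np.array(adj)))) if adj else 0.0
    return length, ordered


def join_split_lgs(lg_a: LinkageGroup, lg_b: LinkageGroup,
                   binary: BinaryMarkerMatrix, min_pairs: int = 20,
                   expansion_cap_cM: float = 200.0
                   ) -> tuple[LinkageGroup | None, dict]:
    """Merge two split LGs, testing both relative phase orientations.

    The two candidate merges (phases aligned vs. flipped for lg_b) are each
    ordered and measured; the shorter total Kosambi length wins — joining
    in repulsion inflates the map.  Returns (joined LG or None, report with
    both candidate lengths).
    """
    if lg_a is lg_b or set(lg_a.markers) == set(lg_b.markers):
        raise ValueError("cannot join a linkage group with itself")
    if not (lg_a.phased and lg_b.phased):
        raise ValueError("both linkage groups must be phased before joining")

    candidates = {}
    for flip in (False, True):
        phase_b = {m: (1 - p if flip else p) for m, p in lg_b.phase.items()}
        merged = LinkageGroup(
            lg_id=f"{lg_a.lg_id}+{lg_b.lg_id}" + ("~flip" if flip else ""),
            markers=[m for m in lg_a.markers if m in lg_a.phase]
                    + [m for m in lg_b.markers if m in phase_b],
            phase={**{m: p for m, p in lg_a.phase.items()}, **phase_b},
            parent=lg_a.parent, chrom_label=lg_a.chrom_label,
            provenance=lg_a.provenance)
        length, ordered = _ordered_length(merged, binary, min_pairs)
        candidates[flip] = (length, merged, ordered)

    best_flip = min(candidates, key=lambda f: candidates[f][0])
    length, merged, ordered = candidates[best_flip]
    report = {"aligned_cM": candidates[False][0], "flipped_cM": candidates[True][0],
              "chosen": "flipped" if best_flip else "aligned", "joined_cM": length}
    len_a, _ = _ordered_length(lg_a, binary, min_pairs)
    len_b, _ = _ordered_length(lg_b, binary, min_pairs)
    report["separate_cM"] = len_a + len_b
    if length > len_a + len_b + expansion_cap_cM:
        warnings.warn("join rejected: merged map implausibly long", stacklevel=2)
        return None, report
    merged.lg_id = f"{lg_a.lg_id}+{lg_b.lg_id}"
    merged.markers = ordered
    return merged, report


# ---------------------------------------------------------------------------
# map construction


def build_genetic_map(lgs: list[LinkageGroup], binary: BinaryMarkerMatrix,
                      min_pairs: int = 20, window: int = 5,
                      apply_filter: bool = True) -> tuple[GeneticMap, pd.DataFrame]:
    """Order and measure every LG; returns the map and the removal report."""
    site_info = binary.markers.set_index("site_id")
    rows = []
    removals = []
    for lg in lgs:
        phased = [m for m in lg.markers if m in lg.phase]
        if len(phased) < 3:
            continue
        work = LinkageGroup(lg_id=lg.lg_id, markers=phased, phase=lg.phase,
                            parent=lg.parent, chrom_label=lg.chrom_label,
                            provenance=lg.provenance)
        X = phase_encode(work, binary)
        miss_frac = (X == MISSING).mean(axis=1)
        usable = miss_frac <= 0.5
        phased = [m for m, u in zip(phased, usable) if u]
        X = X[usable]
        if len(phased) < 3:
            continue
        stats = pairwise_rf(X, phased, min_pairs=min_pairs)
        ordered, aside = order_markers_mst(stats, window=window)
        if apply_filter:
            ordered, rep = filter_ordered_markers(ordered, X, phased,
                                                  min_pairs=min_pairs)
            if len(rep):
                rep.insert(0, "lg", lg.lg_id)
                removals.append(rep)
            # re-order the retained set once
            keep_pos = [phased.index(m) for m in ordered]
            stats2 = pairwise_rf(X[keep_pos], ordered, min_pairs=min_pairs)
            ordered, _ = order_markers_mst(stats2, window=window)

        idx = {m: i for i, m in enumerate(phased)}
        rf = np.where(np.isnan(stats.rf), 0.5, stats.rf)
        adj = np.array([rf[idx[a], idx[b]]
                        for a, b in zip(ordered[:-1], ordered[1:])])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = np.concatenate([[0.0], np.cumsum(kosambi(adj))]) if len(ordered) > 1 \
                else np.array([0.0])
        Xrows = X[[idx[m] for m in ordered]]
        for m, c, xr in zip(ordered, cm, Xrows):
            info = site_info.loc[m]
            rows.append({"marker": m, "lg": lg.lg_id, "parent": lg.parent,
                         "phase": lg.phase[m], "cM": float(c),
                         "chrom": str(info["chrom"]), "pos": int(info["pos"]),
                         "n_missing": int((xr == MISSING).sum())})
    table = pd.DataFrame(rows, columns=["marker", "lg", "parent", "phase", "cM",
                                        "chrom", "pos", "n_missing"])
    removal_report = (pd.concat(removals, ignore_index=True)
                      if removals else pd.DataFrame(columns=["lg", "marker", "reason", "kept"]))
    return GeneticMap(table=table), removal_report
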