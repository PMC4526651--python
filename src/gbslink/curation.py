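"""Five-step genetic-map curation.

Raw GBS maps are inflated: residual genotyping errors look like double
crossovers and stretch every interval.  Curation (per parental map)

1. removes markers with >= 50% missing data and individuals with > 50%
   missing genotypes or more than twice the family-mean crossover count;
2. screens marker order with rf/LOD diagnostics and re-polishes flagged
   segments;
3. estimates the genotyping error rate per linkage group with a two-state
   (phase) hidden Markov model, maximising the log-likelihood over an
   error grid, and re-estimates inter-marker recombination fractions at
   the chosen error rate (EM updates), which deflates distances;
4. scans the effect of dropping one marker at a time in a sliding window
   of nine markers, removing markers that shorten the window by > 2 cM
   with a LOD difference above threshold (default: the 95th percentile of
   the map's drop-one LOD-difference distribution);
5. flags gaps > 2 cM, ripples with a window of seven markers, orients each
   LG along physical coordinates and recomputes Kosambi distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import kosambi, pairwise_rf, polish_order
from .types import MISSING, BinaryMarkerMatrix, GeneticMap, LinkageGroup

# ---------------------------------------------------------------------------
# parameters / report


@dataclass
class CurationParams:
    marker_missing_max: float = 0.5      # >= this fraction missing -> marker removed
    individual_missing_max: float = 0.5  # > this fraction missing -> individual removed
    crossover_multiple: float = 2.0      # > multiple x family mean -> individual removed
    rf_flag: float = 0.4                 # adjacent rf above this flags a segment
    lod_flag: float = 1.0                # adjacent LOD below this flags a segment
    dropone_window: int = 9
    gap_max_cM: float = 2.0
    ripple_window: int = 7
    error_prob_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-4, 0.2, 25))
    lod_diff_threshold: float | None = None   # None -> 95th percentile of the scan
    lod_diff_quantile: float = 0.95
    dropone_min_cM: float = 2.0
    em_iterations: int = 10

    def __post_init__(self) -> None:
        if self.dropone_window % 2 == 0 or self.ripple_window % 2 == 0:
            raise ValueError("scan windows must be odd")
        g = np.asarray(self.error_prob_grid)
        if (g <= 0).any() or (g >= 0.5).any():
            raise ValueError("error grid must lie in (0, 0.5)")


@dataclass
class CurationReport:
    stages: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_markers: dict = field(default_factory=dict)     # step -> list
    removed_individuals: list = field(default_factory=list)
    error_rates: dict = field(default_factory=dict)         # lg -> eps_hat
    dropone_lod_diffs: pd.DataFrame = field(default_factory=pd.DataFrame)
    gap_flags: pd.DataFrame = field(default_factory=pd.DataFrame)
    flagged_segments: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# phase HMM


def hmm_forward_loglik(X: np.ndarray, rf: np.ndarray, eps: float) -> float:
    """Total forward log-likelihood of phase-encoded rows for one LG.

    X is (markers x progeny) with values 0/1/MISSING in map order; rf the
    recombination fraction of each of the m-1 adjacent intervals.  Hidden
    phase follows a two-state Markov chain (switch probability rf per
    interval, uniform start); the observation equals the hidden phase with
    probability 1 - eps and flips with eps; MISSING emits probability 1.
    """
    m, n = X.shape
    if len(rf) != m - 1:
        raise ValueError("need one rf per adjacent interval")

    def emit(i):
        x = X[i]
        e0 = np.where(x == MISSING, 1.0, np.where(x == 0, 1.0 - eps, eps))
        e1 = np.where(x == MISSING, 1.0, np.where(x == 1, 1.0 - eps, eps))
        return e0, e1

    e0, e1 = emit(0)
    a0, a1 = 0.5 * e0, 0.5 * e1
    ll = np.zeros(n)
    c = a0 + a1
    ll += np.log(c)
    a0, a1 = a0 / c, a1 / c
    for j in range(m - 1):
        r = rf[j]
        e0, e1 = emit(j + 1)
        b0 = (a0 * (1 - r) + a1 * r) * e0
        b1 = (a0 * r + a1 * (1 - r)) * e1
        c = b0 + b1
        ll += np.log(c)
        a0, a1 = b0 / c, b1 / c
    return float(ll.sum())


def _hmm_em_rf(X: np.ndarray, rf: np.ndarray, eps: float,
               iterations: int = 10, tol: float = 1e-4) -> np.ndarray:
    """EM re-estimation of interval rf at fixed error rate."""
    m, n = X.shape
    rf = np.clip(np.asarray(rf, dtype=float).copy(), 1e-5, 0.49)

    def emissions():
        E0 = np.where(X == MISSING, 1.0, np.where(X == 0, 1.0 - eps, eps))
        E1 = np.where(X == MISSING, 1.0, np.where(X == 1, 1.0 - eps, eps))
        return E0, E1

    E0, E1 = emissions()
    for _ in range(iterations):
        # forward (scaled)
        A0 = np.empty((m, n)); A1 = np.empty((m, n))
        C = np.empty((m, n))
        a0, a1 = 0.5 * E0[0], 0.5 * E1[0]
        c = a0 + a1
        A0[0], A1[0], C[0] = a0 / c, a1 / c, c
        for j in range(m - 1):
            r = rf[j]
            b0 = (A0[j] * (1 - r) + A1[j] * r) * E0[j + 1]
            b1 = (A0[j] * r + A1[j] * (1 - r)) * E1[j + 1]
            c = b0 + b1
            A0[j + 1], A1[j + 1], C[j + 1] = b0 / c, b1 / c, c
        # backward (scaled)
        B0 = np.empty((m, n)); B1 = np.empty((m, n))
        B0[-1] = B1[-1] = 1.0
        for j in range(m - 2, -1, -1):
            r = rf[j]
            t0 = E0[j + 1] * B0[j + 1]
            t1 = E1[j + 1] * B1[j + 1]
            B0[j] = ((1 - r) * t0 + r * t1) / C[j + 1]
            B1[j] = (r * t0 + (1 - r) * t1) / C[j + 1]
        new_rf = rf.copy()
        for j in range(m - 1):
            r = rf[j]
            t0 = E0[j + 1] * B0[j + 1]
            t1 = E1[j + 1] * B1[j + 1]
            x01 = A0[j] * r * t1 / C[j + 1]
            x10 = A1[j] * r * t0 / C[j + 1]
            x00 = A0[j] * (1 - r) * t0 / C[j + 1]
            x11 = A1[j] * (1 - r) * t1 / C[j + 1]
            tot = x00 + x01 + x10 + x11
            with np.errstate(invalid="ignore", divide="ignore"):
                sw = np.where(tot > 0, (x01 + x10) / tot, 0.0)
            new_rf[j] = float(np.clip(sw.mean(), 1e-5, 0.49))
        if np.max(np.abs(new_rf - rf)) < tol:
            rf = new_rf
            break
        rf = new_rf
    return rf


def _observed_rf(X: np.ndarray) -> np.ndarray:
    """Adjacent-interval rf from raw discordance (pairwise complete)."""
    m = X.shape[0]
    out = np.empty(m - 1)
    for j in range(m - 1):
        ok = (X[j] != MISSING) & (X[j + 1] != MISSING)
        n = int(ok.sum())
        out[j] = (X[j][ok] != X[j + 1][ok]).mean() if n else 0.25
    return np.clip(out, 1e-5, 0.49)


def estimate_error_rate(X: np.ndarray, params: CurationParams | None = None
                        ) -> tuple[float, pd.DataFrame, np.ndarray]:
    """Maximum-likelihood genotyping error rate for one ordered LG.

    Profile likelihood over the error grid: at each candidate error rate the
    interval recombination fractions are re-estimated by bounded EM (raw
    adjacent discordance would otherwise absorb the errors as spurious
    crossovers and bias the estimate low), then the forward log-likelihood
    is evaluated.  Returns (eps_hat, likelihood curve, rf at eps_hat).
    """
    params = params or CurationParams()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 ordered markers")
    rf0 = _observed_rf(X)
    grid = np.asarray(params.error_prob_grid, dtype=float)
    lls = np.empty(len(grid))
    rfs = []
    for i, e in enumerate(grid):
        rf_e = _hmm_em_rf(X, rf0, float(e), iterations=params.em_iterations)
        rfs.append(rf_e)
        lls[i] = hmm_forward_loglik(X, rf_e, float(e))
    best = int(np.argmax(lls))
    eps_hat = float(grid[best])
    curve = pd.DataFrame({"error_prob": grid, "loglik": lls})
    return eps_hat, curve, rfs[best]


# ---------------------------------------------------------------------------
# crossover counting


def obligate_crossovers_per_individual(X: np.ndarray) -> np.ndarray:
    """Phase switches along each progeny's non-missing marker subsequence."""
    m, n = X.shape
    counts = np.zeros(n, dtype=int)
    for j in range(n):
        seq = X[:, j]
        seq = seq[seq != MISSING]
        if len(seq) > 1:
            counts[j] = int((seq[1:] != seq[:-1]).sum())
    return counts


def _adjacent_discordance_matrix(X: np.ndarray) -> np.ndarray:
    M = (X != MISSING)
    A = ((X == 1) & M).astype(float)
    B = ((X == 0) & M).astype(float)
    return A @ B.T + B @ A.T


# ---------------------------------------------------------------------------
# curation steps (operating on one parental map)


class _LgState:
    """Working state for one LG: ordered markers and phase-encoded rows."""

    def __init__(self, lg_id: str, parent: str, markers: list[str],
                 X: np.ndarray, chrom: list[str], pos: list[int]):
        self.lg_id = lg_id
        self.parent = parent
        self.markers = list(markers)
        self.X = X
        self.chrom = list(chrom)
        self.pos = list(pos)
        self.rf: np.ndarray | None = None
        self.eps: float | None = None

    def drop(self, marker_idx: list[int]) -> None:
        keep = [i for i in range(len(self.markers)) if i not in set(marker_idx)]
        self.markers = [self.markers[i] for i in keep]
        self.chrom = [self.chrom[i] for i in keep]
        self.pos = [self.pos[i] for i in keep]
        self.X = self.X[keep]
        self.rf = None

    def observed_length(self) -> float:
        if len(self.markers) < 2:
            return 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(np.sum(kosambi(_observed_rf(self.X))))

    def hmm_length(self) -> float:
        if self.rf is None:
            return self.observed_length()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(np.sum(kosambi(self.rf)))


def _states_from_map(gmap: GeneticMap, binary: BinaryMarkerMatrix,
                     phase_of: dict[str, int]) -> list[_LgState]:
    states = []
    for lg_id in gmap.lg_ids():
        t = gmap.lg_table(lg_id)
        sub = binary.subset_ids(t["marker"])
        X = sub.values.copy()
        for i, m in enumerate(t["marker"]):
            if phase_of[m] == 1:
                X[i] = np.where(X[i] == MISSING, MISSING, 1 - X[i])
        states.append(_LgState(lg_id, t["parent"].iloc[0], list(t["marker"]),
                               X, list(t["chrom"]), list(t["pos"])))
    return states


def filter_missing_and_crossovers(states: list[_LgState],
                                  progeny: list[str],
                                  params: CurationParams
                                  ) -> tuple[list[str], dict[str, list[str]]]:
    """Step 1: marker missingness, then individual missingness/crossovers.

    Mutates the states in place; returns (kept progeny, removed markers per
    LG).  Raises when no individual survives.
    """
    removed: dict[str, list[str]] = {}
    for st in states:
        miss = (st.X == MISSING).mean(axis=1)
        bad = np.flatnonzero(miss >= params.marker_missing_max)
        if bad.size:
            removed[st.lg_id] = [st.markers[i] for i in bad]
            st.drop(list(bad))

    total = np.vstack([st.X for st in states if len(st.markers)])
    ind_miss = (total == MISSING).mean(axis=0)
    xo = np.zeros(total.shape[1], dtype=int)
    for st in states:
        if len(st.markers) > 1:
            xo += obligate_crossovers_per_individual(st.X)
    mean_xo = xo.mean() if len(xo) else 0.0
    drop_ind = (ind_miss > params.individual_missing_max) | \
        (xo > params.crossover_multiple * mean_xo)
    if drop_ind.all():
        raise ValueError("step 1 would remove every individual")
    keep = np.flatnonzero(~drop_ind)
    for st in states:
        st.X = st.X[:, keep]
    kept_progeny = [progeny[i] for i in keep]
    return kept_progeny, removed


def order_diagnostics(st: _LgState, params: CurationParams,
                      min_pairs: int = 20) -> pd.DataFrame:
    """Step 2: flag adjacent pairs with rf > 0.4 or LOD < 1; re-polish if any."""
    if len(st.markers) < 3:
        return pd.DataFrame(columns=["lg", "left", "right", "rf", "lod"])
    stats = pairwise_rf(st.X, st.markers, min_pairs=min_pairs)
    flags = []
    for j in range(len(st.markers) - 1):
        r, l = stats.rf[j, j + 1], stats.lod[j, j + 1]
        if np.isnan(r):
            continue
        if r > params.rf_flag or l < params.lod_flag:
            flags.append({"lg": st.lg_id, "left": st.markers[j],
                          "right": st.markers[j + 1], "rf": float(r),
                          "lod": float(l)})
    if flags:
        D = _adjacent_discordance_matrix(st.X)
        new_order = polish_order(list(range(len(st.markers))), D, window=5)
        st.markers = [st.markers[i] for i in new_order]
        st.chrom = [st.chrom[i] for i in new_order]
        st.pos = [st.pos[i] for i in new_order]
        st.X = st.X[new_order]
    return pd.DataFrame(flags, columns=["lg", "left", "right", "rf", "lod"])


def drop_one_marker_scan(st: _LgState, params: CurationParams,
                         threshold: float | None = None
                         ) -> tuple[list[str], pd.DataFrame]:
    """Step 4 core: windowed drop-one scan for one LG.

    For each interior marker, the HMM log-likelihood (at the LG's eps_hat)
    and the window's Kosambi length are compared with and without the
    marker; candidates shorten the window by more than ``dropone_min_cM``.
    Window lengths use the raw adjacent discordance (an error-corrected map
    would absorb a spurious marker's flips and hide the inflation it
    causes); the LOD difference uses the error-model likelihood.  When
    ``threshold`` is None only the scan table is returned (the caller sets
    the threshold from the map-wide distribution); LG end markers are never
    dropped.
    """
    m = len(st.markers)
    half = params.dropone_window // 2
    rows = []
    if st.eps is None or st.rf is None:
        raise ValueError("run estimate_error_rate before the drop-one scan")
    for i in range(m):
        lo, hi = max(0, i - half), min(m, i + half + 1)
        W = st.X[lo:hi]
        if hi - lo < 3:
            continue
        rf_with = _hmm_em_rf(W, _observed_rf(W), st.eps, iterations=4)
        ll_with = hmm_forward_loglik(W, rf_with, st.eps)
        keep = [j for j in range(lo, hi) if j != i]
        Wd = st.X[keep]
        if len(keep) < 2:
            continue
        rf_wo = _hmm_em_rf(Wd, _observed_rf(Wd), st.eps, iterations=4)
        ll_wo = hmm_forward_loglik(Wd, rf_wo, st.eps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            len_with = float(np.sum(kosambi(_observed_rf(W))))
            len_wo = float(np.sum(kosambi(_observed_rf(Wd))))
        rows.append({"lg": st.lg_id, "marker": st.markers[i], "index": i,
                     "lod_diff": (ll_wo - ll_with) / np.log(10),
                     "cM_decrease": len_with - len_wo,
                     "terminal": i == 0 or i == m - 1})
    scan = pd.DataFrame(rows, columns=["lg", "marker", "index", "lod_diff",
                                       "cM_decrease", "terminal"])
    if threshold is None:
        return [], scan
    hit = scan[(~scan["terminal"])
               & (scan["cM_decrease"] > params.dropone_min_cM)
               & (scan["lod_diff"] > threshold)]
    return list(hit["marker"]), scan


def _corrected_rf(X: np.ndarray, eps: float) -> np.ndarray:
    """Adjacent rf with the observed discordance deflated for emission error."""
    d = _observed_rf(X)
    c = 2.0 * eps * (1.0 - eps)
    return np.clip((d - c) / max(1.0 - 2.0 * c, 1e-6), 1e-5, 0.49)


def _pairwise_corrected_rf(X: np.ndarray, eps: float) -> np.ndarray:
    """All-pairs rf with the discordance deflated for emission error."""
    M = (X != MISSING)
    A = ((X == 1) & M).astype(float)
    B = ((X == 0) & M).astype(float)
    n = M.astype(float) @ M.astype(float).T
    disc = A @ B.T + B @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n > 0, disc / n, 0.25)
    c = 2.0 * eps * (1.0 - eps)
    return np.clip((d - c) / max(1.0 - 2.0 * c, 1e-6), 1e-5, 0.49)


def _likelihood_ripple(st: _LgState, params: CurationParams, window: int = 5,
                       max_passes: int = 3) -> None:
    """Error-aware order refinement: exhaustive window permutations scored
    by the full-LG phase-HMM likelihood.

    The obligate-crossover objective counts an isolated genotyping flip as
    two crossovers; the HMM instead explains it as an emission error, so
    this pass resolves local orders the crossover count cannot.  Forward
    states (prefix) and backward states (suffix) are cached so a candidate
    permutation only costs the window itself.
    """
    import itertools as _it

    m = len(st.markers)
    if st.eps is None or m < window + 1:
        return
    w = window
    eps = st.eps
    perms = list(_it.permutations(range(w)))

    for _ in range(max_passes):
        X = st.X
        n = X.shape[1]
        R = _pairwise_corrected_rf(X, eps)
        E0 = np.where(X == MISSING, 1.0, np.where(X == 0, 1.0 - eps, eps))
        E1 = np.where(X == MISSING, 1.0, np.where(X == 1, 1.0 - eps, eps))

        # backward: Bs[j] = scaled P(x_j..end | state_j), with per-progeny
        # cumulative log scale LB[j]; valid for the whole left-to-right pass
        B0 = np.empty((m, n)); B1 = np.empty((m, n)); LB = np.zeros((m, n))
        B0[-1], B1[-1] = E0[-1], E1[-1]
        sc = B0[-1] + B1[-1]
        B0[-1] /= sc; B1[-1] /= sc; LB[-1] = np.log(sc)
        for j in range(m - 2, -1, -1):
            r = R[j, j + 1]
            b0 = E0[j] * ((1 - r) * B0[j + 1] + r * B1[j + 1])
            b1 = E1[j] * (r * B0[j + 1] + (1 - r) * B1[j + 1])
            sc = b0 + b1
            B0[j], B1[j] = b0 / sc, b1 / sc
            LB[j] = LB[j + 1] + np.log(sc)

        order = list(range(m))
        # forward state before the window (prefix); advanced incrementally
        f0 = np.full(n, 0.5); f1 = np.full(n, 0.5)
        lf = np.zeros(n)
        improved = False
        for start in range(0, m - w + 1):
            prev = order[start - 1] if start > 0 else None

            def chain_ll(widx):
                a0, a1, ls = f0, f1, lf
                last = prev
                for u in widx:
                    if last is None:
                        b0, b1 = a0 * E0[u], a1 * E1[u]
                    else:
                        r = R[last, u]
                        b0 = (a0 * (1 - r) + a1 * r) * E0[u]
                        b1 = (a0 * r + a1 * (1 - r)) * E1[u]
                    sc = b0 + b1
                    a0, a1 = b0 / sc, b1 / sc
                    ls = ls + np.log(sc)
                    last = u
                if start + w < m:
                    nxt = order[start + w]
                    r = R[last, nxt]
                    t0 = (a0 * (1 - r) + a1 * r) * B0[nxt]
                    t1 = (a0 * r + a1 * (1 - r)) * B1[nxt]
                    return float((ls + np.log(t0 + t1) + LB[nxt]).sum())
                return float(ls.sum())

            seg = order[start:start + w]
            best_p = tuple(range(w))
            best_ll = chain_ll(seg)
            for p in perms[1:]:
                ll = chain_ll([seg[i] for i in p])
                if ll > best_ll + 1e-9:
                    best_p, best_ll = p, ll
            if best_p != tuple(range(w)):
                order[start:start + w] = [seg[i] for i in best_p]
                improved = True
            # advance the forward state over the marker leaving the window
            u = order[start]
            if prev is None:
                b0, b1 = f0 * E0[u], f1 * E1[u]
            else:
                r = R[prev, u]
                b0 = (f0 * (1 - r) + f1 * r) * E0[u]
                b1 = (f0 * r + f1 * (1 - r)) * E1[u]
            sc = b0 + b1
            f0, f1 = b0 / sc, b1 / sc
            lf = lf + np.log(sc)

        if improved:
            st.markers = [st.markers[i] for i in order]
            st.chrom = [st.chrom[i] for i in order]
            st.pos = [st.pos[i] for i in order]
            st.X = st.X[order]
        else:
            break


def ripple_and_finalize(st: _LgState, params: CurationParams) -> pd.DataFrame:
    """Step 5: ripple (window 7, obligate-crossover objective), orient, measure.

    Gap flags (intervals > gap_max_cM after re-estimation) are reported for
    manual review, not removed.  The LG is reversed when its cM order
    anticorrelates with physical position.
    """
    m = len(st.markers)
    if m >= 3:
        D = _adjacent_discordance_matrix(st.X)
        new_order = polish_order(list(range(m)), D, window=params.ripple_window)
        st.markers = [st.markers[i] for i in new_order]
        st.chrom = [st.chrom[i] for i in new_order]
        st.pos = [st.pos[i] for i in new_order]
        st.X = st.X[new_order]
        _likelihood_ripple(st, params)
    if st.eps is not None and m >= 3:
        st.rf = _hmm_em_rf(st.X, _observed_rf(st.X), st.eps,
                           iterations=params.em_iterations)
    # orientation against physical coordinates (within the modal chromosome)
    if m >= 3:
        pos = np.asarray(st.pos, dtype=float)
        rank = np.arange(m, dtype=float)
        if np.std(pos) > 0 and np.corrcoef(rank, pos)[0, 1] < 0:
            st.markers.reverse(); st.chrom.reverse(); st.pos.reverse()
            st.X = st.X[::-1]
            if st.rf is not None:
                st.rf = st.rf[::-1]
    gaps = []
    if st.rf is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = kosambi(st.rf)
        for j, dj in enumerate(d):
            if dj > params.gap_max_cM:
                gaps.append({"lg": st.lg_id, "left": st.markers[j],
                             "right": st.markers[j + 1], "gap_cM": float(dj)})
    return pd.DataFrame(gaps, columns=["lg", "left", "right", "gap_cM"])


# ---------------------------------------------------------------------------
# orchestration


def curate_map(gmap: GeneticMap, binary: BinaryMarkerMatrix,
               params: CurationParams | None = None,
               min_pairs: int = 20) -> tuple[GeneticMap, CurationReport]:
    """Run curation steps 1-5 on one (parental) map.

    The report's stage table mirrors the conventional bookkeeping: marker
    counts and total Kosambi length initially, after order diagnostics,
    after the automatic drop-one step, and finally.
    """
    params = params or CurationParams()
    report = CurationReport()
    phase_of = dict(zip(gmap.table["marker"], gmap.table["phase"]))
    states = _states_from_map(gmap, binary, phase_of)
    progeny = list(binary.progeny)

    def snapshot(stage: str, hmm: bool) -> dict:
        return {"stage": stage,
                "n_markers": sum(len(st.markers) for st in states),
                "total_cM": float(sum(st.hmm_length() if hmm
                                      else st.observed_length() for st in states))}

    stages = [snapshot("initial", hmm=False)]

    kept_progeny, removed1 = filter_missing_and_crossovers(states, progeny, params)
    report.removed_individuals = sorted(set(progeny) - set(kept_progeny))
    report.removed_markers["step1"] = sorted(
        m for ms in removed1.values() for m in ms)

    seg_flags = []
    for st in states:
        seg_flags.append(order_diagnostics(st, params, min_pairs=min_pairs))
    report.flagged_segments = pd.concat(seg_flags, ignore_index=True) if seg_flags \
        else pd.DataFrame()
    stages.append(snapshot("after_order_check", hmm=False))

    for st in states:
        if len(st.markers) >= 3:
            eps_hat, _, rf_hat = estimate_error_rate(st.X, params)
            st.eps, st.rf = eps_hat, rf_hat
            report.error_rates[st.lg_id] = eps_hat
    stages.append(snapshot("after_error_model", hmm=True))

    scans = []
    for st in states:
        if st.eps is None:
            continue
        _, scan = drop_one_marker_scan(st, params, threshold=None)
        scans.append(scan)
    all_scan = pd.concat(scans, ignore_index=True) if scans else pd.DataFrame(
        columns=["lg", "marker", "index", "lod_diff", "cM_decrease", "terminal"])
    report.dropone_lod_diffs = all_scan
    thr = params.lod_diff_threshold
    if thr is None and len(all_scan):
        thr = float(np.quantile(all_scan["lod_diff"], params.lod_diff_quantile))
    removed4: list[str] = []
    for st in states:
        if st.eps is None or thr is None:
            continue
        sc = all_scan[all_scan["lg"] == st.lg_id]
        hit = sc[(~sc["terminal"])
                 & (sc["cM_decrease"] > params.dropone_min_cM)
                 & (sc["lod_diff"] > thr)]
        if len(hit):
            removed4.extend(hit["marker"])
            st.drop([st.markers.index(m) for m in hit["marker"]])
        if len(st.markers) >= 3:
            st.rf = _hmm_em_rf(st.X, _observed_rf(st.X), st.eps,
                               iterations=params.em_iterations)
    report.removed_markers["step4"] = sorted(removed4)
    stages.append(snapshot("after_autodrop", hmm=True))

    gap_frames = []
    for st in states:
        gap_frames.append(ripple_and_finalize(st, params))
    report.gap_flags = pd.concat(gap_frames, ignore_index=True) if gap_frames \
        else pd.DataFrame()
    stages.append(snapshot("final", hmm=True))
    report.stages = pd.DataFrame(stages)

    rows = []
    for st in states:
        if len(st.markers) < 2 or st.rf is None:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = np.concatenate([[0.0], np.cumsum(kosambi(st.rf))])
        for mk, c, ch, p, xr in zip(st.markers, cm, st.chrom, st.pos, st.X):
            rows.append({"marker": mk, "lg": st.lg_id, "parent": st.parent,
                         "phase": phase_of[mk], "cM": float(c), "chrom": ch,
                         "pos": int(p), "n_missing": int((xr == MISSING).sum())})
    final = GeneticMap(table=pd.DataFrame(
        rows, columns=["marker", "lg", "parent", "phase", "cM", "chrom", "pos",
                       "n_missing"]))
    return final, report
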