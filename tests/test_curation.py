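"""Curation: phase HMM, error-rate recovery, drop-one, ripple, end-to-end."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from gbslink import (
    CurationParams, curate_map, estimate_error_rate, hmm_forward_loglik,
    obligate_crossovers_per_individual,
)
from gbslink.curation import (
    _LgState, _hmm_em_rf, _observed_rf, drop_one_marker_scan,
    filter_missing_and_crossovers, ripple_and_finalize,
)
from gbslink.mapping import kosambi
from gbslink.simulate import SimConfig, simulate_family
from gbslink.types import MISSING, BinaryMarkerMatrix, GeneticMap, LinkageGroup


# ---------------------------------------------------------------------------
# HMM forward likelihood


def brute_force_loglik(X, rf, eps):
    """Exhaustive sum over all 2^m hidden phase paths (oracle)."""
    m, n = X.shape
    total = 0.0
    for j in range(n):
        p = 0.0
        for path in itertools.product([0, 1], repeat=m):
            lp = 0.5
            for i in range(m):
                if X[i, j] != MISSING:
                    lp *= (1 - eps) if X[i, j] == path[i] else eps
                if i < m - 1:
                    lp *= rf[i] if path[i] != path[i + 1] else (1 - rf[i])
            p += lp
        total += np.log(p)
    return total


@pytest.mark.parametrize("m,seed", [(3, 0), (6, 1), (9, 2), (12, 3)])
def test_forward_matches_exhaustive_path_sum(m, seed):
    rng = np.random.default_rng(seed)
    X = rng.choice([0, 1, MISSING], size=(m, 7), p=[0.45, 0.45, 0.1]).astype(np.int8)
    rf = rng.uniform(0.01, 0.45, size=m - 1)
    eps = 0.07
    assert hmm_forward_loglik(X, rf, eps) == pytest.approx(
        brute_force_loglik(X, rf, eps), abs=1e-8)


def _noisy_lg(seed, eps, n_markers=30, n_progeny=200, length_cM=60):
    cfg = SimConfig(seed=seed, n_chrom=1, chrom_length_cM=length_cM,
                    n_pt_female=n_markers, n_pt_male=0, n_nonpt=0,
                    n_progeny=n_progeny)
    _, truth = simulate_family(cfg)
    order = np.argsort(truth.markers["cM"].to_numpy())
    sids = truth.markers["site_id"].to_numpy()[order]
    rows = truth.true_phase_rows(sids)
    ph = truth.markers["phase_female"].to_numpy()[order]
    X = np.where(ph[:, None] == 1, 1 - rows, rows).astype(np.int8)
    rng = np.random.default_rng(seed + 1)
    if eps > 0:
        flips = rng.random(X.shape) < eps
        X = np.where(flips, 1 - X, X).astype(np.int8)
    return sids.tolist(), X, truth


@pytest.mark.parametrize("eps", [0.01, 0.05, 0.1])
def test_error_rate_recovery(eps):
    """eps_hat within +/- 0.02 of the planted flip rate."""
    _, X, _ = _noisy_lg(seed=211, eps=eps)
    params = CurationParams()
    eps_hat, curve, rf_hat = estimate_error_rate(X, params)
    assert abs(eps_hat - eps) <= 0.02
    # argmax property by construction
    assert curve.loc[curve["loglik"].idxmax(), "error_prob"] == eps_hat


def test_zero_error_simulation_estimates_grid_minimum():
    _, X, _ = _noisy_lg(seed=223, eps=0.0)
    params = CurationParams()
    eps_hat, _, _ = estimate_error_rate(X, params)
    assert eps_hat == params.error_prob_grid[0]


def test_em_rf_deflates_error_inflated_distances():
    """Raw discordance overestimates rf under noise; the EM estimate does not."""
    _, X, truth = _noisy_lg(seed=227, eps=0.05, length_cM=30)
    true_len = 30.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw_len = float(np.sum(kosambi(_observed_rf(X))))
        eps_hat, _, rf_hat = estimate_error_rate(X)
        em_len = float(np.sum(kosambi(rf_hat)))
    assert raw_len > 1.5 * true_len
    assert abs(em_len - true_len) < 0.35 * true_len
    assert em_len < raw_len


# ---------------------------------------------------------------------------
# step 1


def _state_from(X, markers=None, lg_id="1"):
    m = X.shape[0]
    markers = markers or [f"m{i}" for i in range(m)]
    return _LgState(lg_id, "female", markers, X.copy(),
                    ["1"] * m, list((np.arange(m) + 1) * 1000))


def test_step1_marker_and_individual_thresholds():
    rng = np.random.default_rng(31)
    X = rng.integers(0, 2, size=(10, 40)).astype(np.int8)
    X[0, :20] = MISSING                       # exactly 50% missing -> removed (>=)
    X[1, :19] = MISSING                       # 47.5% -> kept
    st = _state_from(X)
    kept, removed = filter_missing_and_crossovers([st], [f"p{i}" for i in range(40)],
                                                  CurationParams())
    assert "m0" in removed["1"]
    assert "m1" in st.markers
    assert len(kept) <= 40


def test_step1_crossover_excess_uses_strict_multiple():
    # individuals: constant phase rows except one with many switches
    X = np.zeros((20, 30), dtype=np.int8)
    X[::2, 29] = 1                            # alternating: 19 switches
    X[10:, :2] = 1                            # everyone else: exactly 1 switch
    st = _state_from(X)
    prog = [f"p{i}" for i in range(30)]
    kept, _ = filter_missing_and_crossovers([st], prog, CurationParams())
    assert "p29" not in kept
    assert len(kept) == 29


def test_step1_refuses_to_remove_everyone():
    X = np.full((5, 8), MISSING, dtype=np.int8)
    st = _state_from(X)
    with pytest.raises(ValueError):
        filter_missing_and_crossovers([st], [f"p{i}" for i in range(8)],
                                      CurationParams())


# ---------------------------------------------------------------------------
# drop-one and ripple


def test_dropone_removes_planted_noisy_marker():
    rng = np.random.default_rng(37)
    sids, X, _ = _noisy_lg(seed=229, eps=0.0, n_markers=15, length_cM=15)
    bad = 7
    flips = rng.random(X.shape[1]) < 0.10     # isolated flips, 10% of progeny
    X[bad] = np.where(flips, 1 - X[bad], X[bad])
    st = _state_from(X, markers=sids)
    st.eps, _, st.rf = estimate_error_rate(X)
    removed, scan = drop_one_marker_scan(st, CurationParams(), threshold=0.0)
    assert sids[bad] in removed
    assert len(scan) == len(sids)             # histogram covers all markers scanned


def test_dropone_scan_on_clean_lg_removes_nothing():
    sids, X, _ = _noisy_lg(seed=233, eps=0.0, n_markers=12, length_cM=30)
    st = _state_from(X, markers=sids)
    st.eps, _, st.rf = estimate_error_rate(X)
    removed, scan = drop_one_marker_scan(st, CurationParams(), threshold=0.0)
    assert removed == []


def test_ripple_restores_adjacent_swap_and_is_idempotent():
    sids, X, _ = _noisy_lg(seed=239, eps=0.0, n_markers=10, n_progeny=400,
                           length_cM=90)
    swapped = list(range(10))
    swapped[4], swapped[5] = swapped[5], swapped[4]
    st = _state_from(X[swapped], markers=[sids[i] for i in swapped])
    st.pos = [(i + 1) * 1000 for i in swapped]
    st.eps, st.rf = 1e-4, _observed_rf(st.X)
    ripple_and_finalize(st, CurationParams())
    assert st.markers == sids or st.markers == sids[::-1]
    before = list(st.markers)
    ripple_and_finalize(st, CurationParams())  # fixed point
    assert st.markers == before


def test_ripple_never_increases_obligate_crossovers():
    rng = np.random.default_rng(41)
    sids, X, _ = _noisy_lg(seed=241, eps=0.03, n_markers=12, length_cM=40)
    perm = rng.permutation(12)
    st = _state_from(X[perm], markers=[sids[i] for i in perm])
    st.eps, st.rf = 0.03, _observed_rf(st.X)

    def total_xo(state):
        return int(obligate_crossovers_per_individual(state.X).sum())

    before = total_xo(st)
    ripple_and_finalize(st, CurationParams())
    assert total_xo(st) <= before


def test_backwards_lg_inverted_against_physical_positions():
    sids, X, truth = _noisy_lg(seed=251, eps=0.0, n_markers=8, length_cM=60)
    st = _state_from(X[::-1], markers=sids[::-1])
    st.pos = list(truth.markers.set_index("site_id").loc[st.markers, "pos"])
    st.eps, st.rf = 1e-4, _observed_rf(st.X)
    ripple_and_finalize(st, CurationParams())
    assert st.pos == sorted(st.pos)


# ---------------------------------------------------------------------------
# end-to-end


def _map_from_truth(truth, binary, lg_ids):
    rows = []
    tm = truth.markers.set_index("site_id")
    present = set(binary.markers["site_id"])
    for lg_id in lg_ids:
        sub = tm[tm["lg_id"] == lg_id].sort_values("cM")
        col = "phase_female" if lg_id.startswith("F") else "phase_male"
        for m in sub.index:
            if m not in present:
                continue
            rows.append({"marker": m, "lg": lg_id,
                         "parent": "female" if lg_id.startswith("F") else "male",
                         "phase": int(sub.loc[m, col]),
                         "cM": float(sub.loc[m, "cM"]),
                         "chrom": str(sub.loc[m, "chrom"]),
                         "pos": int(sub.loc[m, "pos"]), "n_missing": 0})
    return GeneticMap(table=pd.DataFrame(rows))


def test_curation_end_to_end_length_and_bookkeeping(small_family8):
    """Curated length within [0.85, 1.25] x simulated truth; counts shrink only."""
    truth = small_family8["truth"]
    binary = small_family8["binary"]
    gmap = _map_from_truth(truth, binary, ["F1", "M1", "F2"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final, report = curate_map(gmap, binary)
    stages = report.stages
    n = stages["n_markers"].to_numpy()
    assert (np.diff(n) <= 0).all()             # only removals occur
    true_len = small_family8["config"].chrom_length_cM
    for lg in final.lg_ids():
        length = final.lg_length(lg)
        assert 0.85 * true_len <= length <= 1.25 * true_len
    for lg in final.lg_ids():
        t = final.lg_table(lg)
        assert t["cM"].iloc[0] == 0.0
        assert (t["cM"].diff().dropna() >= -1e-12).all()


def test_curation_shrinks_error_inflated_maps():
    """Planted eps = 0.03: curated length strictly below pre-curation length."""
    sids, X, truth = _noisy_lg(seed=257, eps=0.03, n_markers=40, length_cM=100)
    sites = pd.DataFrame({
        "chrom": "1", "pos": truth.markers.set_index("site_id").loc[sids, "pos"].values,
        "major": "A", "minor": "C", "site_id": sids})
    binary = BinaryMarkerMatrix(markers=sites.reset_index(drop=True),
                                progeny=truth.progeny, values=X)
    tm = truth.markers.set_index("site_id")
    rows = [{"marker": m, "lg": "F1", "parent": "female", "phase": 0,
             "cM": float(tm.loc[m, "cM"]), "chrom": "1",
             "pos": int(tm.loc[m, "pos"]), "n_missing": 0} for m in sids]
    gmap = GeneticMap(table=pd.DataFrame(rows))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final, report = curate_map(gmap, binary)
    stages = report.stages.set_index("stage")["total_cM"]
    assert stages["final"] < stages["initial"]
    assert report.error_rates["F1"] == pytest.approx(0.03, abs=0.02)
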