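"""Ordering, two-point statistics, Kosambi, joining, parent assignment."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from gbslink import (
    assign_parent_and_name, build_genetic_map, filter_ordered_markers,
    join_split_lgs, kosambi, kosambi_inverse, order_markers_mst, pairwise_rf,
    phase_encode,
)
from gbslink.simulate import SimConfig, simulate_family
from gbslink.types import MISSING, BinaryMarkerMatrix, LinkageGroup, make_site_table


# ---------------------------------------------------------------------------
# Kosambi


def test_kosambi_values_and_round_trip():
    assert kosambi(0.0) == pytest.approx(0.0)
    assert kosambi(0.25) == pytest.approx(25 * np.log(3), abs=1e-12)  # 27.465 cM
    r = np.linspace(0.0, 0.49, 50)
    assert np.allclose(kosambi_inverse(kosambi(r)), r, atol=1e-12)
    with pytest.raises(ValueError):
        kosambi(-0.01)
    with pytest.warns(UserWarning):
        assert kosambi(0.5) == 50.0          # capped


# ---------------------------------------------------------------------------
# two-point statistics


def test_pairwise_rf_closed_forms():
    n = 20
    a = np.array([0, 1] * (n // 2), dtype=np.int8)
    identical = np.vstack([a, a])
    s = pairwise_rf(identical, ["m1", "m2"], min_pairs=5)
    assert s.rf[0, 1] == 0.0
    assert s.lod[0, 1] == pytest.approx(n * np.log10(2), abs=1e-9)   # ~6.02

    two_discordant = a.copy()
    two_discordant[:2] = 1 - two_discordant[:2]
    s2 = pairwise_rf(np.vstack([a, two_discordant]), ["m1", "m2"], min_pairs=5)
    assert s2.rf[0, 1] == pytest.approx(2 / 20)

    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 2000).astype(np.int8)
    y = rng.integers(0, 2, 2000).astype(np.int8)
    s3 = pairwise_rf(np.vstack([x, y]), ["m1", "m2"], min_pairs=5)
    assert abs(s3.rf[0, 1] - 0.5) < 0.05
    assert s3.lod[0, 1] < 1.0


def test_pairwise_rf_missing_and_min_pairs():
    a = np.array([0, 1, MISSING, 1, 0], dtype=np.int8)
    b = np.array([0, MISSING, 1, 1, 1], dtype=np.int8)
    s = pairwise_rf(np.vstack([a, b]), ["m1", "m2"], min_pairs=3)
    assert s.n_informative[0, 1] == 3
    assert s.rf[0, 1] == pytest.approx(1 / 3)
    s_strict = pairwise_rf(np.vstack([a, b]), ["m1", "m2"], min_pairs=4)
    assert np.isnan(s_strict.rf[0, 1])


# ---------------------------------------------------------------------------
# ordering


def _simulated_lg(seed, n_markers, n_progeny, length_cM):
    cfg = SimConfig(seed=seed, n_chrom=1, chrom_length_cM=length_cM,
                    n_pt_female=n_markers, n_pt_male=0, n_nonpt=0,
                    n_progeny=n_progeny)
    _, truth = simulate_family(cfg)
    order = np.argsort(truth.markers["cM"].to_numpy())
    sids = truth.markers["site_id"].to_numpy()[order]
    rows = truth.true_phase_rows(sids)
    # phase-encode: 1 = haplotype 0 inherited
    ph = truth.markers["phase_female"].to_numpy()[order]
    X = np.where(ph[:, None] == 1, 1 - rows, rows).astype(np.int8)
    return sids.tolist(), X


def test_recovers_true_order_of_spaced_markers():
    """6 markers at 10 cM spacing, 500 progeny: exact order up to reversal."""
    sids, X = _simulated_lg(seed=83, n_markers=6, n_progeny=500, length_cM=60)
    perm = np.random.default_rng(5).permutation(6)
    stats = pairwise_rf(X[perm], [sids[i] for i in perm], min_pairs=5)
    ordered, aside = order_markers_mst(stats)
    assert aside == []
    assert ordered == sids or ordered == sids[::-1]


def test_order_cost_matches_exhaustive_minimum():
    """5-marker noisy toy: adjacent-rf total equals the brute-force optimum."""
    rng = np.random.default_rng(11)
    sids, X = _simulated_lg(seed=89, n_markers=5, n_progeny=120, length_cM=40)
    noise = rng.random(X.shape) < 0.05
    X = np.where(noise, 1 - X, X).astype(np.int8)
    stats = pairwise_rf(X, sids, min_pairs=5)
    ordered, _ = order_markers_mst(stats)
    idx = {m: i for i, m in enumerate(sids)}
    rf = stats.rf

    def cost(order):
        return sum(rf[idx[a], idx[b]] for a, b in zip(order[:-1], order[1:]))

    best = min(cost(list(p)) for p in itertools.permutations(sids))
    assert cost(ordered) <= best + 1e-9


def test_three_markers_middle_identified():
    sids, X = _simulated_lg(seed=97, n_markers=3, n_progeny=400, length_cM=40)
    stats = pairwise_rf(X, sids, min_pairs=5)
    ordered, _ = order_markers_mst(stats)
    assert ordered[1] == sids[1]


def test_order_recovery_quality_on_noisy_lg():
    """80 markers, depth-8-like noise: Kendall tau >= 0.98 up to reversal."""
    rng = np.random.default_rng(13)
    sids, X = _simulated_lg(seed=101, n_markers=80, n_progeny=200, length_cM=100)
    noise = rng.random(X.shape) < 0.015
    X = np.where(noise, 1 - X, X).astype(np.int8)
    perm = rng.permutation(80)
    stats = pairwise_rf(X[perm], [sids[i] for i in perm])
    ordered, _ = order_markers_mst(stats)
    true_rank = {m: i for i, m in enumerate(sids)}
    tau = kendalltau(range(len(ordered)), [true_rank[m] for m in ordered]).statistic
    assert abs(tau) >= 0.98


# ---------------------------------------------------------------------------
# post-ordering filter


def test_redundant_marker_with_fewest_missing_kept():
    base = np.array([0, 1, 1, 0, 1, 0, 0, 1] * 5, dtype=np.int8)
    twin = base.copy()
    twin[:5] = MISSING
    far = 1 - base
    X = np.vstack([base, twin, far])
    markers = ["keep", "gappy", "far"]
    retained, report = filter_ordered_markers(markers, X, markers, min_pairs=5)
    assert "keep" in retained and "gappy" not in retained
    assert report.set_index("marker").loc["gappy", "reason"] == "redundant"


def test_double_crossover_marker_removed():
    rng = np.random.default_rng(17)
    sids, X = _simulated_lg(seed=103, n_markers=9, n_progeny=200, length_cM=8)
    flips = rng.random(X.shape[1]) < 0.3
    X[4] = np.where(flips, 1 - X[4], X[4])   # 30% isolated flips
    retained, report = filter_ordered_markers(sids, X, sids)
    assert sids[4] not in retained
    assert "double_crossover" in set(report["reason"])


def test_clean_lg_loses_nothing():
    sids, X = _simulated_lg(seed=107, n_markers=10, n_progeny=300, length_cM=50)
    retained, report = filter_ordered_markers(sids, X, sids)
    assert retained == sids
    assert len(report) == 0


# ---------------------------------------------------------------------------
# parent assignment and joining


def _truth_binary_and_lgs(seed=109, n_chrom=2):
    cfg = SimConfig(seed=seed, n_chrom=n_chrom, n_pt_female=40, n_pt_male=40,
                    n_nonpt=0, n_progeny=200)
    _, truth = simulate_family(cfg)
    rows = truth.true_phase_rows(list(truth.markers["site_id"]))
    sites = pd.DataFrame({
        "chrom": truth.markers["chrom"].astype(str), "pos": truth.markers["pos"],
        "major": "A", "minor": "C", "site_id": truth.markers["site_id"]})
    binary = BinaryMarkerMatrix(markers=sites.reset_index(drop=True),
                                progeny=truth.progeny,
                                values=rows.astype(np.int8))
    lgs = []
    for lg_id, sub in truth.markers.groupby("lg_id"):
        parent_col = "phase_female" if lg_id.startswith("F") else "phase_male"
        lgs.append(LinkageGroup(
            lg_id=lg_id, markers=list(sub["site_id"]),
            phase=dict(zip(sub["site_id"], sub[parent_col])),
            chrom_label=str(sub["chrom"].iloc[0]), provenance="simulated"))
    return truth, binary, lgs


def test_parent_assignment_matches_truth():
    truth, binary, lgs = _truth_binary_and_lgs()
    prog = pd.DataFrame(index=binary.markers["site_id"])
    tm = truth.markers.set_index("site_id")
    prog["mother"] = ["AB" if k == "pt_female" else "AA" for k in tm["kind"]]
    prog["father"] = ["AB" if k == "pt_male" else "AA" for k in tm["kind"]]
    named = assign_parent_and_name(lgs, prog, binary.markers)
    for lg, orig in zip(named, lgs):
        expected = "female" if orig.lg_id.startswith("F") else "male"
        assert lg.parent == expected
        c = int(orig.lg_id[1:])
        assert lg.lg_id == str(c if expected == "female" else c + 19)


def test_parent_assignment_without_progenitors_is_consistent():
    _, binary, lgs = _truth_binary_and_lgs()
    named = assign_parent_and_name(lgs, None, binary.markers)
    for chrom in {lg.chrom_label for lg in named}:
        labels = sorted(lg.parent for lg in named if lg.chrom_label == chrom)
        assert labels == ["unknown-A", "unknown-B"]


def test_join_split_lgs_prefers_true_orientation():
    truth, binary, lgs = _truth_binary_and_lgs(seed=113, n_chrom=1)
    lg = [l for l in lgs if l.lg_id == "F1"][0]
    order = truth.markers.set_index("site_id").loc[lg.markers, "cM"].sort_values()
    sorted_ids = list(order.index)
    half = len(sorted_ids) // 2
    def chunk(ids, tag, flip):
        return LinkageGroup(
            lg_id=tag, markers=ids,
            phase={m: (1 - lg.phase[m] if flip else lg.phase[m]) for m in ids},
            parent="female", chrom_label="1")
    a = chunk(sorted_ids[:half], "a", False)
    b = chunk(sorted_ids[half:], "b", True)     # stored in flipped phase
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        joined, report = join_split_lgs(a, b, binary, min_pairs=10)
    assert joined is not None
    assert report["chosen"] == "flipped"        # flipping back wins
    assert report["flipped_cM"] < report["aligned_cM"]
    assert report["joined_cM"] <= report["aligned_cM"]


def test_join_rejects_self_join():
    _, binary, lgs = _truth_binary_and_lgs(seed=113, n_chrom=1)
    lg = lgs[0]
    with pytest.raises(ValueError):
        join_split_lgs(lg, lg, binary)


def test_map_length_is_sum_of_adjacent_kosambi(small_family8):
    """Conservation: LG length equals the cumulative Kosambi distance."""
    truth = small_family8["truth"]
    binary = small_family8["binary"]
    tm = truth.markers.set_index("site_id")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = tm[tm["lg_id"] == "F1"]
        present = [m for m in sub.index if m in set(binary.markers["site_id"])]
        lg = LinkageGroup(lg_id="F1", markers=present,
                          phase={m: int(tm.loc[m, "phase_female"]) for m in present},
                          parent="female", chrom_label="1")
        gmap, _ = build_genetic_map([lg], binary)
    t = gmap.table
    assert (t["cM"].diff().dropna() >= -1e-12).all()
    assert t["cM"].iloc[0] == 0.0
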