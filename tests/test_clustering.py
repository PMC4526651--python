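"""Correlation, TOM distance, static-cut clustering, diff filter, phasing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbslink import (
    ClusterParams, binary_correlation_matrix, cluster_static_cut, diff_filter,
    phase_linkage_group, tom_distance,
)
from gbslink.clustering import AGREE, DISAGREE, UNRESOLVED, UNASSIGNED, CorrelationMatrix
from gbslink.simulate import SimConfig, simulate_family
from gbslink.types import MISSING, BinaryMarkerMatrix, make_site_table


def _binary(values, progeny=None):
    values = np.array(values, dtype=np.int8)
    m, n = values.shape
    sites = make_site_table(["1"] * m, (np.arange(m) + 1) * 10, ["A"] * m, ["C"] * m)
    return BinaryMarkerMatrix(markers=sites,
                              progeny=progeny or [f"p{i}" for i in range(n)],
                              values=values)


def _binary_from_truth(rows, truth):
    import pandas as pd

    sites = pd.DataFrame({
        "chrom": truth.markers["chrom"].astype(str),
        "pos": truth.markers["pos"],
        "major": "A", "minor": "C",
        "site_id": truth.markers["site_id"],
    })
    return BinaryMarkerMatrix(markers=sites.reset_index(drop=True),
                              progeny=truth.progeny,
                              values=np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# correlations


def test_correlation_self_complement_and_textbook():
    x = [1, 1, 0, 0, 1]
    y = [1, 0, 0, 0, 1]
    b = _binary([x, [1 - v for v in x], y], progeny=list("abcde"))
    corr = binary_correlation_matrix(b, min_pairs=2)
    assert corr.values[0, 0] == pytest.approx(1.0)
    assert corr.values[0, 1] == pytest.approx(-1.0)   # perfect repulsion
    expected = np.corrcoef(x, y)[0, 1]
    assert corr.values[0, 2] == pytest.approx(expected, abs=1e-12)
    assert np.allclose(corr.values, corr.values.T, equal_nan=True)


def test_correlation_pairwise_complete_and_min_pairs():
    x = [1, 0, 1, MISSING, 0, 1]
    y = [1, 0, MISSING, 1, 0, 0]
    b = _binary([x, y])
    corr = binary_correlation_matrix(b, min_pairs=4)
    ok = [i for i in range(6) if x[i] != MISSING and y[i] != MISSING]
    expected = np.corrcoef([x[i] for i in ok], [y[i] for i in ok])[0, 1]
    assert corr.values[0, 1] == pytest.approx(expected, abs=1e-12)
    assert corr.n_obs[0, 1] == len(ok)
    strict = binary_correlation_matrix(b, min_pairs=5)
    assert np.isnan(strict.values[0, 1])             # too few complete pairs


def test_constant_vector_yields_missing_correlation():
    b = _binary([[1, 1, 1, 1], [1, 0, 1, 0]])
    corr = binary_correlation_matrix(b, min_pairs=2)
    assert np.isnan(corr.values[0, 1])


# ---------------------------------------------------------------------------
# TOM


def brute_force_tom_distance(A):
    """Independent double-loop oracle for the TOM dissimilarity."""
    A = np.array(A, dtype=float)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=1)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n))
            tom = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
            D[i, j] = 1 - tom
    return D


def test_tom_fully_connected_triangle_is_zero_distance():
    assert np.allclose(tom_distance(np.ones((3, 3))), 0.0)


def test_tom_zero_adjacency_gives_unit_distances():
    D = tom_distance(np.zeros((4, 4)))
    off = D[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=20), st.integers(0, 10_000))
def test_tom_matches_brute_force_oracle(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0, 1, size=(n, n))
    A = (A + A.T) / 2
    assert np.allclose(tom_distance(A), brute_force_tom_distance(A), atol=1e-12)


def test_tom_rejects_out_of_range_adjacency():
    with pytest.raises(ValueError):
        tom_distance(np.full((3, 3), 1.5))


# ---------------------------------------------------------------------------
# static cut


def test_two_simulated_chromosomes_form_two_clusters():
    cfg = SimConfig(seed=53, n_chrom=2, n_pt_female=40, n_pt_male=0, n_nonpt=0,
                    n_progeny=150)
    truth_mat, truth = simulate_family(cfg)
    rows = truth.true_phase_rows(list(truth.markers["site_id"]))
    b = _binary(rows, progeny=truth.progeny)
    corr = binary_correlation_matrix(b)
    dist = tom_distance(np.nan_to_num(corr.squared(), nan=0.0))
    labels = cluster_static_cut(dist, ClusterParams(cut_height=0.9,
                                                    min_cluster_size=30))
    assigned = labels != UNASSIGNED
    assert len(set(labels[assigned])) == 2
    chroms = truth.markers["chrom"].to_numpy()
    for c in set(labels[assigned]):
        assert len(set(chroms[labels == c])) == 1    # clusters follow chromosomes


def test_degenerate_cut_leaves_everything_unassigned():
    rng = np.random.default_rng(1)
    b = _binary(rng.integers(0, 2, size=(10, 40)))
    corr = binary_correlation_matrix(b)
    dist = tom_distance(np.nan_to_num(corr.squared(), nan=0.0))
    with pytest.warns(UserWarning):
        labels = cluster_static_cut(dist, ClusterParams(cut_height=1e-9,
                                                        min_cluster_size=2))
    assert (labels == UNASSIGNED).all()


# ---------------------------------------------------------------------------
# diff filter


def _corr_from_means(means_by_group):
    """Build a correlation matrix giving a single query fixed group means."""
    markers = ["q"]
    vals = []
    groups = {}
    for g, (mean, size) in means_by_group.items():
        groups[g] = []
        for i in range(size):
            name = f"{g}_{i}"
            markers.append(name)
            groups[g].append(name)
            vals.append(mean)
    n = len(markers)
    V = np.zeros((n, n))
    V[0, 1:] = np.sqrt(vals)     # squared mode squares these back
    V[1:, 0] = np.sqrt(vals)
    np.fill_diagonal(V, 1.0)
    corr = CorrelationMatrix(markers=markers, values=V,
                             n_obs=np.full((n, n), 100))
    return corr, groups


@pytest.mark.parametrize("means,assigned,expected", [
    ({"g1": (0.40, 3), "g2": (0.15, 3)}, "g1", AGREE),        # 0.40 >= 2 x 0.15
    ({"g1": (0.20, 3), "g2": (0.15, 3)}, "g1", UNRESOLVED),   # 0.20 < 0.30
    ({"g1": (0.40, 3), "g2": (0.15, 3)}, "g2", DISAGREE),     # rank inversion
])
def test_diff_filter_verdicts(means, assigned, expected):
    corr, groups = _corr_from_means(means)
    out = diff_filter({"q": assigned}, groups, corr, diff=2.0, mode="squared")
    assert out["q"]["verdict"] == expected


def test_diff_filter_partitions_and_is_monotone_in_diff():
    """Raising diff never converts unresolved -> agree."""
    rng = np.random.default_rng(7)
    cfg = SimConfig(seed=59, n_chrom=3, n_pt_female=20, n_pt_male=20, n_nonpt=0,
                    n_progeny=100)
    truth_mat, truth = simulate_family(cfg)
    rows = truth.true_phase_rows(list(truth.markers["site_id"]))
    # flip a little noise in
    noise = rng.random(rows.shape) < 0.05
    rows = np.where(noise, 1 - rows, rows).astype(np.int8)
    b = _binary_from_truth(rows, truth)
    corr = binary_correlation_matrix(b)
    groups = {}
    assigned = {}
    for sid, chrom in zip(truth.markers["site_id"], truth.markers["chrom"]):
        groups.setdefault(chrom, []).append(sid)
        assigned[sid] = chrom
    verdicts = {}
    for diff in (1.5, 2.0, 3.0, 5.0):
        out = diff_filter(assigned, groups, corr, diff=diff, mode="squared")
        verdicts[diff] = {m: v["verdict"] for m, v in out.items()}
        assert set(verdicts[diff].values()) <= {AGREE, DISAGREE, UNRESOLVED}
    for lo, hi in [(1.5, 2.0), (2.0, 3.0), (3.0, 5.0)]:
        for m in verdicts[lo]:
            if verdicts[lo][m] == UNRESOLVED:
                assert verdicts[hi][m] != AGREE
            if verdicts[lo][m] == DISAGREE:                 # rank test is diff-free
                assert verdicts[hi][m] == DISAGREE


# ---------------------------------------------------------------------------
# phasing


def test_phasing_recovers_true_haplotypes_and_is_label_symmetric():
    cfg = SimConfig(seed=61, n_chrom=1, n_pt_female=80, n_pt_male=0, n_nonpt=0,
                    n_progeny=200)
    truth_mat, truth = simulate_family(cfg)
    sids = list(truth.markers["site_id"])
    # carrier encoding: 1 iff the minor-bearing haplotype was inherited
    rows = truth.true_phase_rows(sids)
    ph = truth.markers["phase_female"].to_numpy()
    b = _binary_from_truth(rows, truth)
    phase = phase_linkage_group(sids, b, ClusterParams(min_phase_size=30))
    assert phase is not None
    assigned = np.array([phase[m] for m in sids])
    agree = (assigned == ph).mean()
    assert max(agree, 1 - agree) == 1.0    # exact up to label swap


def test_phasing_reports_unphased_when_one_cluster():
    rng = np.random.default_rng(3)
    base = rng.integers(0, 2, size=60)
    rows = np.tile(base, (40, 1))
    flip = rng.random(rows.shape) < 0.02
    rows = np.where(flip, 1 - rows, rows).astype(np.int8)   # single coupling group
    b = _binary(rows)
    phase = phase_linkage_group(list(b.markers["site_id"]), b,
                                ClusterParams(min_phase_size=10))
    assert phase is None


def test_cross_chromosome_correlation_vanishes():
    """Markers on distinct chromosomes: mean |r| < 0.1 at n = 500."""
    cfg = SimConfig(seed=67, n_chrom=2, n_pt_female=25, n_pt_male=0, n_nonpt=0,
                    n_progeny=500)
    truth_mat, truth = simulate_family(cfg)
    rows = truth.true_phase_rows(list(truth.markers["site_id"]))
    b = _binary(rows, progeny=truth.progeny)
    corr = binary_correlation_matrix(b)
    chroms = truth.markers["chrom"].to_numpy()
    cross = corr.values[np.ix_(chroms == "1", chroms == "2")]
    assert np.nanmean(np.abs(cross)) < 0.1
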