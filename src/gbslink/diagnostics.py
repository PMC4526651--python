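"""Repeat diagnostics and windowed genome statistics.

The minor tag frequency (MTF) — minor-allele read depth over total read
depth at a site, pooled across progeny — exposes collapsed tandem repeats
that genotype calls cannot: a normal AB x AA pseudo-testcross site pools to
MTF 1/4 (half the progeny carry the minor allele on one of their two
haplotypes), whereas a tag collapsing two duplicated loci pools to 1/8
(the minor allele is one of four collapsed haplotype copies in carriers,
the 1:7 segregation signature).  Windowed tracks (SNP density, mean MAF,
obligate crossovers per progeny per Mb) support genome-wide review, and
runs of windows with distorted mean MAF are merged into
segregation-distortion regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from .types import AA, AB, BB, MISSING, BinaryMarkerMatrix, GeneticMap, GenotypeMatrix


def expected_mtf(n_copies: int = 1) -> float:
    """Analytic pooled minor-tag frequency of a Pt site with ``n_copies``
    collapsed locus copies (1 = normal site).

    Half the progeny carry the minor allele; in a carrier it occupies one
    of the 2 * n_copies collapsed haplotype copies, so the pooled
    expectation is (1/2) * 1/(2 n_copies): 0.25 for a normal site, 0.125
    for a two-copy duplicate.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    return 0.5 / (2.0 * n_copies)


def pooled_mtf(ad_minor: np.ndarray, ad_major: np.ndarray
               ) -> tuple[float, float]:
    """Pooled minor-tag frequency and its standard error.

    Pools reads over all (site, sample) cells.  The SE is the ratio-
    estimator SE over independent cells, which captures both read-sampling
    noise and the carrier-composition noise that dominates at Pt sites
    (whether a progeny carries the minor allele at all).
    """
    m = np.asarray(ad_minor, dtype=float).ravel()
    t = m + np.asarray(ad_major, dtype=float).ravel()
    total = t.sum()
    if total <= 0:
        return float("nan"), float("nan")
    ratio = m.sum() / total
    se = float(np.sqrt(np.sum((m - ratio * t) ** 2)) / total)
    return float(ratio), se


@dataclass
class SiteStatsResult:
    table: pd.DataFrame                  # site_id, maf, mtf, status
    density: dict                        # status -> DataFrame(x, maf_density, mtf_density)
    modes: dict                          # status -> {"maf": [...], "mtf": [...]}


def _kde_curve(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    v = values[np.isfinite(values)]
    if len(v) < 3 or np.std(v) == 0:
        return np.zeros_like(grid)
    return gaussian_kde(v, bw_method="silverman")(grid)


def _modes(grid: np.ndarray, dens: np.ndarray) -> list[float]:
    idx = argrelmax(dens, order=2)[0]
    return [float(grid[i]) for i in idx]


def maf_mtf_profile(matrix: GenotypeMatrix, final_markers: list[str],
                    removed_markers: list[str]) -> SiteStatsResult:
    """Per-site MAF (from calls) and MTF (from pooled progeny read depths).

    ``matrix`` is the raw (pre-correction) call matrix carrying AD fields;
    each site is labelled final_map / removed by membership.  Histogram
    curves use a Gaussian KDE with Silverman bandwidth; local maxima are
    reported as modes.
    """
    prog = matrix.progeny_only()
    if not (prog.ad_major.any() or prog.ad_minor.any()):
        warnings.warn("no allele-depth information: MTF is missing throughout",
                      stacklevel=2)
    called = prog.gt != MISSING
    minor = np.where(prog.gt == AB, 1, np.where(prog.gt == BB, 2, 0)) * called
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(called.sum(1) > 0, minor.sum(1) / (2.0 * called.sum(1)), np.nan)
    depth_minor = prog.ad_minor.sum(axis=1).astype(float)
    depth_total = depth_minor + prog.ad_major.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mtf = np.where(depth_total > 0, depth_minor / depth_total, np.nan)

    status = np.where(prog.sites["site_id"].isin(final_markers), "final_map",
                      np.where(prog.sites["site_id"].isin(removed_markers),
                               "removed", "other"))
    table = pd.DataFrame({"site_id": prog.sites["site_id"], "chrom": prog.sites["chrom"],
                          "pos": prog.sites["pos"], "maf": maf, "mtf": mtf,
                          "status": status})
    grid = np.linspace(0.0, 0.5, 201)
    density, modes = {}, {}
    for s in ("final_map", "removed"):
        sub = table[table["status"] == s]
        dm = _kde_curve(sub["maf"].to_numpy(), grid)
        dt = _kde_curve(sub["mtf"].to_numpy(), grid)
        density[s] = pd.DataFrame({"x": grid, "maf_density": dm, "mtf_density": dt})
        modes[s] = {"maf": _modes(grid, dm), "mtf": _modes(grid, dt)}
    return SiteStatsResult(table=table, density=density, modes=modes)


# ---------------------------------------------------------------------------
# windowed genome statistics

WINDOW_BP = 1_000_000
SLIDE_BP = 100_000
DISTORT_LO = 0.20
DISTORT_HI = 0.30


def _crossover_midpoints(gmap: GeneticMap, binary: BinaryMarkerMatrix,
                         chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """(midpoint bp, crossover count) per adjacent map-marker interval."""
    mids, counts = [], []
    for lg in gmap.lg_ids():
        t = gmap.lg_table(lg)
        t = t[t["chrom"] == chrom]
        if len(t) < 2:
            continue
        sub = binary.subset_ids(t["marker"])
        X = sub.values.copy()
        for i, ph in enumerate(t["phase"]):
            if ph == 1:
                X[i] = np.where(X[i] == MISSING, MISSING, 1 - X[i])
        pos = t["pos"].to_numpy()
        for j in range(len(t) - 1):
            ok = (X[j] != MISSING) & (X[j + 1] != MISSING)
            counts.append(int((X[j][ok] != X[j + 1][ok]).sum()))
            mids.append(0.5 * (pos[j] + pos[j + 1]))
    return np.asarray(mids, dtype=float), np.asarray(counts, dtype=float)


def windowed_genome_stats(matrix: GenotypeMatrix, gmap: GeneticMap | None = None,
                          binary: BinaryMarkerMatrix | None = None,
                          window_bp: int = WINDOW_BP, slide_bp: int = SLIDE_BP
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sliding-window SNP density, mean MAF, recombination frequency.

    Windows are half-open [start, end) intervals tiling each chromosome.
    Recombination frequency (obligate crossovers per progeny per Mb, from
    the phase-encoded map) requires ``gmap`` and ``binary``.  Contiguous
    runs of windows with mean MAF < 0.20 or > 0.30 are merged into
    segregation-distortion regions.
    """
    prog = matrix.progeny_only()
    called = prog.gt != MISSING
    minor = np.where(prog.gt == AB, 1, np.where(prog.gt == BB, 2, 0)) * called
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(called.sum(1) > 0, minor.sum(1) / (2.0 * called.sum(1)), np.nan)
    n_prog = max(len(prog.progeny_idx), 1)

    rows = []
    for chrom, sub in prog.sites.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        site_maf = maf[sub.index.to_numpy()]
        chrom_end = int(pos.max())
        xo_mid = xo_cnt = None
        if gmap is not None and binary is not None:
            xo_mid, xo_cnt = _crossover_midpoints(gmap, binary, str(chrom))
        start = 0
        while start <= chrom_end:
            end = start + window_bp
            in_w = (pos >= start) & (pos < end)
            rec = {"chrom": str(chrom), "start": start, "end": end,
                   "snp_density": int(in_w.sum()),
                   "mean_maf": float(np.nanmean(site_maf[in_w])) if in_w.any() else np.nan}
            if xo_mid is not None and len(xo_mid):
                sel = (xo_mid >= start) & (xo_mid < end)
                rec["recomb_freq"] = float(xo_cnt[sel].sum()) / n_prog \
                    / (window_bp / 1e6)
            else:
                rec["recomb_freq"] = np.nan
            rows.append(rec)
            start += slide_bp
    windows = pd.DataFrame(rows)

    regions = []
    for chrom, sub in windows.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        distorted = ((sub["mean_maf"] < DISTORT_LO) | (sub["mean_maf"] > DISTORT_HI)) \
            & sub["mean_maf"].notna()
        run_start = None
        prev_end = None
        for _, w in sub.iterrows():
            if distorted.loc[w.name]:
                if run_start is None:
                    run_start = w["start"]
                prev_end = w["end"]
            else:
                if run_start is not None:
                    regions.append({"chrom": str(chrom), "start": int(run_start),
                                    "end": int(prev_end)})
                    run_start = None
        if run_start is not None:
            regions.append({"chrom": str(chrom), "start": int(run_start),
                            "end": int(prev_end)})
    region_df = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    return windows, region_df
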