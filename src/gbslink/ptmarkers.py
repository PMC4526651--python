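"""Parent-independent identification of pseudo-testcross (Pt) markers.

A Pt marker is heterozygous in exactly one parent (AB x AA) and therefore
segregates 1:1 AB:AA in F1 progeny, i.e. 3:1 at the allele level (minor
allele frequency 0.25).  The stage identifies such sites purely from progeny
segregation and uses the genotype quality (GQ) to mask or correct the
heterozygote under-calling typical of shallow GBS data:

1. low-quality homozygous-major calls (possible under-sampled heterozygotes)
   are masked to missing;
2. confident homozygous-minor calls — impossible at a true Pt site — are
   recorded as errors and set missing;
3. low-quality homozygous-minor calls are assumed to be under-sampled
   heterozygotes and recoded AB.

Parental or grandparental genotypes, when present, are only reported for
validation — never used for selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import to_binary
from .types import (
    AA, AB, BB, MISSING,
    FLAG_CORRECTED, FLAG_ERROR, FLAG_MASKED,
    BinaryMarkerMatrix, GenotypeMatrix,
    ROLE_PROGENY,
)


@dataclass
class PtParams:
    """Thresholds of the Pt identification stage (all fractions in [0,1])."""

    allele_freq_min: float = 0.05      # alleles rarer than this are sequencing errors
    genotype_rate_min: float = 0.5     # minimum fraction of called progeny per site
    maf_center: float = 0.25
    maf_halfwidth: float = 0.125       # MAF must fall in 0.25 +/- 0.125 (closed)
    gq_threshold: int = 98             # "high quality" means GQ >= this
    site_error_max: float = 0.05       # max fraction of confident BB calls
    genotype_freq_min: float = 0.05    # a genotype class "segregates" at >= 5%

    @property
    def maf_lo(self) -> float:
        return self.maf_center - self.maf_halfwidth

    @property
    def maf_hi(self) -> float:
        return self.maf_center + self.maf_halfwidth


@dataclass
class PtAudit:
    """Per-stage site counts; categories always sum back to ``initial``."""

    initial: int = 0
    low_rate: int = 0
    monomorphic_after_seq_error: int = 0
    bad_segregation: int = 0
    low_rate_after_correction: int = 0
    high_error: int = 0
    retained: int = 0
    fraction_corrected: pd.Series = field(default_factory=pd.Series)
    fraction_masked: pd.Series = field(default_factory=pd.Series)

    def conserved(self) -> bool:
        removed = (self.low_rate + self.monomorphic_after_seq_error
                   + self.bad_segregation + self.low_rate_after_correction
                   + self.high_error)
        return self.initial == removed + self.retained

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Initial", self.initial),
            ("Low genotyping rate", self.low_rate),
            ("Monomorphic after sequencing error correction",
             self.monomorphic_after_seq_error),
            ("Incorrect segregation patterns", self.bad_segregation),
            ("Low genotyping rate after genotype error correction",
             self.low_rate_after_correction),
            ("High error rate", self.high_error),
            ("Pt markers retained", self.retained),
        ]
        return pd.DataFrame(rows, columns=["stage", "n_sites"])


def _allele_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(minor copies, called copies, called genotypes) per site, MISSING excluded."""
    called = gt != MISSING
    minor = np.where(gt == AB, 1, np.where(gt == BB, 2, 0)) * called
    return minor.sum(axis=1), 2 * called.sum(axis=1), called.sum(axis=1)


def prefilter_sites(matrix: GenotypeMatrix, params: PtParams | None = None
                    ) -> tuple[GenotypeMatrix, PtAudit]:
    """Remove low-genotyping-rate sites, erase rare alleles, drop monomorphics.

    Allele frequencies use allele copies (2N called progeny as denominator).
    Erasing a rare allele from a heterozygote leaves the homozygote of the
    kept allele; a call consisting only of erased alleles becomes MISSING.
    """
    params = params or PtParams()
    prog = matrix.progeny_only()
    if prog.n_samples == 0:
        raise ValueError("no progeny samples in matrix")
    audit = PtAudit(initial=prog.n_sites)

    called = prog.gt != MISSING
    rate = called.mean(axis=1)
    low = rate < params.genotype_rate_min
    audit.low_rate = int(low.sum())
    prog = prog.take_sites(~low)

    minor_copies, total_copies, _ = _allele_counts(prog.gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_freq = np.where(total_copies > 0, minor_copies / total_copies, 0.0)
    major_freq = 1.0 - minor_freq

    gt = prog.gt.copy()
    erase_minor = minor_freq < params.allele_freq_min
    erase_major = major_freq < params.allele_freq_min  # only possible at freq 0.5 ties
    # AB with the rare allele erased collapses to the kept homozygote;
    # a homozygote of an erased allele has no allele left -> MISSING
    rows = np.flatnonzero(erase_minor)
    for i in rows:
        gt[i, gt[i] == AB] = AA
        gt[i, gt[i] == BB] = MISSING
    rows = np.flatnonzero(erase_major & ~erase_minor)
    for i in rows:
        gt[i, gt[i] == AB] = BB
        gt[i, gt[i] == AA] = MISSING
    prog.gt = gt

    minor_copies, total_copies, _ = _allele_counts(prog.gt)
    mono = (minor_copies == 0) | (minor_copies == total_copies)
    audit.monomorphic_after_seq_error = int(mono.sum())
    prog = prog.take_sites(~mono)
    return prog, audit


def select_candidate_sites(matrix: GenotypeMatrix, params: PtParams | None = None,
                           audit: PtAudit | None = None) -> GenotypeMatrix:
    """Keep sites with Pt-like segregation (computed over called progeny).

    Conditions (all closed intervals): two segregating alleles each at
    frequency >= 5%; at least two genotype classes each at frequency >= 5%;
    minor allele frequency within 0.25 +/- 0.125 (major within 0.75 -/+).
    """
    params = params or PtParams()
    gt = matrix.gt
    minor_copies, total_copies, n_called = _allele_counts(gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total_copies > 0, minor_copies / total_copies, 0.0)

    two_alleles = (maf >= params.allele_freq_min) & (1.0 - maf >= params.allele_freq_min)
    n_called_safe = np.maximum(n_called, 1)
    geno_freqs = np.stack([(gt == g).sum(axis=1) / n_called_safe for g in (AA, AB, BB)])
    n_segregating = (geno_freqs >= params.genotype_freq_min).sum(axis=0)
    maf_ok = (maf >= params.maf_lo) & (maf <= params.maf_hi)

    keep = two_alleles & (n_segregating >= 2) & maf_ok & (n_called > 0)
    if audit is not None:
        audit.bad_segregation = int((~keep).sum())
    return matrix.take_sites(keep)


def correct_pt_genotypes(matrix: GenotypeMatrix, params: PtParams | None = None
                         ) -> GenotypeMatrix:
    """Apply the GQ-driven masking/correction rules to candidate Pt sites."""
    params = params or PtParams()
    out = matrix.copy()
    low_q = out.gq < params.gq_threshold
    aa, bb = out.gt == AA, out.gt == BB

    mask = aa & low_q
    out.gt[mask] = MISSING
    out.flag[mask] = FLAG_MASKED

    err = bb & ~low_q
    out.gt[err] = MISSING
    out.flag[err] = FLAG_ERROR

    corr = bb & low_q
    out.gt[corr] = AB
    out.flag[corr] = FLAG_CORRECTED
    return out


def identify_pt_markers(matrix: GenotypeMatrix, params: PtParams | None = None
                        ) -> tuple[GenotypeMatrix, BinaryMarkerMatrix, PtAudit, pd.DataFrame]:
    """Full Pt stage: prefilter, candidate selection, correction, post-filter.

    Returns the corrected progeny matrix restricted to retained Pt markers,
    its binary (minor-allele presence) encoding, the per-stage audit, and a
    table of high-quality progenitor genotypes at the retained loci (empty
    when no parents/grandparents are present; never used for selection).
    """
    params = params or PtParams()
    prefiltered, audit = prefilter_sites(matrix, params)
    candidates = select_candidate_sites(prefiltered, params, audit)
    pre_correction = candidates.copy()
    corrected = correct_pt_genotypes(candidates, params)

    called = corrected.gt != MISSING
    rate_ok = called.mean(axis=1) >= params.genotype_rate_min if corrected.n_samples else \
        np.zeros(corrected.n_sites, dtype=bool)
    audit.low_rate_after_correction = int((~rate_ok).sum())

    pre_called = (pre_correction.gt != MISSING).sum(axis=1)
    n_err = ((pre_correction.gt == BB) & (pre_correction.gq >= params.gq_threshold)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        err_rate = np.where(pre_called > 0, n_err / pre_called, 0.0)
    err_ok = err_rate <= params.site_error_max
    audit.high_error = int((rate_ok & ~err_ok).sum())

    keep = rate_ok & err_ok
    retained = corrected.take_sites(keep)
    audit.retained = retained.n_sites

    ids = retained.sites["site_id"]
    n_prog = max(retained.n_samples, 1)
    audit.fraction_corrected = pd.Series(
        (retained.flag == FLAG_CORRECTED).mean(axis=1), index=ids, name="fraction_corrected")
    audit.fraction_masked = pd.Series(
        (retained.flag == FLAG_MASKED).mean(axis=1), index=ids, name="fraction_masked")

    binary = to_binary(retained)
    progenitors = _progenitor_table(matrix, retained.sites, params)
    return retained, binary, audit, progenitors


def _progenitor_table(matrix: GenotypeMatrix, retained_sites: pd.DataFrame,
                      params: PtParams) -> pd.DataFrame:
    """High-GQ parental/grandparental genotypes at retained Pt loci."""
    prog_roles = {ROLE_PROGENY}
    idx = [i for i, r in enumerate(matrix.roles) if r not in prog_roles]
    if not idx:
        return pd.DataFrame(index=pd.Index(retained_sites["site_id"], name="site_id"))
    sub = matrix.take_samples(idx)
    pos = sub.site_index(retained_sites["site_id"])
    gt = sub.gt[pos].copy()
    gt[sub.gq[pos] < params.gq_threshold] = MISSING
    labels = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
    data = {s: [labels[int(g)] for g in gt[:, j]] for j, s in enumerate(sub.samples)}
    return pd.DataFrame(data, index=pd.Index(retained_sites["site_id"], name="site_id"))
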