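"""Family-level quality control: pollen contaminants, selfs, mislabels.

Two independent signals are combined: (1) a Yang-type genomic relatedness
of every progeny to each parent, and (2) trio Mendelian-incompatibility
counts split by which parent the incompatible allele implicates.  A self of
the maternal parent looks over-related to the mother, under-related to the
father, and strongly enriched for male-incompatible genotypes.  Progeny are
flagged on the *intersection* of the two outlier sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AA, AB, BB, MISSING, GenotypeMatrix

_MAD_FLOOR = 1e-6


@dataclass
class QcReport:
    table: pd.DataFrame          # per-progeny statistics and flags
    relatedness_outliers: list[str]
    mendelian_outliers: list[str]
    flagged: list[str]
    auto_flagging: bool          # False when too few progeny for the MAD rule


def relatedness_matrix(matrix: GenotypeMatrix, gq_min: int = 98) -> pd.DataFrame:
    """Yang relatedness of each progeny to each parent.

    A_jk = mean over usable sites of (g_j - 2p)(g_k - 2p) / (2p(1-p)) with
    g the minor-allele dosage and p the minor allele frequency across all
    samples at the site.  Sites where either call is below ``gq_min``,
    missing, or where p is 0 or 1 are excluded per pair; a pair with no
    usable site gets NaN.
    """
    mi, fi = matrix.mother_idx, matrix.father_idx
    if mi is None or fi is None:
        raise ValueError("both parents must be present for relatedness")
    gt = matrix.gt
    ok = (gt != MISSING) & (matrix.gq >= gq_min)
    dosage = np.where(gt == AB, 1.0, np.where(gt == BB, 2.0, 0.0))

    copies = (dosage * ok).sum(axis=1)
    called = ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, copies / (2.0 * called), np.nan)
    usable_site = (p > 0) & (p < 1)

    rows = []
    prog_idx = matrix.progeny_idx
    for pi, pname in ((mi, "mother"), (fi, "father")):
        centered_p = dosage[:, pi] - 2.0 * p
        ok_p = ok[:, pi]
        for j in prog_idx:
            use = usable_site & ok_p & ok[:, j]
            if not use.any():
                rows.append({"sample": matrix.samples[j], "parent": pname,
                             "relatedness": np.nan, "n_sites": 0})
                continue
            num = (dosage[use, j] - 2.0 * p[use]) * centered_p[use]
            den = 2.0 * p[use] * (1.0 - p[use])
            rows.append({"sample": matrix.samples[j], "parent": pname,
                         "relatedness": float(np.mean(num / den)),
                         "n_sites": int(use.sum())})
    long = pd.DataFrame(rows)
    return long.pivot(index="sample", columns="parent", values="relatedness") \
               .reindex([matrix.samples[j] for j in prog_idx])


def mendelian_incompatibilities(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Counts of progeny alleles absent from each parent's called genotype.

    A site counts only when both parents and the progeny are called; a call
    carrying an allele with zero copies in the father increments the
    male-incompatible count (likewise mother/female), and one call may
    increment both.
    """
    mi, fi = matrix.mother_idx, matrix.father_idx
    if mi is None or fi is None:
        raise ValueError("both parents must be present for Mendelian checks")
    gt = matrix.gt
    trio_ok = (gt[:, mi] != MISSING) & (gt[:, fi] != MISSING)

    has_major = gt != BB     # call contains >= 1 major allele (AA or AB)
    has_minor = gt != AA     # call contains >= 1 minor allele

    rows = []
    for j in matrix.progeny_idx:
        ok = trio_ok & (gt[:, j] != MISSING)
        male_bad = ((has_major[:, j] & ~has_major[:, fi])
                    | (has_minor[:, j] & ~has_minor[:, fi])) & ok
        female_bad = ((has_major[:, j] & ~has_major[:, mi])
                      | (has_minor[:, j] & ~has_minor[:, mi])) & ok
        rows.append({"sample": matrix.samples[j],
                     "n_male_incompatible": int(male_bad.sum()),
                     "n_female_incompatible": int(female_bad.sum())})
    return pd.DataFrame(rows).set_index("sample")


def flag_suspect_progeny(matrix: GenotypeMatrix, gq_min: int = 98,
                         rel_mad_k: float = 4.0, ratio_min: float = 3.0) -> QcReport:
    """Intersection of relatedness outliers and Mendelian-error outliers.

    Relatedness outliers deviate from the progeny median by more than
    ``rel_mad_k`` median absolute deviations in either parent coordinate.
    Mendelian outliers have (male+1)/(female+1) incompatibility ratio of at
    least ``ratio_min`` with the male count above the progeny median.  With
    fewer than 10 progeny automatic flagging is refused (report only).
    """
    rel = relatedness_matrix(matrix, gq_min=gq_min)
    mend = mendelian_incompatibilities(matrix)
    table = rel.join(mend)
    table["incompat_ratio"] = ((table["n_male_incompatible"] + 1.0)
                               / (table["n_female_incompatible"] + 1.0))

    n_prog = len(table)
    auto = n_prog >= 10
    rel_out: list[str] = []
    mend_out: list[str] = []
    if auto:
        for col in ("mother", "father"):
            x = table[col].to_numpy(dtype=float)
            med = np.nanmedian(x)
            mad = max(np.nanmedian(np.abs(x - med)), _MAD_FLOOR)
            hit = np.abs(x - med) > rel_mad_k * mad
            rel_out.extend(table.index[np.nan_to_num(hit, nan=False)])
        rel_out = sorted(set(rel_out))
        male_med = table["n_male_incompatible"].median()
        hit = (table["incompat_ratio"] >= ratio_min) & \
            (table["n_male_incompatible"] > male_med)
        mend_out = sorted(table.index[hit])
    flagged = sorted(set(rel_out) & set(mend_out))

    table["relatedness_outlier"] = table.index.isin(rel_out)
    table["mendelian_outlier"] = table.index.isin(mend_out)
    table["flagged"] = table.index.isin(flagged)
    reason = np.select(
        [table["flagged"],
         table["relatedness_outlier"] & ~table["mendelian_outlier"],
         table["mendelian_outlier"] & ~table["relatedness_outlier"]],
        ["both", "relatedness", "mendelian"], default="")
    table["reason"] = reason
    return QcReport(table=table, relatedness_outliers=rel_out,
                    mendelian_outliers=mend_out, flagged=flagged,
                    auto_flagging=auto)


def drop_flagged(matrix: GenotypeMatrix, flagged: list[str]) -> GenotypeMatrix:
    """Remove flagged samples, then sites invariant or all-missing in the rest."""
    keep = [i for i, s in enumerate(matrix.samples) if s not in set(flagged)]
    out = matrix.take_samples(keep)
    prog = out.progeny_only()
    called = prog.gt != MISSING
    n_called = called.sum(axis=1)
    minor = (np.where(prog.gt == AB, 1, np.where(prog.gt == BB, 2, 0)) * called).sum(axis=1)
    informative = (n_called > 0) & (minor > 0) & (minor < 2 * n_called)
    return out.take_sites(informative)
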