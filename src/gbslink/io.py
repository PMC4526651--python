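"""Readers and writers: VCF (both allele-order dialects), binary marker
tables, and R/qtl "csvsr" cross files.

VCF genotypes are re-expressed on the family's major/minor axis at read
time.  The TASSEL-GBS dialect already lists alleles in major/minor order;
standard ref/alt VCFs are converted by computing allele frequencies across
all samples and swapping when the alternate allele is the majority one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    AA, AB, BB, MISSING,
    FLAG_CORRECTED, FLAG_ERROR, FLAG_LABELS, FLAG_MASKED, FLAG_NONE,
    BinaryMarkerMatrix, GenotypeMatrix,
    ROLE_FATHER, ROLE_GRANDPARENT, ROLE_MOTHER, ROLE_PROGENY,
    make_site_table,
)

_FLAG_FROM_LABEL = {v: k for k, v in FLAG_LABELS.items()}


# ---------------------------------------------------------------------------
# VCF


def read_genotype_vcf(path, allele_order: str = "major_minor",
                      mother: str | None = None, father: str | None = None,
                      grandparents: tuple = ()) -> GenotypeMatrix:
    """Load a multi-sample VCF into a GenotypeMatrix.

    Parameters
    ----------
    allele_order : "major_minor" (TASSEL-GBS dialect, allele 0 is the major
        allele) or "ref_alt" (standard; major/minor recomputed from sample
        allele frequencies and calls re-coded).
    mother, father, grandparents : sample names to assign those roles; all
        other samples are progeny.

    Multi-allelic sites are skipped (with a warning reporting the count);
    absent GQ is recorded as 0 and absent AD as 0/0.
    """
    if allele_order not in ("major_minor", "ref_alt"):
        raise ValueError("allele_order must be 'major_minor' or 'ref_alt'")
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    roles = []
    for s in samples:
        if s == mother:
            roles.append(ROLE_MOTHER)
        elif s == father:
            roles.append(ROLE_FATHER)
        elif s in grandparents:
            roles.append(ROLE_GRANDPARENT)
        else:
            roles.append(ROLE_PROGENY)

    chroms, poss, majors, minors = [], [], [], []
    gts, gqs, adm, adn, flags = [], [], [], [], []
    n_multi = 0
    for rec_no, v in enumerate(vcf, start=1):
        try:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            gt01 = np.array([g[:2] for g in v.genotypes], dtype=object)
            a = np.array([-1 if x is None or x < 0 else x for x in gt01[:, 0]])
            b = np.array([-1 if x is None or x < 0 else x for x in gt01[:, 1]])
            code = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)

            gq = v.gt_quals
            gq = np.where(np.isnan(gq) | (gq < 0), 0, gq).astype(np.int16)
            try:
                ad = v.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                a0 = np.zeros(len(samples), dtype=np.int32)
                a1 = np.zeros(len(samples), dtype=np.int32)
            else:
                ad = np.where(ad < 0, 0, ad)
                a0 = ad[:, 0].astype(np.int32)
                a1 = ad[:, 1].astype(np.int32) if ad.shape[1] > 1 else np.zeros_like(a0)
            try:
                fl = v.format("FL")
            except KeyError:
                fl = None
            if fl is None:
                flag = np.zeros(len(samples), dtype=np.int8)
            else:
                flag = np.array([_FLAG_FROM_LABEL.get(str(x).strip("\x00"), FLAG_NONE)
                                 for x in np.ravel(fl)], dtype=np.int8)

            major, minor = v.REF, v.ALT[0]
            if allele_order == "ref_alt":
                called = code != MISSING
                alt_copies = code[called].sum()
                if called.sum() and alt_copies > called.sum():  # alt freq > 0.5
                    code = np.where(code == MISSING, MISSING, 2 - code).astype(np.int8)
                    a0, a1 = a1, a0
                    major, minor = minor, major
            chroms.append(v.CHROM)
            poss.append(v.POS)
            majors.append(major)
            minors.append(minor)
            gts.append(code)
            gqs.append(gq)
            adm.append(a0)
            adn.append(a1)
            flags.append(flag)
        except Exception as exc:  # noqa: BLE001 - surface the offending record
            raise ValueError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic site(s)", stacklevel=2)

    sites = make_site_table(chroms, poss, majors, minors)
    gm = GenotypeMatrix.empty(sites, samples, roles)
    if gts:
        gm.gt = np.vstack(gts)
        gm.gq = np.vstack(gqs)
        gm.ad_major = np.vstack(adm)
        gm.ad_minor = np.vstack(adn)
        gm.flag = np.vstack(flags)
    gm.n_multiallelic_skipped = n_multi
    return gm


def write_marker_vcf(matrix: GenotypeMatrix, path) -> str:
    """Write a GenotypeMatrix as VCF 4.2 with GT:AD:GQ:FL per call.

    REF holds the major and ALT the minor allele (documented in the header);
    FL records the masked (M) / error (E) / corrected (C) states.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##source=gbslink')
    header.add_line('##gbslink_allele_order=major_minor (REF=major allele, ALT=minor allele)')
    for chrom in dict.fromkeys(matrix.sites["chrom"]):
        maxpos = int(matrix.sites.loc[matrix.sites["chrom"] == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=maxpos + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", 2, "Integer", "Read depth per allele (major,minor)")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    header.formats.add("FL", 1, "String",
                       "Correction flag: .=none M=masked E=error C=corrected")
    for s in matrix.samples:
        header.add_sample(s)

    gt_tuple = {AA: (0, 0), AB: (0, 1), BB: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(matrix.n_sites):
            row = matrix.sites.iloc[i]
            rec = out.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(str(row["major"]), str(row["minor"])), id=str(row["site_id"]),
            )
            for j, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_tuple[int(matrix.gt[i, j])]
                rec.samples[s]["AD"] = (int(matrix.ad_major[i, j]), int(matrix.ad_minor[i, j]))
                rec.samples[s]["GQ"] = int(matrix.gq[i, j])
                rec.samples[s]["FL"] = FLAG_LABELS[int(matrix.flag[i, j])]
            out.write(rec)
    return str(path)


# ---------------------------------------------------------------------------
# binary marker matrix


def to_binary(matrix: GenotypeMatrix) -> BinaryMarkerMatrix:
    """Presence/absence of the minor allele for corrected Pt markers.

    AB -> 1, AA -> 0, anything else MISSING.  A remaining BB call violates
    the Pt contract (correction must have removed them) and raises.
    """
    prog = matrix.progeny_only()
    if (prog.gt == BB).any():
        bad = prog.sites.loc[(prog.gt == BB).any(axis=1), "site_id"].tolist()
        raise ValueError(f"BB calls present at Pt markers (post-correction): {bad[:5]}")
    values = np.where(prog.gt == AB, 1, np.where(prog.gt == AA, 0, MISSING)).astype(np.int8)
    return BinaryMarkerMatrix(markers=prog.sites.copy(), progeny=list(prog.samples),
                              values=values)


def write_binary_table(binary: BinaryMarkerMatrix, path) -> str:
    """Tab-separated table: site_id, chrom, pos, then 0/1/NA per progeny."""
    df = binary.to_frame().replace(MISSING, pd.NA)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return str(path)


def read_binary_table(path) -> BinaryMarkerMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    progeny = [c for c in df.columns if c not in ("site_id", "chrom", "pos")]
    values = df[progeny].to_numpy(dtype=float)
    values = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    markers = pd.DataFrame({
        "chrom": df["chrom"].astype(str), "pos": df["pos"].astype(np.int64),
        "major": "A", "minor": "B", "site_id": df["site_id"],
    })
    return BinaryMarkerMatrix(markers=markers, progeny=progeny, values=values)


# ---------------------------------------------------------------------------
# R/qtl csvsr cross files

#: 4-way codes: the inherited phase of the informative parent, female first.
#: Female-informative markers: inherited haplotype 0 -> 5, 1 -> 6 (maternal
#: origin known, paternal unknown); male-informative: 0 -> 7, 1 -> 8.
FOURWAY_FEMALE = {0: "5", 1: "6"}
FOURWAY_MALE = {0: "7", 1: "8"}
BC_CODES = {1: "H", 0: "A", MISSING: "-"}


def write_crossfile(genetic_map, genotypes: BinaryMarkerMatrix, path,
                    fmt: str = "BC", phenotypes: pd.DataFrame | None = None) -> str:
    """Rotated (markers-as-rows) R/qtl "csvsr" cross file.

    BC alphabet {A, H, -} encodes absence/presence of the minor allele;
    FOURWAY encodes the informative parent's phase origin per progeny using
    codes 5-8 (see module constants).  Optional phenotype columns are
    emitted as leading rows with blank LG/cM cells.
    """
    if fmt not in ("BC", "FOURWAY"):
        raise ValueError("format must be 'BC' or 'FOURWAY'")
    table = genetic_map.table
    missing_markers = set(table["marker"]) - set(genotypes.markers["site_id"])
    if missing_markers:
        raise ValueError(f"markers absent from genotype matrix: {sorted(missing_markers)[:5]}")
    sub = genotypes.subset_ids(table["marker"])
    progeny = sub.progeny

    rows = []
    if phenotypes is not None:
        missing_prog = set(progeny) - set(phenotypes.index)
        if missing_prog:
            raise ValueError(f"progeny absent from phenotype table: {sorted(missing_prog)[:5]}")
        for pheno in phenotypes.columns:
            vals = [str(phenotypes.loc[p, pheno]) for p in progeny]
            rows.append([pheno, "", ""] + vals)

    parent_of_lg = dict(zip(table["lg"], table["parent"]))
    for i, rec in enumerate(table.itertuples(index=False)):
        vals = sub.values[i]
        if fmt == "BC":
            codes = [BC_CODES[int(v)] for v in vals]
        else:
            lut = FOURWAY_MALE if parent_of_lg.get(rec.lg) == "male" else FOURWAY_FEMALE
            ph = int(rec.phase)
            # carrier inherits the minor-bearing haplotype (= marker phase)
            codes = ["-" if v == MISSING else lut[ph if v == 1 else 1 - ph]
                     for v in vals]
        rows.append([rec.marker, str(rec.lg), f"{rec.cM:.3f}"] + codes)

    out = pd.DataFrame(rows, columns=["id", "lg", "cM"] + list(progeny))
    out.to_csv(path, index=False)
    return str(path)


@dataclass
class CrossFile:
    """Parsed csvsr content: marker table plus genotype-code grid."""

    markers: pd.DataFrame       # id, lg, cM
    progeny: list[str]
    codes: pd.DataFrame         # markers x progeny, string codes
    phenotypes: pd.DataFrame | None


def read_crossfile(path) -> CrossFile:
    df = pd.read_csv(path, dtype=str)
    progeny = list(df.columns[3:])
    is_pheno = df["lg"].isna() | (df["lg"] == "")
    pheno = df[is_pheno]
    body = df[~is_pheno]
    markers = pd.DataFrame({
        "id": body["id"].values, "lg": body["lg"].values,
        "cM": body["cM"].astype(float).values,
    })
    codes = body[progeny].reset_index(drop=True)
    phenotypes = None
    if len(pheno):
        phenotypes = pheno.set_index("id")[progeny].T
    return CrossFile(markers=markers, progeny=progeny, codes=codes, phenotypes=phenotypes)
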