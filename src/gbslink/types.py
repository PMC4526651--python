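"""Core containers for GBS genotype data in F1 mapping families.

Genotypes are always expressed relative to the *major/minor* allele of a
site within the family (the TASSEL-GBS convention), not reference/alternate:
``AA`` is homozygous major, ``AB`` heterozygous, ``BB`` homozygous minor.
Calls live in dense numpy arrays (sites x samples) with integer codes so the
whole pipeline stays vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# genotype codes
AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

GT_LABELS = {AA: "AA", AB: "AB", BB: "BB", MISSING: "./."}

# per-call flags set during Pt-marker error correction
FLAG_NONE: int = 0
FLAG_MASKED: int = 1     # low-quality homozygous-major call converted to missing
FLAG_ERROR: int = 2      # confident homozygous-minor call, impossible at a Pt site
FLAG_CORRECTED: int = 3  # low-quality homozygous-minor call recoded as heterozygous

FLAG_LABELS = {FLAG_NONE: ".", FLAG_MASKED: "M", FLAG_ERROR: "E", FLAG_CORRECTED: "C"}

ROLE_PROGENY = "progeny"
ROLE_MOTHER = "mother"
ROLE_FATHER = "father"
ROLE_GRANDPARENT = "grandparent"
ROLE_OTHER = "other"

SITE_COLUMNS = ["chrom", "pos", "major", "minor", "site_id"]


def site_id(chrom: str, pos: int) -> str:
    """Marker name in the community S{chromosome}_{position} convention."""
    return f"S{chrom}_{pos}"


def make_site_table(chrom, pos, major, minor) -> pd.DataFrame:
    """Assemble a site table; validates coordinates and allele symbols."""
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "major": np.asarray(major, dtype=object),
            "minor": np.asarray(minor, dtype=object),
        }
    )
    if (df["pos"] < 1).any():
        raise ValueError("site positions must be 1-based (pos >= 1)")
    if (df["major"] == df["minor"]).any():
        raise ValueError("major and minor allele must differ at every site")
    df["site_id"] = [site_id(c, p) for c, p in zip(df["chrom"], df["pos"])]
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site ids: {dups[:5]}")
    return df.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype calls with per-call quality and allele depths.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos, major, minor, site_id.
    samples : sample identifiers (columns of the call grid).
    roles : one of progeny/mother/father/grandparent/other per sample.
    gt : int8 array of genotype codes (AA/AB/BB/MISSING).
    gq : int16 array of phred-scaled genotype qualities (0 when absent).
    ad_major, ad_minor : int32 read depths per allele (0 when absent).
    flag : int8 array of correction flags.
    """

    sites: pd.DataFrame
    samples: list[str]
    roles: list[str]
    gt: np.ndarray
    gq: np.ndarray
    ad_major: np.ndarray
    ad_minor: np.ndarray
    flag: np.ndarray

    def __post_init__(self) -> None:
        m, n = len(self.sites), len(self.samples)
        for name in ("gt", "gq", "ad_major", "ad_minor", "flag"):
            arr = getattr(self, name)
            if arr.shape != (m, n):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(m, n)}")
        if len(self.roles) != n:
            raise ValueError("roles must align with samples")
        for role in (ROLE_MOTHER, ROLE_FATHER):
            if self.roles.count(role) > 1:
                raise ValueError(f"role {role!r} appears more than once")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def empty(cls, sites: pd.DataFrame, samples: list[str], roles: list[str]) -> "GenotypeMatrix":
        m, n = len(sites), len(samples)
        return cls(
            sites=sites.reset_index(drop=True),
            samples=list(samples),
            roles=list(roles),
            gt=np.full((m, n), MISSING, dtype=np.int8),
            gq=np.zeros((m, n), dtype=np.int16),
            ad_major=np.zeros((m, n), dtype=np.int32),
            ad_minor=np.zeros((m, n), dtype=np.int32),
            flag=np.zeros((m, n), dtype=np.int8),
        )

    # -- basic accessors ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def progeny_idx(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == ROLE_PROGENY], dtype=int)

    @property
    def mother_idx(self) -> int | None:
        return self.roles.index(ROLE_MOTHER) if ROLE_MOTHER in self.roles else None

    @property
    def father_idx(self) -> int | None:
        return self.roles.index(ROLE_FATHER) if ROLE_FATHER in self.roles else None

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=list(self.samples),
            roles=list(self.roles),
            gt=self.gt.copy(),
            gq=self.gq.copy(),
            ad_major=self.ad_major.copy(),
            ad_minor=self.ad_minor.copy(),
            flag=self.flag.copy(),
        )

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset to a site selection (boolean mask or integer positions)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            roles=list(self.roles),
            gt=self.gt[index],
            gq=self.gq[index],
            ad_major=self.ad_major[index],
            ad_minor=self.ad_minor[index],
            flag=self.flag[index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=[self.samples[i] for i in index],
            roles=[self.roles[i] for i in index],
            gt=self.gt[:, index],
            gq=self.gq[:, index],
            ad_major=self.ad_major[:, index],
            ad_minor=self.ad_minor[:, index],
            flag=self.flag[:, index],
        )

    def progeny_only(self) -> "GenotypeMatrix":
        return self.take_samples(self.progeny_idx)

    def site_index(self, ids) -> np.ndarray:
        """Positions of the given site_ids (raises on unknown ids)."""
        lookup = pd.Index(self.sites["site_id"])
        pos = lookup.get_indexer(ids)
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"unknown site ids: {missing[:5]}")
        return pos


@dataclass
class BinaryMarkerMatrix:
    """Pt markers x progeny presence (1) / absence (0) of the minor allele.

    ``values`` uses the same MISSING code (-1) as GenotypeMatrix.
    """

    markers: pd.DataFrame
    progeny: list[str]
    values: np.ndarray  # int8, (n_markers, n_progeny)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.markers), len(self.progeny)):
            raise ValueError("values grid does not match markers x progeny")
        bad = ~np.isin(self.values, [0, 1, MISSING])
        if bad.any():
            raise ValueError("binary values must be 0, 1 or MISSING")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return list(self.markers["site_id"])

    def take_markers(self, index) -> "BinaryMarkerMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return BinaryMarkerMatrix(
            markers=self.markers.iloc[index].reset_index(drop=True),
            progeny=list(self.progeny),
            values=self.values[index],
        )

    def subset_ids(self, ids) -> "BinaryMarkerMatrix":
        lookup = pd.Index(self.markers["site_id"])
        pos = lookup.get_indexer(ids)
        if (pos < 0).any():
            raise KeyError("unknown marker ids in subset")
        return self.take_markers(pos)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.progeny)
        df.insert(0, "pos", self.markers["pos"].values)
        df.insert(0, "chrom", self.markers["chrom"].values)
        df.insert(0, "site_id", self.markers["site_id"].values)
        return df


@dataclass
class LinkageGroup:
    """A set of phased markers attributed to one parent and one chromosome."""

    lg_id: str
    markers: list[str]
    phase: dict = field(default_factory=dict)  # site_id -> 0/1 (may be absent if unphased)
    parent: str = "unknown"                    # female / male / unknown / unknown-A / unknown-B
    chrom_label: str = ""
    provenance: str = ""                       # synteny / denovo / simulated

    @property
    def phased(self) -> bool:
        return bool(self.phase)

    def phase_array(self) -> np.ndarray:
        return np.array([self.phase[m] for m in self.markers], dtype=np.int8)


@dataclass
class GeneticMap:
    """Ordered markers with Kosambi cM positions, one table row per marker.

    ``table`` columns: marker, lg, parent, phase, cM, chrom, pos, n_missing.
    Within each LG positions start at 0 and are nondecreasing.
    """

    table: pd.DataFrame

    def lg_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["lg"]))

    def lg_table(self, lg: str) -> pd.DataFrame:
        return self.table[self.table["lg"] == lg]

    def lg_length(self, lg: str) -> float:
        t = self.lg_table(lg)
        return float(t["cM"].max() - t["cM"].min()) if len(t) else 0.0

    def total_length(self) -> float:
        return float(sum(self.lg_length(lg) for lg in self.lg_ids()))

    def n_markers(self) -> int:
        return len(self.table)
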