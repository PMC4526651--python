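"""Reference-guided linkage-group formation.

Markers are first grouped by the chromosome their tags aligned to; markers
on unanchored/"random" pseudo-chromosomes are dropped.  Each marker's
linkage (mean squared correlation) with every chromosome group is ranked:
only markers whose aligned chromosome wins by the ``diff`` ratio are kept
("agree").  Kept markers are then clustered within each chromosome (r^2
adjacency, TOM distance, static cut) into one linkage group per parent —
or more, when a parent's contribution splits — and each LG is phased.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import (
    AGREE, DISAGREE, UNRESOLVED, UNASSIGNED,
    ClusterParams, CorrelationMatrix,
    binary_correlation_matrix, cluster_static_cut, diff_filter,
    phase_linkage_group, tom_distance,
)
from .types import BinaryMarkerMatrix, LinkageGroup

#: chromosomes whose label matches are treated as unanchored ("random")
#: pseudo-chromosomes; the default matches the trailing-"00" renaming
#: convention (e.g. "200" for 2_random) and the "999" unknown bucket.
DEFAULT_RANDOM_PATTERN = r"(?:.+00|999)"


@dataclass
class ChromosomeGroupAudit:
    initial: int = 0
    random_chrom: int = 0
    disagree: int = 0
    unresolved: int = 0
    agree: int = 0

    def conserved(self) -> bool:
        return self.initial == (self.random_chrom + self.disagree
                                + self.unresolved + self.agree)

    def to_frame(self) -> pd.DataFrame:
        rows = [("Initial", self.initial),
                ("Markers on random chromosomes", self.random_chrom),
                ('In linkage with another chromosome ("Disagree")', self.disagree),
                ('In linkage with multiple chromosomes ("Unresolved")', self.unresolved),
                ('In linkage with aligned chromosome ("Agree")', self.agree)]
        return pd.DataFrame(rows, columns=["stage", "n_markers"])


def assign_chromosome_groups(binary: BinaryMarkerMatrix,
                             random_pattern: str = DEFAULT_RANDOM_PATTERN
                             ) -> tuple[dict[str, list[str]], ChromosomeGroupAudit]:
    """Group markers by aligned chromosome, dropping unanchored ones."""
    audit = ChromosomeGroupAudit(initial=binary.n_markers)
    pat = re.compile(random_pattern)
    chroms = binary.markers["chrom"].astype(str)
    is_random = chroms.map(lambda c: bool(pat.fullmatch(c)))
    audit.random_chrom = int(is_random.sum())
    kept = binary.markers[~is_random.values]
    groups: dict[str, list[str]] = {}
    for chrom, sub in kept.groupby("chrom", sort=True):
        groups[str(chrom)] = list(sub["site_id"])
    if not groups:
        raise ValueError("no markers on assembled chromosomes")
    return groups, audit


@dataclass
class SyntenyResult:
    linkage_groups: list[LinkageGroup]
    audit: ChromosomeGroupAudit
    verdicts: pd.DataFrame                # marker, chrom, verdict
    unclustered: list[str] = field(default_factory=list)
    unphased_lgs: list[str] = field(default_factory=list)


def build_synteny_lgs(groups: dict[str, list[str]], binary: BinaryMarkerMatrix,
                      params: ClusterParams | None = None,
                      audit: ChromosomeGroupAudit | None = None,
                      min_pairs: int = 20) -> SyntenyResult:
    """Mis-assignment filter, per-chromosome LG separation, phasing."""
    params = params or ClusterParams()
    audit = audit or ChromosomeGroupAudit(
        initial=sum(len(v) for v in groups.values()))

    order = [m for chrom in groups for m in groups[chrom]]
    sub = binary.subset_ids(order)
    corr = binary_correlation_matrix(sub, min_pairs=min_pairs)
    assigned = {m: chrom for chrom, members in groups.items() for m in members}
    verdicts = diff_filter(assigned, groups, corr, diff=params.diff, mode="squared")

    vrows = [{"marker": m, "chrom": assigned[m], "verdict": v["verdict"]}
             for m, v in verdicts.items()]
    vdf = pd.DataFrame(vrows)
    audit.disagree = int((vdf["verdict"] == DISAGREE).sum())
    audit.unresolved = int((vdf["verdict"] == UNRESOLVED).sum())
    audit.agree = int((vdf["verdict"] == AGREE).sum())

    lgs: list[LinkageGroup] = []
    unclustered: list[str] = []
    unphased: list[str] = []
    for chrom in groups:
        keep = [m for m in groups[chrom] if verdicts[m]["verdict"] == AGREE]
        if len(keep) < params.min_cluster_size:
            warnings.warn(f"chromosome {chrom}: only {len(keep)} agreeing markers; skipped",
                          stacklevel=2)
            unclustered.extend(keep)
            continue
        csub = binary.subset_ids(keep)
        ccorr = binary_correlation_matrix(csub, min_pairs=min_pairs)
        adj = np.nan_to_num(ccorr.squared(), nan=0.0)
        labels = cluster_static_cut(tom_distance(adj), params)
        for c in dict.fromkeys(labels[labels != UNASSIGNED]):
            members = [m for m, l in zip(keep, labels) if l == c]
            lg = LinkageGroup(lg_id=f"{chrom}_{c}", markers=members,
                              chrom_label=str(chrom), provenance="synteny")
            phase = phase_linkage_group(members, binary, params, min_pairs=min_pairs)
            if phase is None:
                unphased.append(lg.lg_id)
            else:
                lg.phase = phase
            lgs.append(lg)
        unclustered.extend(m for m, l in zip(keep, labels) if l == UNASSIGNED)
    return SyntenyResult(linkage_groups=lgs, audit=audit, verdicts=vdf,
                         unclustered=unclustered, unphased_lgs=unphased)


def run_synteny_pipeline(binary: BinaryMarkerMatrix,
                         params: ClusterParams | None = None,
                         random_pattern: str = DEFAULT_RANDOM_PATTERN,
                         min_pairs: int = 20) -> SyntenyResult:
    """Chromosome grouping followed by LG formation and phasing."""
    groups, audit = assign_chromosome_groups(binary, random_pattern)
    return build_synteny_lgs(groups, binary, params, audit, min_pairs=min_pairs)
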