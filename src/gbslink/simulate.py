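"""Synthetic F1 GBS families with known truth.

The generator emulates the data a shallow-coverage genotyping-by-sequencing
run produces for an outcrossed F1 family of a highly heterozygous species:

* pseudo-testcross (Pt) loci — heterozygous in exactly one parent (AB x AA),
  segregating 1:1 AB:AA in progeny and 3:1 at the allele level;
* loci heterozygous in both parents (AB x AB) that the Pt filters must reject;
* meiosis with a Poisson crossover process (rate = map length / 100 Morgans,
  uniform positions, no interference);
* per-call read depth ~ Poisson(mean_depth), binomial read sampling with a
  per-read miscall probability, maximum-likelihood genotype calling and a
  phred-scaled genotype quality (GQ), so heterozygotes are under-called at
  low depth exactly the way real GBS genotypes are;
* optional anomalies: pollen-contaminant progeny that are actually selfs of
  the maternal parent, and tandem-duplicate loci whose reads collapse with an
  invariant second copy before genotype calling (halving the minor-read
  fraction, the 1:7 signature).

Every simulated marker carries a truth record (informative parent, phase,
true linkage group, transmitted haplotypes), so downstream stages can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AA, AB, BB, MISSING,
    GenotypeMatrix,
    ROLE_FATHER, ROLE_MOTHER, ROLE_PROGENY,
    make_site_table,
)

BP_PER_CM = 400_000  # physical scale: ~40 Mb for a 100 cM chromosome

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulated family.

    mean_depth is the expected reads per genotype call; seq_error the
    per-read miscall probability.  gq_gain scales the phred likelihood gap
    into the reported GQ so that the conventional GQ >= 98 gate separates
    confidently sampled calls (depth >= ~5) from under-sampled ones, which is
    how the gate behaves on real GBS data; gq values are capped at 99.
    """

    n_chrom: int = 19
    chrom_length_cM: float = 100.0
    n_pt_female: int = 80      # Pt loci per chromosome heterozygous in the mother
    n_pt_male: int = 80
    n_nonpt: int = 10          # AB x AB loci per chromosome (to be rejected)
    n_progeny: int = 200
    mean_depth: float = 6.0
    seq_error: float = 0.01
    n_contaminants: int = 0    # selfed-mother progeny to inject
    n_dup_loci: int = 0        # tag-collapsed tandem duplicate Pt loci
    seed: int = 0
    gq_gain: float = 7.0
    gq_cap: int = 99
    include_parents: bool = True

    def validate(self) -> None:
        counts = [self.n_chrom, self.n_pt_female, self.n_pt_male, self.n_nonpt,
                  self.n_progeny, self.n_contaminants, self.n_dup_loci]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.n_contaminants >= self.n_progeny and self.n_progeny > 0:
            raise ValueError("n_contaminants must be smaller than n_progeny")


@dataclass
class TruthSet:
    """Ground truth of a simulated family.

    markers: one row per emitted site (site_id, chrom, cM, pos, kind,
    phase_female, phase_male, lg_id, duplicate).  hap_female / hap_male hold
    the parental haplotype (0/1) transmitted to each progeny at each marker.
    """

    markers: pd.DataFrame
    hap_female: np.ndarray
    hap_male: np.ndarray
    crossovers: pd.DataFrame       # sample, parent, chrom, n_crossovers
    progeny: list[str]
    contaminants: list[str] = field(default_factory=list)
    duplicate_sites: list[str] = field(default_factory=list)

    def true_lg(self, site_ids) -> pd.Series:
        tab = self.markers.set_index("site_id")["lg_id"]
        return tab.loc[list(site_ids)]

    def true_phase_rows(self, site_ids) -> np.ndarray:
        """Phase-encoded truth (1 = minor-bearing haplotype inherited) for Pt markers."""
        tab = self.markers.set_index("site_id")
        idx = self.markers.set_index("site_id").index.get_indexer(list(site_ids))
        rows = []
        for sid, i in zip(site_ids, idx):
            rec = tab.loc[sid]
            if rec["kind"] == "pt_female":
                rows.append((self.hap_female[i] == rec["phase_female"]).astype(np.int8))
            elif rec["kind"] == "pt_male":
                rows.append((self.hap_male[i] == rec["phase_male"]).astype(np.int8))
            else:
                raise ValueError(f"{sid} is not a Pt marker")
        return np.vstack(rows)


# ---------------------------------------------------------------------------
# meiosis


def _gamete_haplotypes(rng: np.random.Generator, positions_cM: np.ndarray,
                       length_cM: float) -> tuple[np.ndarray, int]:
    """Haplotype (0/1) transmitted at each position for one meiosis.

    Crossover count ~ Poisson(length/100), positions uniform, no interference.
    """
    start = int(rng.integers(0, 2))
    n_xo = int(rng.poisson(length_cM / 100.0))
    if n_xo == 0:
        return np.full(positions_cM.shape, start, dtype=np.int8), 0
    xo = np.sort(rng.uniform(0.0, length_cM, size=n_xo))
    hap = (start + np.searchsorted(xo, positions_cM)) % 2
    return hap.astype(np.int8), n_xo


def _layout_sites(cfg: SimConfig, rng: np.random.Generator):
    """Marker coordinates, kinds and phases for every chromosome."""
    def balanced_phases(n: int) -> np.ndarray:
        # exact half-half split, shuffled: the two phases of a real LG hold
        # comparable marker numbers, and at desk scale binomial fluctuation
        # would spuriously push one phase below the minimum cluster size
        ph = np.arange(n) % 2
        return rng.permutation(ph)

    recs = []
    for c in range(1, cfg.n_chrom + 1):
        n_tot = cfg.n_pt_female + cfg.n_pt_male + cfg.n_nonpt
        kinds = np.array(["pt_female"] * cfg.n_pt_female
                         + ["pt_male"] * cfg.n_pt_male
                         + ["nonpt"] * cfg.n_nonpt)
        phase_f = np.zeros(n_tot, dtype=int)
        phase_m = np.zeros(n_tot, dtype=int)
        phase_f[kinds == "pt_female"] = balanced_phases(cfg.n_pt_female)
        phase_m[kinds == "pt_male"] = balanced_phases(cfg.n_pt_male)
        both = kinds == "nonpt"
        phase_f[both] = rng.integers(0, 2, size=cfg.n_nonpt)
        phase_m[both] = rng.integers(0, 2, size=cfg.n_nonpt)
        order = rng.permutation(n_tot)
        cM = cfg.chrom_length_cM * (np.arange(n_tot) + 0.5) / n_tot
        for slot, j in enumerate(order):
            recs.append(
                {
                    "chrom": str(c),
                    "cM": float(cM[slot]),
                    "pos": int(round(cM[slot] * BP_PER_CM)) + 1,
                    "kind": str(kinds[j]),
                    "phase_female": int(phase_f[j]),
                    "phase_male": int(phase_m[j]),
                }
            )
    df = pd.DataFrame(recs)
    lg = np.where(df["kind"] == "pt_female", "F" + df["chrom"],
                  np.where(df["kind"] == "pt_male", "M" + df["chrom"], ""))
    df["lg_id"] = lg
    df["duplicate"] = False
    return df


def simulate_family(config: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """True (error-free) genotypes of progeny and parents, plus the truth set."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    layout = _layout_sites(config, rng)
    m = len(layout)
    n = config.n_progeny
    progeny = [f"prog{j:03d}" for j in range(n)]

    alleles_major = _BASES[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)
    alleles_minor = _BASES[(np.char.index("ACGT", alleles_major.astype("U1")) + shift) % 4]
    sites = make_site_table(layout["chrom"], layout["pos"], alleles_major, alleles_minor)

    hap_f = np.zeros((m, n), dtype=np.int8)
    hap_m = np.zeros((m, n), dtype=np.int8)
    xo_recs = []
    for c in layout["chrom"].unique():
        idx = np.flatnonzero((layout["chrom"] == c).values)
        cM = layout["cM"].values[idx]
        for j, sample in enumerate(progeny):
            g, nf = _gamete_haplotypes(rng, cM, config.chrom_length_cM)
            hap_f[idx, j] = g
            g, nm = _gamete_haplotypes(rng, cM, config.chrom_length_cM)
            hap_m[idx, j] = g
            xo_recs.append({"sample": sample, "parent": "female", "chrom": c, "n_crossovers": nf})
            xo_recs.append({"sample": sample, "parent": "male", "chrom": c, "n_crossovers": nm})

    kind = layout["kind"].values
    ph_f = layout["phase_female"].values[:, None]
    ph_m = layout["phase_male"].values[:, None]
    dosage = np.zeros((m, n), dtype=np.int8)
    is_f = kind == "pt_female"
    is_m = kind == "pt_male"
    is_n = kind == "nonpt"
    dosage[is_f] = (hap_f[is_f] == ph_f[is_f]).astype(np.int8)
    dosage[is_m] = (hap_m[is_m] == ph_m[is_m]).astype(np.int8)
    dosage[is_n] = ((hap_f[is_n] == ph_f[is_n]).astype(np.int8)
                    + (hap_m[is_n] == ph_m[is_n]).astype(np.int8))
    gt_prog = dosage  # dosage 0/1/2 coincides with AA/AB/BB codes

    samples = list(progeny)
    roles = [ROLE_PROGENY] * n
    gt_cols = [gt_prog]
    if config.include_parents:
        mother = np.where(is_f | is_n, AB, AA).astype(np.int8)
        father = np.where(is_m | is_n, AB, AA).astype(np.int8)
        gt_cols += [mother[:, None], father[:, None]]
        samples += ["mother", "father"]
        roles += [ROLE_MOTHER, ROLE_FATHER]

    truth_mat = GenotypeMatrix.empty(sites, samples, roles)
    truth_mat.gt = np.hstack(gt_cols).astype(np.int8)
    truth_mat.gq = np.full(truth_mat.gt.shape, 99, dtype=np.int16)

    layout = layout.copy()
    layout["site_id"] = sites["site_id"].values
    truth = TruthSet(
        markers=layout[["site_id", "chrom", "cM", "pos", "kind",
                        "phase_female", "phase_male", "lg_id", "duplicate"]],
        hap_female=hap_f,
        hap_male=hap_m,
        crossovers=pd.DataFrame(xo_recs),
        progeny=progeny,
    )
    return truth_mat, truth


# ---------------------------------------------------------------------------
# sequencing emulation


def _call_from_reads(depth: np.ndarray, k_minor: np.ndarray, seq_error: float,
                     gq_gain: float, gq_cap: int):
    """ML genotype + scaled phred GQ from (total, minor) read counts.

    Likelihoods are binomial in the minor-read count with per-read minor
    probability e (AA), 0.5 (AB), 1-e (BB); the combinatorial term cancels.
    GQ is the gap between best and second-best log-likelihood on the phred
    scale, multiplied by gq_gain and capped.
    """
    e = max(seq_error, 1e-4)
    d = depth.astype(float)
    k = k_minor.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.stack([
            k * np.log(e) + (d - k) * np.log(1.0 - e),
            d * np.log(0.5),
            k * np.log(1.0 - e) + (d - k) * np.log(e),
        ])
    order = np.argsort(ll, axis=0)
    best = order[-1]
    gap = np.take_along_axis(ll, order[-1][None], 0)[0] - \
        np.take_along_axis(ll, order[-2][None], 0)[0]
    gq = np.minimum(gq_cap, np.floor(gq_gain * 10.0 * gap / np.log(10.0))).astype(np.int16)
    gt = best.astype(np.int8)
    zero = depth == 0
    gt[zero] = MISSING
    gq[zero] = 0
    return gt, gq


def simulate_sequencing(truth: GenotypeMatrix, config: SimConfig,
                        rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Shallow-sequencing genotype calls from true genotypes.

    depth ~ Poisson(mean_depth) per call; each read reports the minor allele
    with probability e (true AA), 1/2 (AB) or 1-e (BB); the called genotype
    maximises the binomial likelihood; depth 0 yields MISSING with gq 0.
    """
    if (truth.gt == MISSING).any():
        raise ValueError("truth matrix must not contain missing genotypes")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    shape = truth.gt.shape
    depth = rng.poisson(config.mean_depth, size=shape)
    p_minor = np.choose(truth.gt, [config.seq_error, 0.5, 1.0 - config.seq_error])
    k_minor = rng.binomial(depth, p_minor)
    gt, gq = _call_from_reads(depth, k_minor, config.seq_error, config.gq_gain, config.gq_cap)
    called = truth.copy()
    called.gt = gt
    called.gq = gq
    called.ad_major = (depth - k_minor).astype(np.int32)
    called.ad_minor = k_minor.astype(np.int32)
    called.flag = np.zeros(shape, dtype=np.int8)
    return called


# ---------------------------------------------------------------------------
# anomalies


def inject_anomalies(calls: GenotypeMatrix, truth: TruthSet, config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[GenotypeMatrix, TruthSet]:
    """Inject selfed-mother contaminants and tag-collapsed duplicate loci.

    Contaminant columns are regenerated as offspring of a mother x mother
    selfing (two independent maternal meioses) and re-sequenced.  Duplicate
    loci receive the pooled reads of an invariant homozygous-major second
    copy before genotype calling, so the minor-read fraction of carriers
    drops from 1/2 to 1/4 (pooled expectation 1/8).
    """
    if config.n_contaminants >= len(truth.progeny) and config.n_contaminants > 0:
        raise ValueError("cannot make every progeny a contaminant")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    out = calls.copy()
    truth_markers = truth.markers.reset_index(drop=True)
    kind = truth_markers["kind"].values
    ph_f = truth_markers["phase_female"].values

    contaminants: list[str] = []
    if config.n_contaminants > 0:
        prog_cols = {s: i for i, s in enumerate(out.samples)}
        chosen = rng.choice(len(truth.progeny), size=config.n_contaminants, replace=False)
        for j in sorted(chosen):
            sample = truth.progeny[j]
            col = prog_cols[sample]
            dosage = np.zeros(len(truth_markers), dtype=np.int8)
            for c in truth_markers["chrom"].unique():
                idx = np.flatnonzero((truth_markers["chrom"] == c).values)
                cM = truth_markers["cM"].values[idx]
                g1, _ = _gamete_haplotypes(rng, cM, config.chrom_length_cM)
                g2, _ = _gamete_haplotypes(rng, cM, config.chrom_length_cM)
                het = (kind[idx] == "pt_female") | (kind[idx] == "nonpt")
                dos = np.zeros(len(idx), dtype=np.int8)
                dos[het] = ((g1[het] == ph_f[idx][het]).astype(np.int8)
                            + (g2[het] == ph_f[idx][het]).astype(np.int8))
                dosage[idx] = dos
            depth = rng.poisson(config.mean_depth, size=dosage.shape)
            p_minor = np.choose(dosage, [config.seq_error, 0.5, 1.0 - config.seq_error])
            k_minor = rng.binomial(depth, p_minor)
            gt, gq = _call_from_reads(depth, k_minor, config.seq_error,
                                      config.gq_gain, config.gq_cap)
            out.gt[:, col] = gt
            out.gq[:, col] = gq
            out.ad_major[:, col] = depth - k_minor
            out.ad_minor[:, col] = k_minor
            contaminants.append(sample)

    duplicate_sites: list[str] = []
    markers2 = truth_markers.copy()
    if config.n_dup_loci > 0:
        pt_idx = np.flatnonzero(np.isin(kind, ["pt_female", "pt_male"]))
        chosen = rng.choice(pt_idx, size=min(config.n_dup_loci, len(pt_idx)), replace=False)
        for i in sorted(chosen):
            extra = rng.poisson(config.mean_depth, size=out.n_samples)
            extra_minor = rng.binomial(extra, config.seq_error)
            d = out.ad_major[i] + out.ad_minor[i] + extra
            k = out.ad_minor[i] + extra_minor
            gt, gq = _call_from_reads(d, k, config.seq_error, config.gq_gain, config.gq_cap)
            out.gt[i] = gt
            out.gq[i] = gq
            out.ad_major[i] = d - k
            out.ad_minor[i] = k
            duplicate_sites.append(truth_markers["site_id"].iloc[i])
        markers2.loc[markers2["site_id"].isin(duplicate_sites), "duplicate"] = True

    new_truth = TruthSet(
        markers=markers2,
        hap_female=truth.hap_female,
        hap_male=truth.hap_male,
        crossovers=truth.crossovers,
        progeny=truth.progeny,
        contaminants=contaminants,
        duplicate_sites=duplicate_sites,
    )
    return out, new_truth


def simulate_gbs_family(config: SimConfig
                        ) -> tuple[GenotypeMatrix, GenotypeMatrix, TruthSet]:
    """Full generator: (called matrix, true matrix, truth set) for one family."""
    truth_mat, truth = simulate_family(config)
    calls = simulate_sequencing(truth_mat, config)
    calls, truth = inject_anomalies(calls, truth, config)
    return calls, truth_mat, truth
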