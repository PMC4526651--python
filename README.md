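# gbslink

Dense, phased, parent-separated genetic linkage maps for F1 families of
highly heterozygous, outcrossing species (grapevine-style crosses) from
shallow-coverage genotyping-by-sequencing (GBS) calls — without requiring
parental genotypes.

## The problem

GBS genotypes thousands of markers cheaply but shallowly: calls are full of
missing data, and heterozygotes are systematically under-called (a site
sampled three reads deep shows only one allele in a quarter of
heterozygotes).  In an outbred F1 cross there are no inbred lines to lean
on, and parental genotypes are often missing or poor.  The observation that
rescues mapping is the **pseudo-testcross (Pt)** configuration: a site
heterozygous in exactly one parent (AB × AA) segregates 1:1 AB:AA in the
progeny — 3:1 at the allele level, minor allele frequency (MAF) 0.25 — and
can be mapped like a backcross marker for that parent, identified purely
from progeny segregation.

## The pipeline

1. **Family QC** — pollen contaminants, selfs and mislabels are flagged by
   the intersection of Yang-type genomic relatedness to each parent and
   parent-specific Mendelian-incompatibility counts.
2. **Pt marker identification** — sites are filtered on allele frequency
   (≥ 5%), genotyping rate (≥ 50%), MAF 0.25 ± 0.125 and genotype
   frequencies; genotype-quality (GQ) rules then repair heterozygote
   under-calling: low-GQ AA → missing (*masked*), confident BB → missing
   (*error*, impossible at a Pt site), low-GQ BB → AB (*corrected*).
3. **Linkage groups** — markers are encoded as presence/absence of the
   minor allele; pairwise Pearson r² becomes a network adjacency, the
   topological overlap measure (TOM) rewards shared neighbourhoods, and
   average-linkage clustering of 1 − TOM with a static dendrogram cut
   yields linkage groups.  Either *synteny*-guided (per reference
   chromosome, with a `diff = 2` best/second mean-correlation filter
   against mis-assignment) or *de novo* (one global dendrogram, a sweep
   over cut heights × minimum cluster sizes selecting ≥ 2 LGs per
   chromosome while maximising assigned markers).
4. **Phasing** — within each LG the adjacency is the *signed* correlation
   truncated at zero (coupling-phase markers correlate positively), and
   the same clustering resolves the parent's two haplotype phases.
5. **Ordering** — phase-encoded markers behave like a backcross; a minimum
   spanning tree of the rf-weighted marker graph provides a backbone
   order, polished by exhaustive sliding-window permutation; redundant and
   double-crossover-inducing markers are removed; distances are Kosambi,
   d = 25 ln((1+2r)/(1−2r)) cM.
6. **Curation** — missing-data and crossover-excess filters; a two-state
   phase HMM estimates the genotyping error rate ε per LG by profile
   likelihood and re-estimates rf under it (deflating the error-inflated
   map); a drop-one-marker scan (window 9) removes markers that shorten
   the map > 2 cM with a high LOD difference; a ripple (window 7, then an
   error-aware likelihood refinement) settles the final order.
7. **Diagnostics** — the minor tag frequency (MTF = pooled minor-read
   fraction) exposes tags collapsing two tandem-duplicated loci: a normal
   Pt site pools to 1/4, a two-copy collapse to 1/8 (1:7 segregation).

A **simulator** generates complete synthetic families — meiosis with
Poisson crossovers, binomial read sampling with maximum-likelihood calling
and GQ, selfed-mother contaminants, tag-collapsed duplicates — with full
ground truth, so every stage is testable at desk scale.

## Worked example

`examples/03_order_and_curate.py` simulates a 2-chromosome family
(200 progeny, mean depth 8), builds synteny LGs, orders and curates:

```
            stage  n_markers    total_cM
          initial        320 1198.342935
after_order_check        320 1176.539067
after_error_model        320  389.910266
   after_autodrop        309  388.095206
            final        309  383.796859

fitted genotyping error rate per LG: {'20': 0.0116, '1': 0.0159, '21': 0.0159, '2': 0.0159}

LG 20: 77 markers, 97.8 cM (simulated truth: 100 cM)
LG 1: 78 markers, 92.1 cM (simulated truth: 100 cM)
LG 21: 77 markers, 98.5 cM (simulated truth: 100 cM)
LG 2: 77 markers, 95.4 cM (simulated truth: 100 cM)
```

The raw map is ~3× inflated (1198 cM for four 100 cM chromosomes) because
residual genotyping errors look like double crossovers; fitting ε ≈ 0.012–
0.016 and re-estimating recombination fractions under the error model
recovers lengths within a few cM of the simulated truth.  Female LGs are
numbered 1–19 and male LGs 20–38 by convention.

The other examples cover Pt identification (`01`), synteny vs de novo LG
formation (`02`) and contaminant QC plus repeat diagnostics (`04`).

## Command line

A thin CLI chains the stages through files:

```sh
gbslink simulate --n-chrom 5 --n-progeny 200 --seed 1 --out-prefix fam
gbslink qc fam.vcf --out-prefix fam
gbslink pt fam.vcf --out-prefix fam
gbslink synteny fam.binary.tsv --out-prefix fam          # or: gbslink denovo
gbslink order fam.binary.tsv fam.lgs.tsv --progenitors fam.progenitors.tsv --out-prefix fam
gbslink curate fam.map.tsv fam.binary.tsv --out-prefix fam
```

`curate` also writes an R/qtl "csvsr" cross file for downstream QTL work.

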