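# Methods

This note documents the models behind `gbslink`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the places
where the design was genuinely open.

## Genetic model

An outbred F1 family has four parental haplotypes.  A pseudo-testcross
(Pt) site — heterozygous in exactly one parent — transmits its minor
allele to half the progeny, so progeny segregate 1:1 AB:AA (allele ratio
3:1, MAF 0.25).  Writing each Pt marker as presence/absence of the minor
allele turns the family into a backcross for that parent: once markers are
phase-aligned (the minor allele placed on the same parental haplotype),
the recombination fraction between two markers is the discordance rate
among progeny informative for both, and Kosambi's function
d = 25 ln((1+2r)/(1−2r)) maps rf to additive centimorgans.

Sites heterozygous in both parents (AB × AB) have progeny MAF 0.5 and are
rejected by the MAF window (0.25 ± 0.125, closed interval); the window
also tolerates moderate segregation distortion, which real chromosomes
show in patches.

## Genotype-quality correction

The three correction rules assume heterozygote under-calling is the
dominant error mode at shallow depth:

* AA with GQ < 98 → missing, *masked* (potentially an under-sampled AB);
* BB with GQ ≥ 98 → missing, *error* (a confident BB cannot exist at a Pt
  site);
* BB with GQ < 98 → AB, *corrected* (an under-sampled heterozygote).

GQ comparisons use ≥ 98 for "high quality" throughout; the post-correction
filters re-impose the 50% genotyping rate and reject sites whose
confident-BB fraction (over pre-correction non-missing calls) exceeds 5%.
The audit reports every removal category, and the categories always sum to
the initial site count.

## Clustering and phasing

Pairwise Pearson correlations are computed over pairwise-complete progeny;
entries with fewer than `min_pairs = 20` complete pairs are treated as
missing (tiny overlaps otherwise produce spurious ±1), and missing
correlations enter adjacencies as 0 (no evidence of linkage).  For linkage
groups the adjacency is r² (coupling and repulsion both indicate shared
parental origin); for phasing it is max(r, 0) (only coupling-phase markers
attract).  The topological overlap dissimilarity

TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  dist = 1 − TOM

with self-adjacency excluded from the connectivity k, feeds average-linkage
(UPGMA) hierarchical clustering with a *static* cut: groups below the
minimum cluster size dissolve into "unassigned".  Defaults follow the
reference-guided path (cut 0.9, min size 30; phasing min 30) and the
de novo path (grid of heights 0.95…0.85 × min sizes 50…300; phasing min
10).  Phasing reports the two largest clusters as phases and warns about
extras; a group resolving into fewer than two clusters is reported
unphased.

The `diff` mis-assignment filter ranks a marker's mean correlation (r² for
group assignment, signed r exposed via `mode`) against every candidate
group: *agree* requires the assigned group to rank first by at least
`diff = 2` over the runner-up; a rank inversion alone is *disagree*
(consistent with the separate bookkeeping of the two categories);
everything else is *unresolved*.

The de novo sweep builds one dendrogram and cuts it at every grid point;
the selected point has at least 2 × n_chrom linkage groups and maximises
the assigned fraction (ties prefer the larger minimum size, then the lower
height — fewer spurious groups).  LGs whose phasing fails or whose mean
within-LG r² falls below 0.02 are flagged atypical for manual review.

## Ordering

Within a phase-aligned LG the marker graph is complete with rf weights
(missing rf → 0.5).  Components linked at rf < 0.4 smaller than 5 markers
split off as unlinked fragments; markers with > 50% missing calls are
excluded before ordering.  The order is the minimum spanning tree's
heaviest path, extended by cheapest insertion of off-path markers, then
polished by an exhaustive sliding-window permutation search (window 5)
plus a single-marker relocation pass, minimising the total adjacent
discordance count (the obligate-crossover objective).  Redundant markers
(adjacent rf = 0) collapse to the member with fewest missing calls, and a
marker contradicting agreeing flanking neighbours in > 20% of informative
progeny is removed as a double-crossover artifact; the retained set is
re-ordered once.

Two-point LOD is the standard backcross form
R log10(2r̂) + (n−R) log10(2(1−r̂)), giving n log10 2 at r̂ = 0 and 0 at
r̂ = 0.5.

Split LGs of the same parent and chromosome are joined by testing both
relative phase orientations and keeping the shorter ordered map — joining
in repulsion expands the apparent distances.  Candidate merges are ordered
without fragment pruning, otherwise the repulsion junction (rf ≈ 0.5)
would drop half the markers and make the wrong orientation look short.
A join inflating the map by more than 200 cM over the separate lengths is
refused.

## Curation

Steps, in order, distances re-estimated after each destructive step:

1. Markers with ≥ 50% missing data are removed, then individuals with
   > 50% missing genotypes or with more than twice the family-mean
   obligate-crossover count (strict >; the wording is ambiguous and the
   strict reading removes fewer individuals).
2. Adjacent pairs with rf > 0.4 or LOD < 1 flag an LG for re-polishing.
   Fully manual order inspection cannot be automated; the stated decision
   rules are, and everything else is logged.
3. The genotyping error rate ε of each LG is fitted with a two-state
   (phase) HMM: switch probability per interval = rf, emission flips the
   observed value with probability ε, missing emits 1.  ε̂ maximises a
   *profile* likelihood over a 25-point log-spaced grid (1e-4 … 0.2): at
   each candidate ε the interval rf are re-estimated by bounded EM
   (10 iterations).  Fixing rf at the observed discordance instead biases
   ε̂ low, because the discordance has already absorbed the errors as
   spurious crossovers.  The EM-corrected rf deflate the error-inflated
   map — the dominant curation effect.
4. Drop-one scan: for each interior marker, the window (9 markers) is
   scored with and without it.  Removal requires the window to shorten by
   > 2 cM *and* a LOD difference above the threshold (default: the 95th
   percentile of the map's drop-one LOD-difference distribution,
   emulating "remove the upper tail").  Window lengths use raw adjacent
   discordance — the error-corrected map would absorb a spurious marker's
   flips and hide the inflation it causes — while the LOD difference uses
   the HMM likelihood at ε̂.  LG end markers are never auto-dropped
   (trimming ends shortens any map trivially).
5. Markers creating gaps > 2 cM are flagged (report only); the order is
   rippled with a window of 7 under the obligate-crossover objective and
   then refined by an error-aware likelihood ripple (window 5, scored by
   the full-LG HMM likelihood with error-deflated rf, forward/backward
   states cached so each candidate costs only the window).  The
   crossover-count objective scores an isolated genotyping flip as two
   crossovers and cannot resolve near-tie local orders; the likelihood
   refinement is the same decision R/qtl's likelihood ripple makes.
   Finally each LG is reversed if its order anticorrelates with physical
   position, and distances are recomputed (Kosambi of the EM rf).

Obligate crossovers are counted two ways, deliberately: per *individual*
(QC filter, windowed recombination tracks) along each progeny's
non-missing marker subsequence; per *order objective* as the sum of
pairwise-complete adjacent discordance counts, which makes the exhaustive
window searches cheap and deterministic.

## Family QC

Relatedness is the Yang-type estimator
A_jk = mean over usable sites of (g_j − 2p)(g_k − 2p) / (2p(1−p)) on
GQ ≥ 98 calls, with p the within-family minor allele frequency — so
absolute values are family-centred and only *relative* separation is
meaningful.  Mendelian incompatibilities count progeny alleles absent from
a parent's called genotype (male- and female-incompatible separately; one
call can increment both).  The published procedure flagged outliers by
eye; here a reproducible rule substitutes: relatedness outliers deviate
from the progeny median by > 4 MADs in either parent coordinate, Mendelian
outliers have (male+1)/(female+1) ≥ 3 with the male count above the
median (the +1 guards the zero denominator), and a progeny is removed only
when in *both* sets.  Fewer than 10 progeny: report only, no automatic
flagging.

## Simulator

The generator defines the study conditions: 19 chromosomes of 100 cM,
80 Pt loci per parent per chromosome plus 10 AB × AB loci, 200 progeny,
mean depth 6, per-read miscall rate 0.01, no interference (crossover count
Poisson(L/100), positions uniform).  Physical coordinates place 1 cM at
400 kb — a 100 cM chromosome spans 40 Mb, grape-like.  Marker phases are
an exact shuffled half-half split within each parent × chromosome: real
LGs hold hundreds of markers per phase, where binomial fluctuation is
negligible relative to the minimum cluster size; at desk scale a Bernoulli
assignment can push one phase below that minimum by pure scaling accident,
a regime the method is never asked to survive at full size.  Eighty
markers per LG (rather than a bare minimum) keeps phases (~40) above the
phasing minimum (30) and LGs above the smallest de novo cluster size (50)
for the same reason.

Sequencing: depth ~ Poisson(mean_depth); each read reports the minor
allele with probability e (true AA), 1/2 (AB) or 1−e (BB); the call
maximises the binomial likelihood (combinatorial terms cancel); depth 0 is
missing.  GQ is the phred-scaled gap between the best and second-best
genotype log-likelihood, multiplied by a gain (`gq_gain = 7`) and capped
at 99.  The gain is a deliberate modelling choice: an unscaled likelihood
gap credits a homozygote ~3 phred per read, so the conventional GQ ≥ 98
gate would pass only calls ~33 reads deep and, at single-digit GBS depths,
mask essentially every homozygote — whereas on real GBS data the gate
demonstrably passes the majority of genotypes at retained sites.  With the
gain, the gate separates calls at roughly depth 5, reproducing the
qualitative behaviour the correction rules rely on (most AA confident,
under-sampled heterozygotes masked or corrected).  The simulator targets
this qualitative behaviour, not numeric equivalence with any particular
caller.

Anomalies: contaminants are regenerated as selfed-mother offspring (two
independent maternal meioses) and re-sequenced — the dominant real-world
contamination mode; duplicate loci pool the reads of an invariant
homozygous-major second copy before calling, halving the carrier
minor-read fraction (pooled expectation 1/8 vs 1/4; the analytic value is
`expected_mtf(n_copies)` = 1/2 · 1/(2·n_copies)).

Not emulated: read-level FASTQ, restriction-site/tag positions, PCR
duplicates, depth overdispersion across sites, reference mis-alignment,
crossover interference.  Passing tests therefore demonstrate the
*machinery* — segregation filters, clustering, phasing, ordering, HMM
curation — under controlled noise, not robustness to every artifact of a
real GBS build.

## Numerical choices

* Pooled minor-tag frequencies are compared with their analytic
  expectations using a ratio-estimator SE over (site, sample) cells, which
  captures carrier-composition variance; a binomial read-level SE
  understates the spread several-fold.
* Allele-frequency thresholds are computed on allele copies (2N called
  progeny); all threshold intervals are closed.
* Ties in clustering labels, ordering polish and selection rules resolve
  deterministically (first appearance / incumbent order), so fixed seeds
  reproduce bit-identically.
* Correlations with |r| clipped to 1; rf capped at 0.5; Kosambi of a
  capped rf reports a configurable 50 cM with a warning.
* MAF/MTF density curves use a Gaussian KDE with Silverman bandwidth;
  modes are local maxima of the evaluated curve.

## Problem sizes

The test-suite and acceptance computations run on: the default
19-chromosome family (3,230 sites × 202 samples) for Pt identification,
clustering, sweeping and phasing; a 3-chromosome depth-8 family for
ordering and curation; 1–5-chromosome families for QC, joining and
anomaly checks; and 30-marker single-LG fixtures for the HMM parameter
recovery.  These sizes keep every stage in the regime the method expects
(cluster sizes above minima, ≥ 150 informative progeny pairs) while each
stage completes in seconds.

## Known limitations

* The drop-one LOD threshold default (95th percentile) is a tail heuristic;
  heavily corrupted maps may need a manual threshold.
* Parent assignment without progenitor genotypes is arbitrary per
  chromosome (unknown-A/B); cross-chromosome parent identity then relies
  on joining evidence, which only exists for split LGs.
* The de novo sweep assumes the expected 2 × n_chrom groups is attainable;
  for fragmented data it reports best-effort with a flag.
* Relatedness values are family-centred; they are not comparable across
  families or to pedigree-expected coefficients.
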