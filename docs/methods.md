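# Methods

## The model being tested

A miRNA cluster is treated as one transcription unit: a single RNA
polymerase II promoter upstream of the first hairpin produces a polycistronic
pri-miRNA, every hairpin of which is processed into a mature miR and a minor
miR\*. Under purely transcriptional control, all products of one cluster
inherit the same tissue activity profile, so (a) pairwise Pearson
correlations of member profiles across libraries should be high, (b) each
gene's miR and miR\* profiles should agree, and (c) predicted TSSs should sit
upstream of the cluster, not between hairpins. Departures from (a) with (b)
— a member whose miR decouples while its star still tracks the cluster, or
vice versa — indicate post-transcriptional regulation of arm stability or
hairpin processing rather than an independent internal promoter, provided (c)
holds and the absence of internal TSSs is not just a short-gap artifact.

## Pipeline definitions

**Clusters.** Genes on one chromosome strand are chained single-linkage when
the gap between adjacent precursor intervals is ≤ `max_gap` (default 1000 nt,
boundary inclusive). Gaps are measured end-to-start between precursors (the
annotated gene bodies), not between mature arms. Same-strand chaining is the
default because one polycistronic transcript cannot span strands; it can be
switched off. Genes whose mature miR sequences are string-identical form a
paralog group; within a cluster such members collapse onto the genomically
first representative, and a cluster left with fewer than two distinguishable
members is excluded from expression analysis. A cluster can additionally be
split at one genomic boundary when every cross-boundary pair correlates below
`split_threshold` (default 0.6) while each side of ≥ 2 members is internally
above it — the formalization of the observation that a 1-kb rule can chain
two independently behaving sub-clusters.

**Read assignment.** A read is assigned to a mature arm iff its first 18
bases (T/U-normalized) equal the arm sequence's first 18 bases; bases beyond
the prefix are ignored, matching how heterogeneous 3' ends behave in
practice. Reads are matched to arm sequences directly rather than through a
genome aligner: the aligner's only role in this analysis would be to reach
"reads at annotated miRNA positions", which prefix matching reproduces
without the dependency. Reads hitting arms of one paralog group increment
the pooled representative once; reads hitting arms of different groups are
discarded as ambiguous and tallied. Reads outside 18–30 nt or with
non-ACGTUN characters are skipped and tallied; inputs are assumed
adapter-clipped. Assigned + ambiguous + skipped = total, per library, by
construction.

**Profiles.** Counts are scaled per library to relative frequencies; the
denominator is the total of reads assigned to annotated arms (not the total
library size), which insulates profiles from non-miRNA content differing
between libraries; a total-reads denominator is available. Correlations are
computed on relative frequencies (an optional log10-with-pseudocount mode
exists); heatmap rows are z-scored with the sample (n−1) standard deviation,
and constant rows become all-zero flagged rows.

**Classification.** With `hi` = 0.6 and `lo` = 0.3: a cluster is
*coordinated* when all member pairs have r > hi; a member is *uncorrelated*
when r < lo against every cluster-mate while the remaining members stay
pairwise above hi, making the cluster *uncoordinated*; a two-member cluster
with r < lo is uncoordinated with both members listed. Any other pattern is
*indeterminate* — intermediate correlation structures are reported with
their full r table rather than forced into a label. Members whose summed
raw miR counts fall below `min_total_count` (default 50) are set aside
before classification, so decorrelation calls cannot rest on counting noise.
Raising `lo` can only move a cluster toward uncoordinated (threshold
monotonicity, property-tested). When an uncorrelated member has an
identical-sequence paralog outside the cluster, the classification carries a
note: its pooled profile superposes the paralog's expression and the
decorrelation may be an artifact of indistinguishability.

**miR/miR\* flags.** For each clustered gene with a detected star
(star counts ≥ `min_total_count`), three correlations are computed on
relative frequencies: r(miR, star), r(star, other members' miRs), and
r(miR, other members' miRs). Exactly one flag follows:

| flag | condition |
| --- | --- |
| `mir_level_regulation` | gene is an uncorrelated member, r(miR, star) < lo, and the star correlates > hi with ≥ 1 other member |
| `star_level_regulation` | gene's miR is coordinated, but r(miR, star) < lo and the star is < lo against all other members |
| `hairpin_level_regulation` | r(miR, star) > hi while both arms are < 0.6 against every other member |
| `none` | anything else, with the unmet precondition recorded |

The hairpin band deliberately uses < 0.6 rather than < lo: the canonical
pattern (arms agreeing at r ≈ 0.9 while drifting to 0.3–0.5 against
neighbors) is a softer departure than full decorrelation, and the band has
its own config key. The three conditions are mutually exclusive by
construction (the first two require r(miR, star) < lo, the third > hi; the
first two differ on coordination status), verified by exhaustive enumeration.

**TSS placement and gap probabilities.** TSSs come in as a strand-annotated
BED track from an external promoter predictor; only sense-strand TSSs count
by default (the question is sense transcription), with a `--both-strands`
switch. Upstream calls scan `window` = 5000 nt from the transcription-first
precursor's 5' start; intra-cluster calls scan each inter-precursor gap,
attributing hits to the downstream member — the gap is the only span whose
TSS would imply independent transcription of that member, and TSSs inside
precursor bodies are not gap calls. The ecdf of nearest-upstream-TSS
distances is built over *all* annotated miRNA genes, capped at 100 kb
(configurable); genes with no upstream TSS within the cap are excluded and
counted rather than imputed. The ecdf is right-continuous
(P(x) = #(d ≤ x)/n), so a gap exactly at an observed distance counts it.
P = ecdf(x) for each gap length x, summarized by mean and median across all
cluster gaps.

## The synthetic generator

The generator emulates the study conditions the analysis assumes, not a
genome:

* **Geometry.** Non-overlapping 90-nt precursors on a virtual chromosome;
  cluster sizes uniform on 2–6 (default 8 clusters + 12 singletons);
  consecutive transcription units separated by 8–20 kb. Intra-cluster gaps
  are drawn from a mixture — probability 0.18 of Uniform(500, 1000) nt, else
  LogNormal(μ = 4.038, σ = 1.0), rejection-sampled into (0, 1000] — which
  was calibrated once to the observed intra-cluster gap statistics
  (mean ≈ 213 nt, median ≈ 75 nt). A single truncated log-normal cannot
  reach that mean at that median with a 1-kb ceiling (the achievable mean
  plateaus near 150 nt over σ ∈ [1.2, 2]), hence the explicit long-gap
  component. Arm sequences are random 22-mers with globally unique 18-nt
  prefixes; optional paralog tandems copy both arm sequences of a neighbor
  to exercise collapsing.
* **Expression.** Each unit (cluster or singleton) gets a per-tissue
  activity a ~ LogNormal(0, 1.5) over 9 tissues (the default library count),
  scaled by 10⁻³ outside a per-unit active subset of 3–7 tissues. Each gene
  draws its miR share f ~ Beta(8, 2) (mean 0.8 — miRs dominate stars).
  Expected miR abundance is a·f·m_miR and star abundance a·(1−f)·m_star,
  where the modulation factors m default to 1. Counts per library are
  Multinomial(round(depth·(1−background)), normalized abundances) — fixed
  sequencing depth and compositionality, the regime relative frequencies
  live in — with depth 10⁶ and a 0.2 background (non-miRNA) fraction.
  Optional read emission writes each counted molecule as its arm sequence
  with ±1-nt random 3'-end variation.
* **Modulation.** `mir_stability` multiplies only the miR, `star_stability`
  only the star, `hairpin` both arms. The helper that builds tissue-specific
  modulations draws the modulated tissues from the target cluster's active
  subset: a stability change in a tissue where the cluster is silent is
  unobservable.
* **TSS tracks.** 1–3 sense TSSs 50–3000 nt upstream of each unit's first
  hairpin; optional implanted intra-cluster TSSs as positive controls; an
  optional genome-wide Poisson background (a density of one TSS per ~15 kb
  is of the order of genome-wide promoter-prediction tracks).

All randomness flows through a single seeded generator; identical seed and
config produce byte-identical files.

**What the generator does not model** — and what passing tests therefore do
not show about real data: cloning/ligation biases between library protocols,
isomiR 5'-end heterogeneity (assignment assumes intact 18-nt prefixes),
A-to-I editing, cross-mapping to non-miRNA loci, and any correlation between
cluster activity and genomic position. Passing the null study shows the
pipeline does not fabricate uncoordination from multinomial noise under the
polycistronic model; it does not certify behavior under protocol-specific
biases.

## Sensitivity of the Pearson screen to multiplicative modulation

A point worth stating explicitly, because it bounds what parameter-recovery
tests can show: for a modulated profile a·m against its cluster-mates'
shared profile a, the population correlation is
ρ = E[m]·var(a) / √(var(a)·var(a·m)), which stays near 0.9 for a 4-fold
suppression (m ∈ {0.25, 1} over 4 of 9 tissues) under LogNormal(0, 1.5)
activities — the shared tissue pattern dominates a 4-fold change, and the
shared active/inactive contrast anchors the correlation further. Monte
Carlo over the generator's defaults puts the probability of a sample r
below 0.3 across 9 libraries at well under 5% for any choice of modulated
tissues. Decorrelation at the r < 0.3 level requires modulation strong
enough to reorder the profile — effectively silencing the gene in its
dominant tissues (~20-fold or more) — consistent with real uncorrelated
cluster members showing r ≈ 0.02–0.04, i.e. near-complete tissue
decoupling. The replicated recovery study (`mircluster.experiments`,
exercised by the acceptance suite at the 4-fold setting) reports its honest
detection and mode-recovery rates; at 4-fold they sit near zero for the
reason above.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 is converted from
  1-based inclusive on read/write, BED taken as-is. Cluster ids are
  `<first>~<last>` short names in transcription order.
* Welch's unequal-variance two-sided t-test compares category r
  distributions (group variances are not plausibly equal).
* Pearson r uses the standard product-moment form via `numpy.corrcoef`;
  zero-variance rows are excluded with a flag and their pairs reported as
  undefined rather than NaN-propagated.
* The r histograms bin [−1, 1] at width 0.1 and are normalized to each
  category's own maximum bin.
* The ecdf uses the right-continuous convention for ties; `statsmodels`'
  ECDF implements it.
* Ambiguous reads (prefix shared across paralog groups) are discarded and
  tallied, not fractionally split: deterministic and auditable.
* Degenerate inputs fail loudly: zero-count libraries, single-library
  z-scores, < 3 libraries for correlation, < 10 ecdf distances, arms outside
  precursors, malformed coordinates (with the offending line named).
* Replicated studies in `mircluster.experiments` use 100 replicates at the
  default problem size (8 clusters + 12 singletons, 9 tissues, depth 10⁶),
  chosen so a full study completes in seconds while multinomial noise at
  depth 10⁶ is far below the classification thresholds.

## Known limitations

* The indeterminate class is deliberately conservative; real clusters with
  intermediate correlation structure receive no coordination verdict.
* Paralog pooling resolves identity by exact string equality only; near
  identical paralogs (1-nt variants) are treated as distinct and can
  cross-absorb reads only through the shared-prefix ambiguity tally.
* The intra-cluster TSS scan uses the inter-precursor gap as the search
  region; a promoter buried inside an upstream precursor body would be
  invisible to it, as it is to the gap-probability argument.
* The pipeline quantifies mature arms only; it says nothing about pri- or
  pre-miRNA abundance, so "hairpin-level" flags cannot distinguish
  processing from degradation mechanisms.
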