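# mircluster

Coordination analysis of clustered miRNA expression from small-RNA
sequencing libraries.

Nearly half of *Drosophila melanogaster* miRNA genes sit in genomic clusters
— runs of hairpin precursors no more than 1 kb apart — that are presumed to
be transcribed as single polycistronic pri-miRNAs. If that is the whole
story, the mature products of one cluster should share a tissue expression
profile, and the cluster should have a promoter only upstream of its first
hairpin. `mircluster` is a pipeline for testing both predictions and for
asking what a violation means:

1. **Cluster detection** — single-linkage chaining of annotated precursors
   along each chromosome strand (inter-precursor gap ≤ 1 kb), with collapsing
   of identical-sequence paralogs that sequencing cannot distinguish.
2. **Expression profiles** — small-RNA reads are assigned to mature arms
   (miR and miR\*) by perfect match of the first 18 nt; per-library counts
   become relative frequencies, the unit on which everything downstream runs.
3. **Coordination classification** — all pairwise Pearson correlations *r*
   across libraries. A cluster is *coordinated* when every member pair has
   *r* > 0.6; a member is *uncorrelated* when it has *r* < 0.3 against every
   cluster-mate while the rest stay mutually coherent. The four pair
   categories (same cluster, different clusters, clustered vs non-clustered,
   non-clustered) are compared by a Welch t-test.
4. **Promoter placement** — predicted TSSs (a strand-annotated BED track)
   are located in the 5-kb upstream window of each cluster and in the
   inter-hairpin gaps. Whether an *absent* intra-cluster TSS is informative
   is judged by the empirical probability P = ecdf(x) of finding a TSS in a
   span of length x, where the ecdf is built from the distances of all miRNA
   genes to their nearest upstream predicted TSS.
5. **miR/miR\* discordance** — both arms come from one transcript, so their
   profiles should agree. Per-gene discordance patterns are flagged as
   miR-level, star-level, or hairpin-level post-transcriptional regulation.

A fully seeded synthetic-data generator (annotation geometry, polycistronic
tissue activities, multinomial sequencing noise, TSS tracks) makes the whole
pipeline testable without any external downloads.

## Worked example

Generate a synthetic dataset and run the full pipeline on it:

```sh
mircluster simulate --seed 5 -o demo_data
mircluster cluster demo_data/annotation.gff3 --fasta demo_data/mature.fa \
    -o demo_clusters.tsv
```

which prints

```
wrote synthetic dataset to demo_data
8 clusters, 12 non-clustered
```

— 8 genomic clusters recovered from the simulated annotation (they match
`demo_data/true_clusters.tsv` exactly) plus 12 singleton genes. The
end-to-end analysis runs from a YAML config:

```sh
cat > demo_run.yaml <<EOF
annotation_path: demo_data/annotation.gff3
fasta_path: demo_data/mature.fa
counts_path: demo_data/counts.tsv
tss_path: demo_data/tss.bed
output_dir: demo_run
EOF
mircluster all demo_run.yaml
```

`demo_run/report.txt` then contains, for this seed:

```
genes: 47  clusters: 8 (0 excluded)  non-clustered: 12

cluster classification:
  11~6: coordinated
  13~12: coordinated
  14~19: coordinated
  1~5: coordinated
  20~23: coordinated
  27~24: coordinated
  32~28: coordinated
  35~33: coordinated

same-cluster vs different-cluster r (Welch t-test): t = 96.89, p = 0

TSS gap probabilities: mean P = 0.080, median P = 0.021
```

Every member pair inside a cluster correlates near r = 1 (the generator
transcribes each cluster as one unit and no modulation was implanted), pairs
from different clusters do not (the Welch p underflows double precision,
hence the printed 0), and the inter-hairpin gaps are short enough that
finding almost no TSS inside them would be statistically unsurprising
(mean P = 0.08). All numbers in the report also appear in machine-readable TSVs
(`pairs.tsv`, `classification.tsv`, `gap_probabilities.tsv`, ...) next to
per-cluster heatmaps of row-z-scored profiles with miRs on top and stars
below.

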