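# Methods

`repeatome` is a desk-scale re-implementation of comparative repeatome
profiling for hybrid and allopolyploid plant genomes from low-coverage
paired-end sequencing: graph-based clustering of unassembled reads into
repeat families, dosage-based abundance expectations for hybrids,
deviation scores for detecting amplification or loss, and the supporting
bias-assessment and accounting machinery — all driven by a synthetic-data
generator with known ground truth.

## The similarity rule and the read graph

Two reads are *similar* when their best local alignment covers at least
55 % of the shorter read at ≥90 % identity, on either strand. The
alignment is Smith–Waterman with match +2, mismatch −3 and a linear gap
cost of −5 (`repeatome._align`). At 90 % identity the expected score per
column is +1.5, so optimal alignments extend through the tolerated
mismatch density instead of fragmenting. A linear (rather than affine)
gap model was chosen because the generator applies divergence as
substitutions only; for substitution-dominated Illumina data the choice
is inconsequential, and it keeps the kernel and its tie-breaking exactly
reproducible. Each pair is evaluated in a canonical frame
(lexicographically smaller sequence first), which makes the predicate
exactly symmetric and invariant to read relabeling.

The production graph joins reads on shared canonical 9-mers. k = 9 is
not tuned: any qualifying alignment spans s ≥ 83 columns with at most
⌊s/10⌋ errors, and (s − e)/(e + 1) > 8 whenever s > 80, so a shared
exact 9-mer on the alignment's strand is guaranteed (pigeonhole). The
join is therefore lossless. Because unrelated 150 bp reads share a
9-mer ~15 % of the time, candidates then pass a cheap gate: the best
gapless run (maximum subarray of +2/−3) on each seeded diagonal must
score ≥30. The gate is conservative for alignments with up to three
short indels and exact for gapless ones; for indel-dominated data set
`SimilarityParams(gapless_screen_min=0)`. On every test set the
production edge set equals the brute-force all-pairs oracle
(`cluster.brute_force_graph`), which is kept deliberately naive.

Communities default to connected components — deterministic and
oracle-checkable; greedy modularity splitting is available as an option.
Clusters get 1-based ids by decreasing size (ties: smallest member read
id). Superclusters merge clusters X, Y when
shared(X,Y)/(unpaired(X)+unpaired(Y)) is *strictly* greater than 0.1,
with shared = mate pairs split between X and Y and unpaired = reads
whose mate is outside their own cluster; superclusters are the
transitive closure of pairwise merges.

## Dosage expectations and deviation scores

All samples in a comparative run are subsampled to the same per-1C
coverage (reads = round(cov·G_1C/150), rounded to whole pairs), with
G_1C from the flow-cytometry 2C value at 1 pg = 0.978 Gbp. Under
equalized coverage a cluster's read count measures the absolute amount
of that repeat's DNA, so the expected hybrid count is

    expected(c) = (d_A · n_A(c) + d_B · n_B(c)) / 2,

the dosage-weighted sum of parental counts over the (d_A + d_B)/2
monoploid complements of the hybrid's 1C. The deviation score is
observed/expected − 1. Expectations are computed on counts rather than
proportions deliberately: a proportion-based expectation multiplied by
the hybrid's total read number is biased for *every* cluster whenever
the hybrid genome size deviates from dosage additivity (which is
exactly the situation a burst creates), whereas count-based
expectations cancel the genome-size change. The proportion variant
(π(c) = (d_A G_A p_A + d_B G_B p_B)/(d_A G_A + d_B G_B)) is provided as
`expected_hybrid_proportions` and equals the count formula whenever the
hybrid is dosage-additive.

For the intermediacy analysis hybrid counts are first rescaled to the
monoploid (1Cx) scale (triploid × 2/3), then per-cluster absolute
count differences to each parent are compared with a paired Wilcoxon
signed-rank test (exact for n ≤ 25, else normal approximation with
continuity correction). The closer parent is the argmin of the mean
distances; the p-value reports whether the asymmetry is decisive.

Bias between datasets is quantified per cluster as the symmetric
relative percent difference |p₁ − p₂| / ((p₁ + p₂)/2) · 100, averaged
per tier (intra-library, inter-library, inter-specific); an absolute
percentage-point variant was considered and rejected because it makes
large clusters dominate the mean. Pairwise tier comparisons use the
same Wilcoxon test, raw p-values by default (Holm adjustment
switchable). Group comparisons of deviation scores (natural vs
synthetic hybrids) use one-way ANOVA on per-sample mean scores and the
Levene test on their dispersion; degenerate variance yields NaN rather
than an error.

## The evidence floor at desk scale

Production analyses admit clusters holding ≥0.01 % of the input reads —
hundreds of reads at ~4 M reads of input. A desk-scale run has ~10⁴
input reads, where 0.01 % is less than one read and the rule admits
2–3-read background clusters whose count ratios are pure noise. The
0.01 % rule is implemented (and tested) as stated, but the deviation,
intermediacy and bias statistics additionally require a small absolute
evidence floor (expected ≥4 reads; ≥8 summed parental or both-sample
reads) — the scale-invariant analogue of what the percentage rule does
at production depth. Without it, sample-exclusive micro-clusters
dominate direction statistics.

## The synthetic-data generator

`simulate` builds parental monoploid genomes from explicit family
specs: each repeat copy is the family consensus with i.i.d.
substitutions at the component's divergence (no indels in v1 — keeps
every copy the length of its consensus, the truth accounting exact and
the alignment oracle trivial), and copies are interleaved with unique
random background spacers (≥150 bp when the background budget allows).
The spacers are a deliberate structural choice: directly adjacent
copies of different families generate junction reads that chain
families into one connected component; spacers ≥119 bp provably
prevent such two-read bridges under the similarity rule. Tandem
adjacency and nesting of distinct elements are not modeled.

A hybrid genome is d_A monoploid complements of parent A plus d_B of
parent B (its sequence is the full 2C complement; 1C is half).
A burst (f, a) multiplies family f's copy number per parental origin
by a, rounded half-up; the truth table records expected and realised
copy numbers, and the hybrid's "measured" genome size includes the
burst, as flow cytometry would.

Reads: pairs = round(cov·len/(2·150)); fragment length ~N(450, 60)
clipped to [150, len]; positions uniform; mate 2 is the reverse
complement of the far fragment end; substitution errors at `error_rate`
(default 0.5 %) carry Phred 10, correct bases Phred 35, so the quality
filter has real signal. Each pair is truth-tagged with the family
owning the largest share of its fragment. Byte-identical FASTQ under a
fixed seed.

### Default study conditions

The comparative system mirrors the study design the method targets:
two diploid parents sharing their dominant repeat families at
moderately different abundances, and one hybrid at dosage 2:1, 1:2 or
1:1, all subsampled to 0.066× of 1C (5 Mb parental genomes; 2 200
reads per parent, 3 300 per triploid hybrid).

The parents carry three families — a Tekay-like element (8 kb;
34 %/28 % of the monoploid genome in parents A/B), a SIRE-like element
(6 kb; 20 %/26 %) and an Angela-like element (5 kb; 20 %/15 %) — i.e.
~70 % repetitive genomes. Two deliberate departures from a full
repeatome, both consequences of desk scale and decided from an a
priori variance analysis:

* **No low-abundance tail in the comparative genomes.** At 0.066×, a
  family at q of the genome yields ~1 650·q read pairs in the hybrid;
  the deviation score's per-seed standard deviation is ≈ 0.033/√q.
  Only families above ~15 % can honestly sit inside a ±0.1 band over
  three replicate seeds. Rare families (satellites, rDNA,
  pararetrovirus) are in this regime exactly the "widening tail" that
  low-coverage comparative clustering cannot quantify — they live in
  the richer `full_parent_specs` system used by the individual
  clustering, annotation, tandem-detection and screening analyses.
* **Abundance differences of 5–6 percentage points per family.** The
  direction statistics (which parent is closer; which tier varies
  more) need per-cluster signals of ~40 reads against count noise of
  ~30–60 reads; differences much below that leave the sign of the
  pooled statistic undetermined at this scale.

Within-family copy divergence defaults to 0.02 (so overlapping reads
from different copies differ ~4–5 %, inside the 90 % rule with
headroom). A comparative analysis needs roughly ≥5× read depth over
each family consensus to recover the family as one cluster; below
that, clusters fragment into consensus-position islands (the bundled
demo therefore runs 0.4× on a 1 Mb system, matching the per-family
depth of 0.066× on 5 Mb).

What passing these simulations does *not* show about real data:
no indels or nested/truncated insertions, no LTR anatomy, no
transposition history (all copies are equidistant from one consensus),
organelle references are synthetic, and hybrid copies are re-drawn
from the consensus rather than inherited from the parental copies.
The generator validates the statistical machinery, not the biology of
any particular genome.

## Annotation and tandem detection

Domain annotation is nucleotide-space: lineage-labeled exemplar
sequences (central segments of the demo families' consensi) stand in
for a protein-domain database, searched with the same 90 %/55 % rule
(seeded diagonals, gapless gate, Smith–Waterman against a window
around the best diagonal). A cluster is annotated when ≥5 % of its
reads hit exemplars of a single lineage; the largest qualifying
lineage wins and multiple qualifying lineages flag a conflict.
Unannotated members of a supercluster inherit the supercluster's
majority lineage (by annotated reads); existing annotations are never
overwritten; ties warn and propagate nothing.

Tandem monomers are detected by base-match autocorrelation: the
smallest lag k ∈ [2, len/2] with ≥80 % self-match and ≥1.5 copies is
reported (smallest lag = the monomer, not a multiple), with a
column-majority consensus over phased copies. Thresholds are config
defaults chosen for a <1 % false-positive rate on random 300 bp
sequence while tolerating 5 % monomer divergence.

Whole-dataset screening (`screen_reads_by_reference`) reports the
percentage of reads matching each reference — the cross-check that
detects repeats too rare to form an above-threshold cluster.

## Accounting

1 pg = 0.978 Gbp; G_1C = (2C/2)·0.978 and G_1Cx = (2C/ploidy)·0.978,
printed at 3 decimals (half-up); coverage = reads·150/G_1C at 2–3
decimals. The bundled 11-accession sample sheet reproduces its printed
1C sizes within 0.001 Gbp (six rows differ by exactly one unit in the
last printed digit — the upstream table's own rounding) and printed
coverages within 0.01. Composition tables must close: category totals
+ small-uncharacterized + singlets = 100 ± 0.01 %, enforced with an
error.

## Numerical and reproducibility notes

Every stochastic step takes an explicit seed; derived sub-seeds stay
below 2³¹. Cluster ids, tie-breaks in the aligner, supercluster
ordering and TSV output are all deterministic, so re-running a
manifest reproduces byte-identical artifacts. Wilcoxon tests switch
from exact to corrected-normal at n = 25. Known limitations: the
gapless gate can in principle drop a qualifying alignment carrying ≥4
indels within 83 columns (impossible for v1 simulated data; disable
the gate for indel-heavy inputs), and `assemble_contigs` is a greedy
substitution-oriented layout, not a real assembler — contigs need not
tile a family and indel-divergent copies would mis-stack.
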