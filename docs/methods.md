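# Methods

`phagehost` reimplements, as a tested pipeline over synthetic data, the
computational workflow used to resolve a complete temperate phage out of a
freshwater SAR11 (*Fonsibacter*-like) host genome and to link lytic phage
to their hosts across metagenome series. This note documents the models,
the synthetic data-generating process, the numerical choices, and what the
tests do and do not establish.

## 1. Synthetic study system

### Host chromosome (`simulate.genome`)

The host is a circular chromosome assembled from back-translated CDS, tRNA
genes at requested sites, and intergenic spacers. Defaults mirror the
system the pipeline targets: 1,136,868 bp, GC 29.6%, 1,229 CDS, a
tRNA-Leu(TAG) integration site, bidirectional replication with `ori` at 0
and `ter` at mid-genome. Tests and analysis drivers run scaled-down copies
(typically 50–300 kb hosts, 12–20 kb phage); the structure, not the size,
is what downstream stages consume, and all sizes used are stated in the
driver/test code.

Two constraints are built into sampling rather than imposed by post-hoc
editing:

* **GC content.** A genome's codon profile is per-class synonymous
  fractions derived from gamma-noise weights times a two-parameter base
  tilt. The first parameter (GC level) is solved by bisection so the
  *expected coding GC equals the target*. Crucially, amino-acid
  frequencies are calibrated jointly: with uniform amino-acid usage,
  coding sequence cannot fall below ~33% GC (Gly/Ala/Pro/Arg codons are
  GC-obligate), so the model shifts AA composition exactly as real low-GC
  genomes do (toward Lys/Ile/Asn/Phe). Realized genome GC lands within
  ±0.01 of the target; the residual ~0.3–0.5% deficit comes from fixed
  start/stop codons and is inside that tolerance.
* **GC skew.** The second tilt parameter (G-vs-C balance) is solved so the
  profile carries *zero intrinsic strand skew*; otherwise profile identity
  would masquerade as replication structure. Planted skew `s`
  (`skew_strength`, default 0.5) then enters as strand-asymmetric
  sampling: intergenic bases use P(G) ∝ (1+s), P(C) ∝ (1−s) on the strand
  that leads on each replichore, and CDS tilt their synonymous choices by
  (1+s)^nG (1−s)^nC (sign flipped for lagging-strand genes). The realized
  windowed skew is ≈ ±0.2 at s = 0.5 — strong but within the range of
  real skewed genomes.

### Lysogen and att sites (`simulate.prophage`)

Integration follows the biology of tRNA-targeting temperate phage: the
shared "core" is the terminal `core_length` bases (default 11 bp) of the
host tRNA; the lysogen is `host[:t1] + phage[c:] + core + host[t1:]` for a
phage rotated to start at the core, leaving identical direct repeats at
attL (ending exactly at the intact tRNA's 3' end) and attR. The phage
carries its own tRNA as a *diverged homolog* (15% body substitutions): its
body precedes the attR core copy so a complete phage tRNA is reconstituted
at attR, but only the core itself is identical to the host copy. The
generator forces the single base flanking each side of the core to differ
between the two copies so that the core is exactly the *maximal* identical
repeat — the defining property of att cores in real systems. Without this,
the trivially duplicated full tRNA (not the 11-bp core) would be the
maximal repeat.

A warning is raised (and recorded in truth) when the core happens to occur
elsewhere in the lysogen — a legitimate hard case that the detector flags
as degenerate rather than silently resolving.

### Read pool (`simulate.reads`)

Fragments are drawn from community members (lysogen, prophage-free host,
free circular phage) proportional to weight × length; fragment lengths are
normal (default 320 ± 30 at 100-bp reads in scaled runs; 350 ± 35 at
150-bp reads at full scale), clipped below at two read lengths so mates
never overlap; mates face inward; substitutions occur at a flat
`error_rate` (default 10⁻³).

Besides FASTQ, the simulator emits an **idealized alignment table**
against the lysogen computed from ground-truth coordinates: each member
carries a block map onto lysogen coordinates, and a read crossing a block
breakpoint (circular-phage junction, or the attB junction of a
prophage-free cell) is reported as a mapper would place it — the longer
segment aligned, *extended through the duplicated core* (the aligner
cannot know where the copy ends), the remainder soft-clipped. The
downstream detector sees only alignment records (`read_id, mate, ref,
pos0, strand, nm, cigar`), never the truth. This replaces an out-of-scope
read mapper; a naive exact-substring mapper is provided for small
error-free tests.

**Planting the circularizing fraction.** The expected number of detectable
junction-crossing pairs from a circular phage of length P is
(E[L_f] − 1 − c)/P per fragment (c core bases at the fragment-end side are
undetectable because the read maps contiguously through the duplicated
core), and the expected number of integrated-state pairs covering an att
core with ≥1 bp flanks is 2(E[L_f] − c − 1)/(L_lys − E[L_f] + 1) per
lysogen fragment. `weights_for_circularizing_fraction` solves the
free-phage weight so that the expected fraction equals the target (5% in
the study conditions). Validated empirically: at 149k informative pairs
the pooled estimate was 0.0494 (z = −1.0 vs the planted 0.05), i.e. any
residual planting bias is below ~0.15 test standard errors at the n ≈
2,000 used in the calibration checks.

### Marker datasets and proteomes

Marker datasets plant genotype presence/absence per sample (with an
enforced "phage ⇒ host present" co-occurrence option), lognormal coverages
(σ = 0.5 around mean depth 10), and optionally an exact per-sample target
fraction (12% in the calibration runs) by rescaling target coverages.
Read-sampled coverage tables draw per-gene read counts Poisson(cov ·
len/R). Phage proteomes are back-translated under (1 − d)·host + d·uniform
synonymous fractions, so d = 0 converges to the host profile and d = 1 is
uniform; amino-acid composition follows the host model.

What the generators do **not** emulate: quality-score models, indels,
assembly artifacts, strain microheterogeneity below the genotype level,
compositional covariation between taxa, and uneven coverage along genes.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated generative model, not robustness to every artifact of
real metagenomes.

## 2. Sequence diagnostics (`seqstats`)

GC content excludes ambiguous bases from numerator and denominator. Skew
is (G − C)/(G + C) per window on the given strand (window 10 kb, step 1 kb
by default — the standard choice for ~1-Mb genomes; exposed as
parameters); windows with no G or C score 0; circular genomes wrap. The
origin/terminus estimates are the global minimum/maximum of the cumulative
skew. In planted genomes they land within half a window of truth; the
contract tested is within two window-widths.

`replication_form_check` scores the cumulative curve against the two-chord
sawtooth through its extrema on the circularly rotated coordinate:
`score = 1 − 2·RMS(curve − chords)/(max − min)`, clipped to [0, 1]. A
perfect sawtooth scores 1; genomes with planted skew score ≳ 0.95;
unstructured genomes (random-walk cumulative curves) concentrate around
0.55–0.6 with a thin upper tail (95th percentile ≈ 0.77 in simulation), so
the default threshold 0.8 separates the two regimes. The chord form (no
free slope fit) was chosen deliberately: a free two-segment least-squares
fit tracks random walks too well.

## 3. Prophage resolution (`prophage`)

**att search** is seed-and-extend on a k-mer index (k = `min_core`,
default 10; floor 8): position pairs sharing a k-mer at a spacing within
the prophage-size bounds (default 10–100 kb) are extended to maximal
identical repeats, deduplicated, and filtered to length ∈ [min_core,
max_core]. An exhaustive per-offset scan serves as the independent test
oracle on inputs ≤ 5 kb.

**Ranking.** Repeat length alone cannot identify an ~11-bp core: a 50-kb
genome at GC 0.3 contains on the order of 10² chance maximal direct
repeats ≥ 11 bp at prophage-like spacing, some longer than a true 11-bp
core (the count grows as N²·q^k with per-base match probability q ≈ 0.29).
The ranking therefore puts integration-site biology first when annotations
are available: candidates whose core copies end exactly at annotated tRNA
3' ends rank highest (2 matches > 1 > 0) — attL ends at the regenerated
host tRNA and attR at the phage's tRNA copy — then core length, then
spacing closest to the expected phage size (default 40 kb), then leftmost.
Chance repeats almost never terminate exactly at a tRNA 3' end, which is
what makes 11-bp cores recoverable (25/25 in the round-trip suite).
Without annotations the length-first ranking is used and is reliable only
for cores ≳ 17 bp at these genome sizes.

**Read evidence** classifies mate pairs at an att pair (mismatch filter
`nm ≤ 3` per mate, mirroring the 98%-similarity coverage filter):

* *junction* (circular excised phage): a soft clip landing exactly on the
  junction coordinates (M-end at attR's core end, or clipped M starting at
  attL's core start), or an everted pair inside the prophage region;
* *attB-spanning* (prophage-free cell): the mirrored clip signature
  (M-end at attL's core end / M-start at attR's core start), or a
  normally-oriented pair bridging the entire prophage at deleted-state
  spacing (span > `max_span`, default 1,000 bp);
* *integrated*: full-length pairs at normal spacing whose fragment covers
  an att core with at least 1 bp of flank on each side.

`circularizing_fraction` = junction / (junction + integrated); with no
informative pairs it is `None` and flagged, never 0. The definition of the
denominator is a choice this package makes explicit (published estimates
of "% of reads circularizing" rarely state one); results are reported
together with the raw counts so other definitions can be recomputed.

**Excision** removes [attL_start, attR_start), keeping one core copy (the
attB site); the phage is returned circular, starting at the core. Which
copy the rotation starts at is a convention; all consumers treat phage
sequences as rotation-invariant.

## 4. Codon usage (`codonuse`)

Profiles are synonymous fractions per amino-acid class (translation table
11; the three stop codons form one class, included in the 64-vector as the
cusp convention does; per-1000 usage is carried alongside). Genomes are
clustered by Euclidean distance on the 64-vector with average-linkage
(UPGMA) hierarchical clustering; profiles are sorted by id before
clustering so the result is input-order invariant. Flat clusters default
to the silhouette-maximizing cut over k = 2…n−1 — an explicit, documented
stand-in for reading subclusters off a heatmap; fixed k or height are
available and the cut rule is surfaced in outputs. Host candidates for a
phage are the non-phage genomes sharing its flat cluster; an empty set is
flagged rather than silently dropped. In calibration runs (divergence ≤
0.1, three decoy hosts at mutual distance ≫ phage–host distance) the true
host is recovered in ≥ 95% of communities.

## 5. Markers (`markers`)

One identity definition is used everywhere: global (Needleman–Wunsch)
alignment identity — identical columns over alignment columns, gaps in the
denominator — under BLOSUM62 with gap cost 11 + k (open 11, extend 1,
BLAST convention). The affine-gap kernel (numba) has a documented
deterministic tie-break (substitution > gap-in-second > gap-in-first), so
an independent DP implementation reproduces it exactly; Biopython's
`PairwiseAligner` cross-checks the optimal score (which is unique even
when alignments are not).

Genotype clustering is greedy and incremental in cd-hit order (length
descending, then id): a sequence joins the first representative at
identity ≥ threshold, else founds a genotype. Threshold 1.0 reduces to
exact dereplication; 0.99 is the genotype threshold; 0.80 the coarse
TerL-grouping threshold. Coverage is Σ aligned bases / gene length after
dropping alignments with > `max_mismatch` (default 3) mismatches; a
missing mismatch field is an error naming the record. Relative abundance
per sample is a/b × 100% (a = target-taxon marker coverage sum, b = all
bacterial/archaeal marker coverage sum) and c/b × 100% for phage; phage
markers are excluded from b; b = 0 is flagged undefined. Alignment-column
filtering removes columns with gap fraction strictly above 0.95 and
optionally trims ambiguous termini up to the first column with ≤ 50% gaps
(an explicit rendering of the usual "ambiguously aligned termini" rule).

## 6. Protein families (`families`)

All-versus-all similarity (supplied as a hit table, or computed internally
with Smith–Waterman for ≤ 2,000 proteins; E-values via a Karlin–Altschul
approximation with the tabulated gapped-BLOSUM62 constants λ = 0.267,
K = 0.041) is filtered at E ≤ 10⁻³ and mutual coverage ≥ 0.5. Greedy set
cover (most uncovered neighbors; ties by summed edge score, then id)
yields subfamilies; members are star-aligned onto the representative.

Distant homology between subfamilies is scored by profile–profile dynamic
programming instead of HMM–HMM search: column frequency profiles
(pseudocount 0.02 per residue) are aligned semi-globally over the
column-score matrix F₁·B62·F₂ᵀ (linear gap 2.0); the raw score is
standardized against 30 column-shuffled alignments of the same pair and
squashed through a fixed logistic centered at z = 8. The resulting
probability-like score keeps the published ≥ 0.95 filter meaningful:
self-comparisons score ≈ 1, shuffled profiles stay far below threshold
(z ≈ 0 ± 1 by construction), and genuinely related subfamilies sit many
null standard deviations above it. Edge weight = probability ×
min-coverage. All calibration constants are fixed and logged; nothing is
fitted at run time beyond the per-pair null.

Markov Clustering follows the canonical recipe: self-loops at each node's
maximum incident weight, column normalization, then alternating expansion
(matrix square) and inflation (elementwise power 2.0, renormalize),
pruning entries < 10⁻⁴, until the maximum change < 10⁻⁶ (cap 200
iterations; non-convergence returns a warning flag). Overlapping attractor
systems merge; each node joins the cluster receiving its largest flow.
Core families are those present in ≥ (1 − slack) of genomes; slack
defaults to 0 and can be raised to tolerate incomplete genomes.

## 7. Problem sizes and determinism

Tests and the acceptance script use scaled systems chosen to keep each
suite in minutes on one CPU: 40–70 kb hosts with 10–20 kb phage for att
recovery (25 systems), ~2,100 informative pairs per circularization
replicate (50 replicates), 20 codon-usage communities of 5 genomes,
50 abundance replicates over a 50-sample series, and 10 pan-genomes of
10 × 8 proteins for family recovery. One full-scale (1.14 Mb) chromosome
is generated for the replication diagnostics. Every random draw flows from
a named `numpy` `SeedSequence` stream derived from the configuration seed;
identical seeds give byte-identical FASTA/FASTQ/TSV outputs.

## 8. Known limitations

* The idealized alignment table assumes a mapper that always finds the
  truth placement; mapping ambiguity and chimeric alignments are not
  modeled.
* Multi-prophage genomes and nested/overlapping repeats are handled only
  by ranking and degeneracy flags, not jointly resolved.
* The profile-comparison probability is calibrated against a
  column-shuffle null, not against a database of true/false homolog pairs;
  its absolute scale is internally consistent but not comparable to
  HHsearch probabilities.
* Validation against the deposited *Fonsibacter*/Fonsiphage assemblies
  requires downloading them into `data/reference/` (see
  `phagehost.reference`); those checks are part of the test suite but can
  only run once the data are present.
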