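# Methods

This note documents the model, the parameter choices and their rationale,
what the simulator does and does not emulate, and the numerical conventions
— in the package's own terms.

## Reference ranges

The genome is partitioned into reference ranges: gene intervals expanded by
`flank_bp` (default 1000 bp) on each side, clipped to the chromosome, with
overlapping *or abutting* expanded intervals merged.  Abutting intervals
are merged deliberately: a zero-width gap would create a boundary with no
inter-range sites and no biological meaning.  Sites between ranges
(intergenic beyond the flanks) are excluded from the model and reported,
not imputed: the trellis is defined on genic haplotypes.  Ranges left with
zero segregating sites are kept as trellis columns carrying a single
all-reference placeholder node so paths remain continuous.

All coordinates are 0-based half-open internally; conversion happens only
at the VCF (1-based) and GFF3 (1-based inclusive) boundaries.  Only
biallelic SNPs enter the model; other records are skipped and counted.
Sites missing in more than half the panel are dropped with a warning, and
panel allele frequencies are computed over non-missing calls (how a real
panel's missingness should be treated is genuinely open; these are the
package's choices and are logged).

## Haplotype sampling from runs of homozygosity

For every (taxon, range) the heterozygosity rate is the number of het
calls divided by the range's length in *base pairs* (not its site count —
the rate is a property of the genomic segment, and the threshold below is
calibrated per bp).  At or below `het_threshold` = 0.001 het/bp, the two
genome copies are classified as identical by descent and one haplotype is
emitted whose alleles follow the homozygous calls.  The comparison is
inclusive (rate ≤ threshold) so the boundary case passes.  Tolerated het
calls inside a passing range are treated as noise (de-novo mutation or
call error), not signal: they take the panel major allele and are counted
to the log.  Missing calls stay missing in the sampled haplotype and are
resolved by the cluster majority at collapse time.

Fully phased genomes (e.g. simulator founders) can instead be loaded
directly via `haplotypes_from_phased`; each phase enters under its own
sample label so adjacency evidence is tracked per genome copy.

## Consensus collapsing

Per range, pairwise haplotype distance is the mismatch proportion over
sites non-missing in both (the het-rate threshold is per bp, but distance
is per compared site — they are different parameters with different
units).  UPGMA (size-weighted average linkage, implemented in-package with
a deterministic tie-break: among minimum-distance pairs, merge the one
whose smallest original member indices are lexicographically least) builds
the merge tree; flat clusters are cut so every within-cluster merge height
is ≤ `max_divergence` = 0.001, i.e. members differ at fewer than 1 in 1000
compared sites.  The consensus allele at each site is the member majority,
ties going to the reference allele — a reproducibility convention; each
member's distance to its consensus is checked and logged if it exceeds the
divergence cut.

## The trellis and its transition model

Nodes per range are the consensus haplotypes; the edge count c(h→h′)
between adjacent same-chromosome ranges counts sample labels (taxa for IBD
sampling, taxon-phases for phased loading) that contributed a haplotype to
cluster h and to cluster h′ — for IBD data this means taxa homozygous in
*both* flanking ranges, the only configuration that gives phase-certain
adjacency evidence.  Chromosome breaks carry no edge; the HMM restarts on
each chromosome from member-count-proportional node priors.

Transition probabilities are smoothed count fractions
P(h′|h) = (c(h→h′) + α/k′) / (Σ c(h→·) + α).  The pseudocount α (default
0.5) is a *total* Dirichlet mass spread over the k′ target nodes, not a
per-cell addition: α is then interpretable as the weight, in observation
units, of "jump to a track the panel never showed" — essentially
recombination onto an unsampled background — and it does not grow with
graph density.  A per-cell pseudocount would add α·k′ phantom transitions
per row; with the 1–2 genome copies of evidence per edge that a small
panel provides and ~40 nodes per range, that flattens the on-track
probability from near 1 to below 0.1 and destroys the HMM's haplotype
persistence.  Closed-loop accuracy is insensitive to α in [0.05, 0.5]
under the total-mass form.

Sparse panels also under-determine transitions directly; the remedy is
path-based augmentation: impute the panel's own taxa (their genotype calls
converted to per-site observations), then add each inferred path's two
haplotype transitions (+1 per boundary each) back into the edge counts.
Nodes are never added.  The build command runs a configurable number of
augmentation rounds (default in the library pipeline: zero; `--augment-iterations`
in the CLI); whether path-derived counts should be down-weighted relative
to sampled counts is unknown, and they are weighted equally.

## Emission model and diploid Viterbi

A read observation is a set of covered site indices within one range plus
the observed alleles (reads spanning a boundary are split per range).  The
emission for state (h_a, h_b) is the product over reads of the diploid
mixture likelihood ½ f(r|h_a) + ½ f(r|h_b), with f(r|h) = 1−ε if the read
matches h at all covered sites (up to `mismatch_tol`, default 0) and ε
otherwise.  So a read consistent with both nodes contributes 1−ε, with
exactly one ≈ ½, with neither ε.  The ½ factor is what lets read *depth*
distinguish homozygous from heterozygous states: under a
"consistent-with-either" rule, (a, a) and (a, x) are exactly tied whenever
all reads come from a, and homozygous ranges can never be called
confidently at any coverage.  ε (default 0.01) absorbs sequencing error,
misassignment and residual within-cluster divergence.  At most
`max_reads_per_range` (default 50) reads are scored per range, taken
deterministically (first N after a stable sort) — a cap against
over-confident deep ranges; with no reads the emission is uniform.

Decoding is exact Viterbi over ordered node pairs.  Because pair
transitions factor into per-haplotype transitions, each boundary update is
done as two O(k³) max-plus sweeps (maximize over the first thread, then
the second) instead of one O(k⁴) sweep; backpointers from the two sweeps
reconstruct the exact joint argmax.  Ties resolve deterministically toward
smaller node indices (the final-state argmax is lexicographic over ordered
pairs).  States are reported as unordered pairs; the global thread-swap
mirror of any path has identical probability and identical unordered
reporting.  Only the argmax path is produced — no per-range posteriors —
and the path converts directly to phased haplotypes and dosages.

## The simulator

The simulator generates the closed-loop validation design: `n_founders`
= 20 phased founders, `generations` = 5 of random mating at constant
`pop_size` = 100, and skim reads at coverages 0.1/0.5/1/5/10×.  Founder
alleles are independent Bernoulli draws at per-site alt frequencies
uniform on [0.05, 0.5]; founders are therefore in Hardy–Weinberg
proportions, unrelated, and maximally diverse for their frequencies.

Genome layout: 2 chromosomes × 30 ranges (2 kb genes, 1 kb flanks, 4 kb
gaps between flanked ranges) with 80 SNPs per 4 kb range.  The density
follows a diverse-panel genic region (~20 SNPs/kb; dense crop haplotype
maps are denser still), and — with the 3-site read window — reproduces the
field geometry in which one short read covers ~4% of a range, so the
*reads per range* at a given coverage match what base-space skim
sequencing delivers.  This ratio, not coverage alone, is what the
0.5×-saturation behaviour depends on; simulations with few sites per range
and proportionally long reads under-supply per-range evidence at low
coverage and push the plateau rightward.

Recombination happens at range boundaries only, with switch probability
`switch_prob` = 0.01 per boundary per meiosis (chromosome starts re-draw
the parental copy): the trellis is the unit of inference, so within-range
crossovers would be invisible to the model anyway.  There is no mutation —
a closed system in which every offspring haplotype segment is an exact
copy of a founder haplotype (lineage bookkeeping records which one, and
the tests assert it).  Reads pick one of the two true haplotypes uniformly,
cover a contiguous window of `read_len_sites` = 3 sites placed uniformly
within the range, and flip each observed allele with probability
`seq_error` (default 0.002; the recovery experiments use 0 to isolate the
graph/HMM stages).  Read counts are Poisson with mean
coverage · sites/read_len per range.

What the simulator does **not** emulate: base-space reads and alignment
(reads are variant-space windows), GBS-style site ascertainment, genetic
maps finer than the range grid, mutation, selection, migration, population
structure beyond a single mating pool, and missing haplotypes — by design
every truth haplotype is present in the graph, which is exactly the regime
where the method's accuracy ceiling is read-information-limited.  Passing
closed-loop tests therefore demonstrates the correctness of the
graph/HMM machinery and its coverage behaviour, not performance under
incomplete haplotype sampling or real sequencing artifacts.

Phenotypes are additive: `n_qtl` = 50 sites with standard-normal effects;
the noise is decorrelated from the genetic values in-sample and scaled so
realized Var(g)/Var(y) equals `heritability` (default 0.5).

## Evaluation and genomic prediction

Accuracy is the squared Pearson correlation of alt-allele dosages pooled
over all (taxon, site) calls (a per-site-averaged variant is available as
an option through the stratified reports).  Pooled R² is sign-blind and
undefined under zero variance (reported as NaN with a warning).  Truth
calls are classified from the *panel* allele frequency: a homozygous call
on an allele with frequency ≥ 0.5 is hom-major (exactly 0.5 counts as
major), otherwise hom-minor; frequency-stratified concordance bins hom
calls by the carried allele's frequency over (0, 1] and het calls by
minor-allele frequency.

Genomic prediction uses VanRaden's method-1 relationship matrix
G = ZZ′ / 2Σp(1−p) (dosages centered at 2p; monomorphic sites excluded;
missing dosages mean-imputed, i.e. zero contribution) in the
single-random-effect model y = μ + g + e.  Per training fold, the
heritability is estimated by REML profiled on a grid h² ∈ {0.01…0.99}
(after one eigendecomposition of the training G), and held-out phenotypes
are predicted by BLUP.  Accuracy is the Pearson correlation of predicted
vs observed phenotype *within the held-out fold*, averaged over folds per
replication: pooling predictions across folds before correlating induces a
known negative bias through fold-specific training means.  For the same
reason, permutation nulls draw a fresh permutation per replication — a
single fixed permutation can sit far from zero by chance alignment with
family structure (null SD ≈ 0.1 at n = 200 here).  A leave-one-out mode
reports one pooled accuracy.  Multi-environment random effects (block,
location, year, interactions) are out of scope: synthetic phenotypes carry
no environmental structure, so y = μ + g + e is the matching model.

## Numerical conventions and degenerate inputs

- Dosage sentinel −1 for missing calls; haplotype allele sentinel −1 for
  missing sites in sampled haplotypes.
- Zero-read taxa are imputed from priors and transitions with a warning.
- A pseudocount of 0 is allowed only when every node has outgoing counts.
- `transition` rows are validated to sum to 1 within 1e-12 at model
  construction.
- All stochastic stages take a `numpy` Generator seeded from
  (config seed, stage salt); identical seeds give byte-identical outputs
  end to end, including serialized graph JSON and VCFs.

## Problem sizes used by the test suite and acceptance script

Closed-loop runs use the generator defaults (20 founders, 100 offspring,
60 ranges, 4800 SNPs) with three replicate seeds for the coverage-plateau
check; the genomic-prediction check enlarges the population to n = 200.
The Viterbi oracle enumerates all diploid paths on 200 random trellises of
≤5 ranges × ≤4 nodes; the UPGMA oracle compares against scipy's
average-linkage on random haplotype sets whose distances are tie-free
(merge order under tied distances is ambiguous in any UPGMA, so comparing
implementations is only well-defined without argmin ties).

## Known limitations

- The emission treats reads as conditionally independent given the node
  pair; overlapping reads from the same molecule would violate this.
- Consensus collapsing discards within-cluster variation (< 0.001); the
  imputed genotype at such sites is the cluster majority, a floor on
  attainable accuracy in real data.
- The lumped cluster-level Markov chain approximates the underlying
  per-copy track process; where many copies share a node and then diverge,
  path probabilities are diluted relative to per-track truth.
- Real-data pathways (alignment, variant calling, external phasers) are
  out of scope; evidence enters as site-indexed observations or per-site
  pileup tables.
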