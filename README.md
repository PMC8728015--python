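# haplograph

Haplotype-graph genotype imputation for heterozygous diploid species —
sample phased haplotypes from runs of homozygosity, collapse them into a
consensus haplotype trellis, and impute whole-genome diploid genotypes from
very low-coverage ("skim") sequencing with a two-path Viterbi HMM.  A
forward simulator and an evaluation/genomic-prediction suite make every
stage verifiable on synthetic data.

## The problem

Genomic selection and association studies need dense genotypes for many
individuals, but per-sample sequencing depth is expensive.  Imputation from
a reference panel closes the gap — yet in highly heterozygous crops (e.g.
clonally propagated root crops) both genome copies must be modelled, and
statistical phasing from short reads is unreliable.  Two observations make
the problem tractable:

1. **Runs of homozygosity are free phasing.**  Within a breeding pool,
   identical-by-descent (IBD) segments are common.  Where an individual is
   (nearly) homozygous across a genomic region, its haplotype can be read
   directly from the genotype calls — no phasing needed.
2. **A pan-genome of haplotypes turns imputation into path-finding.**  The
   genome is partitioned into *reference ranges* (genic regions ± 1 kb
   flanks, overlaps merged).  Per range, sampled haplotypes are clustered
   (UPGMA on pairwise mismatch distance, cut at maximum divergence 0.001)
   into consensus haplotypes — the nodes of a trellis graph.  Edges connect
   nodes of adjacent ranges, weighted by how many sampled genome copies
   carry both.

## The model

For a diploid individual the hidden state at range *t* is an ordered pair
of nodes (h_a, h_b).  With read set R_t for range *t*:

- **Emission** — the diploid read likelihood
  P(r | h_a, h_b) = ½ f(r|h_a) + ½ f(r|h_b), where f(r|h) = 1−ε if read r
  matches h at every covered site and ε otherwise (ε = 0.01 default).
- **Transition** — per haplotype, the smoothed edge fraction
  P(h′|h) = (c(h→h′) + α/k′) / (Σ c(h→·) + α), with total Dirichlet mass
  α = 0.5 spread over the k′ next-range nodes; pair transitions factor as
  the product.  Inferred whole-genome paths can be folded back into the
  counts ("augmentation") without adding nodes.
- **Decoding** — exact Viterbi over the k² pair states (factored into two
  O(k³) max-plus sweeps per boundary), independently per chromosome,
  starting from member-count node priors.  The argmax path yields phased
  haplotypes and unphased dosages per site.

Accuracy is scored as the squared Pearson correlation (R²) of alternate
allele dosages against truth, plus concordance stratified by allele class
(hom-major / hom-minor / het relative to panel frequency) and frequency
bin.  Imputed genotypes feed a GBLUP mixed model y = μ + g + e,
g ~ N(0, G σ²_g) with VanRaden's G, for cross-validated genomic prediction.

## Worked example

`examples/02_closed_loop_imputation.py` runs the closed-loop experiment at
desk scale: 20 phased founders populate the graph, 30 offspring from five
generations of random mating are imputed from noiseless skim reads:

```
graph: 20 ranges, 800 consensus haplotype nodes
imputing 30 offspring at 800 SNPs
  coverage  0.1x: dosage R^2 = 0.8537
  coverage  0.5x: dosage R^2 = 0.9839
  coverage  1.0x: dosage R^2 = 0.9943
  coverage  5.0x: dosage R^2 = 1.0000
```

Every offspring haplotype is a mosaic of founder haplotypes already in the
graph, so accuracy is limited only by read information: it saturates by
about 0.5× coverage — a handful of reads per range suffices to identify
both paths.  The other examples cover IBD haplotype sampling
(`01_ibd_haplotype_sampling.py`), accuracy stratification by allele class
and frequency (`03_accuracy_stratification.py`), and genomic prediction
with imputed genotypes (`04_genomic_prediction.py`).

A thin CLI wires the same stages for file-based use:

```bash
haplograph simulate --out sim/ --seed 1
haplograph build   --panel sim/founders.vcf --genes sim/genes.bed --out graph.json
haplograph impute  --graph graph.json --reads sim/reads_1x.tsv --out imputed.vcf
haplograph evaluate --imputed imputed.vcf --truth sim/offspring.vcf --out report.json
haplograph predict-cv --genotypes imputed.vcf --phenotypes sim/phenotypes.tsv \
    --seed 1 --out cv.json
```

## Scope

The package operates in variant space (biallelic SNPs): read evidence is
site-indexed observations, either simulated or converted from per-site
pileups; base-space alignment, multiallelic/structural variants and
polyploids are out of scope.  See `docs/methods.md` for the model details,
parameter rationale and known limitations.
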