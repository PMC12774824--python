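# Methods

## The chimeric-panel algorithm

The panel builder operates on one contig of diploid biallelic genotypes with
missing calls encoded as a sentinel (−3 internally, `./.` in VCF). Input is
expected to be pre-filtered: multiallelic sites removed and sites with more
than 20% missing calls dropped (`validate_and_filter`, threshold
configurable). The algorithm assumes observed genotypes are error-free;
quality-based filtering belongs upstream.

**Window scan.** A window of `window_size` bp (default 1,000) is anchored at
the first unprocessed variant site. If fewer than the required number of
samples have complete genotypes across all sites in the window, the window
contracts from the right. Contraction is implemented as removal of the
rightmost *variant site* rather than literal 1 bp decrements: a decrement
that removes no site cannot change the complete-sample set, so the two are
equivalent while skipping no-op iterations. The left edge stays fixed. When
contraction reaches a single site that still lacks enough complete samples,
the scan terminates with an error naming the position (CLI exit code 3);
the remedy is stricter input filtering or a smaller panel.

**Bucket partition.** Each accepted window yields a bucket (interval
endpoints = first/last included site positions; the site run; the complete
sample set). The next window is anchored immediately after the last site the
bucket *kept*, so sites shrunk off the right edge are re-processed. This
makes bucket site runs contiguous, disjoint, exhaustive and ordered — the
partition invariant the tests assert. Windows containing no variant site are
skipped by advancing the anchor to the next site. The minimum complete-sample
requirement defaults to the panel size `K` (a separate `--min-complete`
override exists).

**Assembly.** Per bucket, `K` individuals are drawn uniformly without
replacement from the complete set with a seeded generator; slot order is draw
order; genotype values and phase separators are copied verbatim. No attempt
is made to match individuals across adjacent buckets — slot continuity is
deliberately random. Identical (matrix, config) input yields a byte-identical
panel VCF.

## Bundled imputation engine

A standard haplotype-copying (Li–Stephens) HMM imputes each target haplotype
independently against the panel's 2K haplotypes. States are panel
haplotypes; between adjacent sites at distance `d` bp the chain stays with
probability `exp(-ρd)`, otherwise jumps to a uniformly chosen state;
emissions are `1−ε` on allele match, `ε` on mismatch, 1 at missing sites.
Posteriors come from the scaled forward–backward recursion (the rank-one
transition makes each step O(states)); queries are processed in batches for
vectorisation. A missing allele is called alternate iff its posterior
exceeds the threshold (default 0.5); exact ties go to the reference allele,
making output deterministic. Defaults: ρ = 1e-6 per bp (the 1 cM/Mb scale),
ε = 1e-3.

The bundled engine requires phased targets and panels — phase is known for
synthetic truth, and re-implementing a production phasing model is out of
scope. Unphased real data should go through an external engine; an adapter
stages target/panel/map files and shells out to a user-supplied Beagle-style
jar, and a PLINK-format writer produces uniform-rate genetic maps
(`cM = bp × rate / 1e6`) for rate sweeps in the 0.5–2 cM/Mb range. Target
sites absent from the panel are left missing and reported, mirroring the
discarding behaviour of conventional engines confronted with novel variants.

## Masking and scoring conventions

- Masking selects exactly `floor(fraction × n_samples × n_sites)` cells among
  currently observed cells, both alleles at once (no half-leakage from
  heterozygotes), walking a seeded permutation and skipping sites whose
  missingness budget is exhausted. The per-site cap (default 20%, matching
  the input-filter rule) bounds pre-existing + new missingness; an
  infeasible request fails loudly rather than under-delivering. A 30% global
  fraction cannot fit a 20% per-site budget, so the 30% study condition runs
  with the cap disabled — plain uniform masking.
- Accuracy is the proportion of masked cells whose imputed ordered allele
  pair matches the truth exactly (`0|1` ≠ `1|0`); unphased truth is compared
  unordered. Still-missing cells and cells at engine-discarded sites count
  as incorrect: information loss is penalised, not excused. Cell-weighted
  overall accuracy is primary; an unweighted per-site average is also
  reported since the two can differ when masking is uneven across sites.
- MAC is computed from the original unmasked matrix; bins default to upper
  edges {2, 5, 10, 20, 50, 100} with a closed-left convention (MAC equal to
  an edge joins the lower bin) and are configurable, as no canonical edge
  set exists. Replicates are summarised as mean ± sd/√n (se = 0 for a single
  replicate, flagged).

## Synthetic cohort generator

The generator emulates a single-population diploid cohort: each of the
2N haplotypes is a Markov mosaic over `n_founders` founder haplotypes
(switch to a uniform founder with `switch_prob` per inter-site interval,
copy the founder allele, flip it with `flip_prob`), giving block-wise LD and
shared haplotype structure — the property the chimeric panel relies on.
Founder allele frequencies are Beta(0.5, 0.5); positions are evenly spaced.
Defaults (the "benchmark" preset used by the experiment harness and the
acceptance script): 8 founders, 200 diploids, 2,000 sites at 500 bp spacing
(1 Mb), switch_prob 0.002 per interval (mean founder-block ≈ 250 kb),
flip_prob 5e-4.

What the generator does **not** emulate: realistic site density (real
short-read cohorts carry tens of variants per kb, versus two per kb here),
a rare-allele-dominated site-frequency spectrum (Beta(0.5, 0.5) has mean
MAF ≈ 0.2; real spectra are far more skewed), non-random missingness
(GC/coverage-driven clustering), genotype error, multiple populations, or
recombination-rate variation. Passing tests on this cohort therefore
demonstrate the *machinery* — partition invariants, exact masking, HMM
correctness, scoring conventions — not field performance on real data.

## What the evaluation numbers mean

Two structural facts dominate accuracy on the default preset and are worth
stating explicitly:

1. **Within-bucket context is the panel's only context.** Because per-bucket
   selection randomly reshuffles source individuals, a panel haplotype's
   identity carries no information across bucket boundaries; everything the
   imputer can learn about a masked allele comes from sites inside the same
   bucket. At 500 bp spacing a 1,000 bp window holds exactly two variant
   sites, so a masked haplotype allele has at most one informative
   within-bucket neighbour, capping phase-aware genotype accuracy near 0.7
   at *every* masking fraction (measured ≈ 0.69 at 1%, 10% and 30%). The
   same pipeline on a cohort with 10 bp spacing (100 sites per window)
   reaches 0.99 at 1% masking, and the bundled imputer with a coherent
   (non-chimeric) external panel reaches ≈ 0.995 at covered sites — the
   geometry, not the engine or the algorithm, is the binding constraint.
   Higher masking additionally shrinks buckets (a sample is complete across
   k sites with probability ≈ (1−f)^k), which is why window/panel-size
   trade-offs matter on dense data.
2. **Coverage loss is scored as error.** In the novel-variant experiment the
   external panel loses 20% of its positions; with discarded-site cells
   counted incorrect its overall accuracy is bounded near 0.8 × (accuracy at
   covered sites) ≈ 79.6%, while the chimeric panel retains 100% site
   coverage by construction at every drop fraction.

The acceptance script reports exactly these computed quantities; problem
sizes (2,000 sites, 200–250 diploids, 3 replicates) are the preset study
conditions and keep a full run around one minute on a single CPU.

## Numerical and design notes

- Forward–backward runs in scaled linear space; ε > 0 guarantees strictly
  positive emission rows, so no underflow at these problem sizes. Posterior
  normalisation is asserted to 1e-9 against exhaustive path summation on
  small instances.
- Half-calls (`0/.`) are coerced to fully missing on read: the call model is
  all-or-nothing, consistent with both-allele masking.
- Coordinates are 1-based inclusive bp throughout, matching VCF; bucket
  intervals use first/last included site positions.
- GVCF symbolic `<NON_REF>` alleles are rejected; only the GT FORMAT field
  is read, and writes emit GT-only VCF v4.2 (bgzip when the path ends in
  `.gz`).
- Known limitations: one contig per run (run chromosomes in parallel
  externally); fixed panel size per bucket; no haplotype-similarity-aware
  slot matching across windows; the bundled imputer does not phase.
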