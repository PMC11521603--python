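# Methods

`defcnv` estimates diploid copy numbers of the bovine β-defensin gene family
from short-read depth and from droplet-digital PCR, detects genes that gain
and lose copies together, and tests whether transcript abundance tracks
genomic copy number. This note records the models, the defaults and why they
are what they are, and what the synthetic cohorts do and do not establish.

## Gene catalogue

The packaged catalogue (`defcnv/data/catalogue.tsv`) lists 54 annotated
β-defensin regions on the ARS-UCD1.2 cattle assembly with 1-based inclusive
coordinates, the human orthologue where one exists, and an *assay group* per
record. Assay groups exist because short reads cross-map freely among
near-identical paralogues: the two annotated *DEFB103* regions (*DEFB103A*,
*DEFB103B*) are quantified as one group with `reference_copies = 3` — the
assembly carries three *DEFB103* copies (a *DEFB103A*-like region lacking an
initial methionine has no separate catalogue row, which is why 54 rows stand
for a 55-gene family; the third copy is carried in the group's copy count
rather than as a row). Every other gene is its own singleton group. The
expected diploid copy number of a group is `2 × reference_copies`: 2 for
singletons, 6 for *DEFB103*.

BED output converts 1-based inclusive coordinates to 0-based half-open
(`start − 1`, `end`), the convention genome browsers and `bedtools` expect;
the conversion round-trips losslessly. Interval overlap is closed (records
sharing only an endpoint count as overlapping) — conservative, because even
a single shared base can double-count reads.

C-terminal tail length is the residue count strictly after the last cysteine
of the mature peptide; β-defensins close their six-cysteine core at that
residue, and an extended tail is where mucin-type O-glycans attach. A
sequence without cysteines raises an explicit error rather than returning 0,
since "no core" and "no tail" are different statements. The Ser/Thr count in
the tail is a deliberate proxy for O-glycosylation potential (O-glycans
attach to Ser/Thr hydroxyls); it flags candidates, it does not predict
sites. The "long tail" cutoff defaults to 20 residues — the family separates
into tails of ~40+ residues versus under ~10, so any cutoff in between
draws the same line; 20 is configurable.

## Read-depth copy number

For sample *s*, assay group *g* and reference gene *TP53* (two copies in
every diploid genome):

    ratio(s, g)    = count(s, g) / count(s, TP53)
    estimate(s, g) = expected_cn(g) × ratio(s, g) / baseline(g)

where `baseline(g)` is the cohort mean of `ratio(·, g)`. Dividing by the
reference count removes per-sample depth; dividing by the cohort baseline
removes per-gene factors (region length, mappability), which also makes
explicit length normalisation unnecessary — any per-gene constant cancels.
With the mean baseline the cohort mean of the estimates equals the expected
CN *exactly*, by construction; the test suite asserts this to 1e-12.

Two consequences of that construction are worth stating plainly:

* **Bias under common variation.** Pinning the cohort mean to the expected
  CN is only unbiased when deletion/duplication alleles are rare. If a
  deletion segregates at high frequency, every estimate is inflated by
  `expected / mean(truth)`. A `baseline="median"` option resists this for
  variants under ~50% frequency; the default stays `mean` because it is the
  canonical form of this normalisation.
* **Scale invariance.** Multiplying all counts of one sample by any
  constant leaves its estimates unchanged (the reference ratio absorbs it),
  so sequencing depth differences cannot masquerade as CNV.

Read counting assigns a read to a region when its alignment start falls
inside the region (no length-weighted overlap), excludes unmapped and
duplicate-flagged reads, and deliberately **keeps MAPQ-0 multi-mappers**:
paralogous regions attract ambiguous alignments, and discarding them
systematically deflates multi-copy estimates. Counts for regions in one
assay group are summed before normalisation. Samples below 10× mean genome
coverage are excluded before estimation (strictly below: 10.0× is
retained); missing coverage metadata is an error, never silently ignored.

Calling uses one fractional rule: the normal band is
`expected_cn × (1 ± 0.25)`, with strict inequalities outside it. This
single rule yields <1.5 / >2.5 for two-copy genes and <4.5 / >7.5 for the
six-copy *DEFB103* group — both threshold sets are the same statement at
different expected CN, which is why the implementation parameterises the
fraction rather than the absolute cutoffs.

## Covariation blocks

If several genes sit on one copy-number-variable segment, their estimates
rise and fall together across individuals. The detector computes the
gene × gene Pearson correlation of CN estimates (Spearman by flag), keeps
pairs with signed r ≥ threshold (default 0.9; negative covariation has no
shared-segment reading, so |r| is not used), and chains pairs into blocks as
connected components of the pair graph — components, not cliques, because
pairwise evidence A–B and B–C already places all three on one candidate
segment. Each block reports its weakest internal pairwise r from the full
matrix. Zero-variance genes yield missing correlations and can never
satisfy the threshold.

Blocks whose members' genomic intervals overlap are flagged as likely
counting artifacts: two annotations over the same exons receive the same
reads and correlate at r ≈ 1 without any shared variable segment. The flag
annotates rather than removes, since overlap and genuine co-variation are
not mutually exclusive.

## ddPCR quantification

A reaction partitions template into N droplets (default 20000) and counts
how many fluoresce. Under Poisson partitioning the mean template copies per
droplet is

    λ = −ln(1 − k/N)

for k positive droplets. Copy number is the λ ratio to a *TP53* reference
well scaled by the reference's diploid CN: `CN = 2 × λ_target / λ_ref`.
Droplet volume (0.85 nL default) enters only the reported concentration in
copies/µL — it cancels in the ratio, and the tests assert that. All
droplets positive is a saturation error, not a number: λ is unbounded there
and the assay must be diluted. EvaGreen intercalating-dye chemistry measures
one assay per well, so target and reference are separate wells of one
sample; replicate wells are pooled by summing droplets before estimating λ,
which is the maximum-likelihood combination for Poisson partitions. The
*DEFB103* assay is modelled as one primer pair binding all three loci with
equal efficiency (equal efficiency is an assumption; the droplet counts
cannot distinguish it from unequal binding). Classification reuses the
sequencing caller's fractional rule verbatim; a dedicated concordance
report gives correlation, mean bias (ddPCR − WGS) and categorical-call
agreement for matched samples.

## Expression and dosage

TPM is computed as `1e6 × (count/length) / Σ(count/length)` per sample;
rows sum to 1e6 except all-zero samples, which stay zero with a warning.
The two-group differential stage is a deliberately simple screen: log2 fold
change of group means with a 1-TPM pseudo-count, Welch's t on
log2(TPM + 1), Benjamini–Hochberg FDR at 0.1. It flags large
maturation-scale shifts; it is not a negative-binomial count model and its
fold changes are not comparable to one.

Dosage correlation is computed per gene across matched samples on
untransformed TPM by default (log1p by flag), Pearson by default (Spearman
by flag), reporting r, the two-sided nominal p, r², and the slope sign.
Nominal p is the decision statistic; a BH-adjusted column is emitted
alongside for transparency. Genes with zero variance in either variable are
reported as missing rather than given an arbitrary r.

## Synthetic cohorts

The generator exists so every stage can be scored against planted truth.
Its default conditions: 100 diploid individuals; per-sample depth normal
around 30× (sd 5, floored at 5×); 150 bp reads; region counts Poisson with
mean `depth × length × CN / (2 × read_length)`; a 19 kb two-copy reference
region; 20000-droplet wells at reference λ = 0.2 copies/droplet.

* **Copy numbers** are the sum of two independent haploid alleles, so
  heterozygote/homozygote structure and Hardy–Weinberg checks are
  meaningful. Bi-allelic genes carry deletion/duplication alleles at 5%
  each by default (diploid CN mostly 1–3); the multi-allelic *DEFB103*-like
  gene draws haploid counts from a truncated geometric (mean ≈ 3,
  support 0–15), giving diploid totals up to ~30 — wide multi-allelic
  variation of the kind a 1–29 diploid range implies.
* **Segments**: one shared diploid event (allele frequencies 0.2 deletion /
  0.15 duplication by default, segment CN variance ≈ 0.7) perturbs all
  member genes identically — the default cohort plants one three-gene
  block (DEFB113–DEFB112–DEFB110-1).
* **Expression** is linear in CN with Gaussian noise, truncated at zero.
  Default coupled genes plant |r| ≈ 0.5 (noise set to
  `|slope| × sd(CN) × sqrt(1/r² − 1)`), one positive (DEFB10), two negative
  (DEFB127, DEFB103), plus a null high-expression gene.
* **ddPCR wells** draw positives ~ Binomial(N, 1 − e^(−λ)) with
  `λ_target = λ_ref × CN/2` — the exact model the quantifier inverts.

Everything is drawn from one seeded generator in a fixed order; a fixed
seed reproduces every layer byte-identically, and simulation without an
explicit seed is an error.

What the simulations do **not** emulate: GC and mappability bias,
overdispersed (non-Poisson) coverage, read-level cross-mapping between
paralogues (cross-mapping is represented only by summing assay-group
counts), unequal ddPCR amplification efficiency, and the compositional or
batch structure of real RNA-seq. Passing recovery tests therefore shows the
estimators are correct under their stated assumptions at realistic depths
and cohort sizes — not that real cattle cohorts are free of the biases the
assumptions exclude.

## Problem sizes and numerical choices

Recovery checks run at the cohort sizes the estimators are designed for:
n = 100 at 30× for integer CN recovery and block detection (50 replicates),
n = 94 for dosage slope-sign recovery (300 replicates), 1000 replicates of
20000-droplet wells for ddPCR precision, and 1000 binomial replicates per λ
for the estimator-consistency check. These finish in seconds while leaving
the Monte-Carlo error far below the margins being asserted.

Ties and degenerate inputs: threshold comparisons are strict on both sides,
so estimates exactly at a cutoff are "normal"; a zero cohort-baseline ratio
makes a gene's estimates missing (with a warning) rather than infinite;
zero reference counts are an error for the affected sample; correlation
thresholds outside (0, 1] are rejected.

## Known limitations

* No segmentation or breakpoint model: the unit of analysis is the
  annotated gene region, and block detection is correlational, not
  positional.
* The mean-baseline bias described above is inherent to the normalisation;
  the median option mitigates but does not remove it.
* The differential-expression stage is a screen, not an inference engine.
* Orthologue annotations are consumed from the catalogue, never computed.
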