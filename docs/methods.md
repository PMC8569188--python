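# Methods

## The event model

A tumour is a rooted tree of clones hanging off a `germline` root. Each node
carries a non-negative **branch weight**, interpreted as a relative
mutational branch length: tumour-wide somatic SNV, indel and CNV totals are
split across branches by a multinomial draw with probabilities proportional
to the weights. (The structure-string format leaves the second field's
semantics open; relative branch length is the reading we fix, and the one
that makes mutation counts scale with branch "age".)

Event classes and their defaults:

| parameter | default | meaning |
|---|---|---|
| `snvgermline`, `indgermline` | 0.0014, 0.00014 /bp | germline SNV/indel rates; counts are Binomial(genome length, rate) |
| `dbsnpsnvproportion`, `dbsnpindelproportion` | 0.9, 0.5 | fraction of germline variants drawn (without replacement) from a known-sites panel |
| `cnvrepgermline`, `cnvdelgermline` | 160, 1000 | exact per-genome germline CNV event counts (read as exact counts, not Poisson means — the simplest reading of printed integers) |
| `snvsomatic_total`, `indsomatic_total` | 1000, 100 | tumour-wide somatic point-mutation burdens |
| `cnvsomatic_rep`, `cnvsomatic_del` | 20, 20 | tumour-wide somatic CNV counts |
| `aneuploid` | 4 | per-tumour count of single-chromosome gain/loss events (uniform clone and chromosome, gain/loss equiprobable) |
| `wgdprob` | 0.333 | probability the tumour contains exactly one whole-genome duplication, on a uniformly chosen clone; the germline is never duplicated |
| `cnv*mean/variance/multiply` | germline (−10, 3, 1e6); somatic (−1, 3, 1e6); indel (−2, 2, 1) | lognormal lengths: `round(exp(N(mean, variance))·multiply)`, floored at 1 bp |
| `cnvcopiesmean/variance` | 1, 0.5 | added copies of a replication: `max(1, round(exp(N(mean, variance))))` (the discretisation is ours; the distribution parameters are the documented ones) |

The germline/somatic rate and length parameters above are the published
whole-genome simulation settings; the somatic *totals* are not published, so
the defaults are burdens that give a few hundred to a thousand truth
variants on the 2 × 100 kb toy genome — enough to estimate per-sample
metrics with low variance while keeping a full chain sub-minute. Note the
somatic CNV length scale (median ≈ 368 kb) exceeds toy contig lengths, so on
toy genomes somatic CNVs are effectively arm/chromosome-scale events; pass a
smaller `cnvsomaticmultiply` for focal toy CNVs.

## Genome profiles as copy-instance lineages

Each clone's genome is a per-chromosome list of **copy instances**:
independent lineages of one parental allele copy (haplotype A or B), each
covering a possibly fragmented set of half-open intervals and carrying the
set of point variants that arose on it. Events on a branch get uniform
timestamps and are applied in time order:

* a **replication** picks one instance overlapping the event region
  (uniformly, unless the event pins a target copy) and appends `added_copies`
  clones of its restriction to the region, duplicating the variants it
  carries there — so an SNV followed by a +1 replication of its copy has
  multiplicity 2 and locus total 3;
* a **deletion** removes the region from one instance and the variants that
  lose coverage; deleting an already-zero-copy region is skipped with a
  warning;
* **WGD** clones every instance; **aneuploidy** clones or removes one whole
  chromosome instance;
* a **point variant** lands on one covering instance (its assigned haplotype
  for germline variants, uniform for somatic); if no copy covers the
  position it is simply absent from that clone.

Children copy the parent profile before applying their own branch events, so
inheritance is automatic and exact. Copy number at a position is the count
of covering instances (per haplotype: major/minor), a variant's multiplicity
`m` the count of covering instances that carry it, and the locus total `n`
the count of covering instances. Everything downstream (expected VAFs,
segment tables, ploidy) is derived from these integer counts; no sequence is
rearranged.

## Bulk samples and truth

A bulk composition assigns read fractions to clones plus a normal fraction
(purity = 1 − normal). True CCF of a variant is the sum of *tumour
proportions* (clone fractions renormalised to exclude normal) over the
clones that still carry it — clones whose profile lost the variant to a
deletion are excluded by default (`account_deletions=False` restores the
plain subtree sum; whether published truth CCFs make this subtraction is not
stated, so both are available). Expected VAF mixes multiplicities and locus
totals by read fraction, with the germline locus total (2 at autosomal loci
without germline CNVs) weighting the normal compartment. Observations are
count-level: Poisson depth, binomial alternate counts (beta-binomial with
dispersion ρ via concentration (1−ρ)/ρ when requested). Count-level
simulation is the primary path; the paired-FASTQ emitter is a deliberately
simple extra (uniform fragments, substitution errors only, SNV-consensus
haplotypes) for pipelines that need sequence-shaped input — it models no
capture bias, insert-size distribution, duplicates or platform error
profile. Sex chromosomes are not simulated; toy contigs are autosomal-like.

## Evaluation semantics

* **Matching** is allele-exact on (chrom, pos, ref, alt) after
  left-normalisation (suffix/prefix trimming plus reference-guided left
  shifts for indels). No positional tolerance: a call at the right position
  with the wrong allele is both a false positive and a false negative.
  Region restriction removes truth outside the regions from the recall
  denominator rather than counting it as missed.
* **Zero-denominator conventions**: precision of an empty call set and F1 of
  an all-zero pair are 0, keeping F1 defined on degenerate inputs. Unscored
  calls rank below all scored calls in PR thresholding; PR points group tied
  scores and the final point equals the unthresholded metrics. Empty VAF
  bins report NaN, not 0.
* **Copy number**: tracks are compared on a fixed bin grid (length-weighted
  segment means; bins with no covering segment are missing and excluded).
  Truth mode emits per-clone tracks plus a tumour-proportion-weighted `bulk`
  track (purity-independent); both are exported because it is ambiguous
  which a given caller should be judged against. Ploidy classes use a
  tolerance of 0.3 (the published classification is visual; 0.3 separates
  diploid/tetraploid confusions cleanly), testing accurate, then halved,
  then doubled.
* **CCF**: MADif averages per-sample mean absolute differences with equal
  sample weight, over called true variants only (false positives and
  uncalled truth are excluded upstream; samples with zero true positives are
  dropped with a log note rather than failing a whole report). The true
  partition for the adjusted Rand index assigns one label per origin clone.
  We report the mean ARI across samples (the "absolute" in some phrasings is
  read as magnitude of agreement, not an extra |·|). The K-means baseline
  uses scikit-learn with a fixed seed and 10 restarts; cluster CCF is the
  cluster mean, and k is reduced with a warning when fewer distinct values
  exist.
* **Deconvolution inputs**: CNA segments contribute their major/minor copy
  numbers to a variant only when their cellular fraction is ≥ 0.5
  (inclusive, matching the "in ≥50% of cells" rule); otherwise, and outside
  all segments, the neutral 1/1 state is used with normal copy number 2.

## What the fixtures do and do not show

Toy references are uniform random sequence; known-site panels are uniform
positions. The synthetic caller drops truth at a flat rate, injects
uniform-position false positives and jitters VAFs with truncated Gaussian
noise — enough to exercise every metric path with known labels, but it has
no coverage-, mappability- or signature-dependent error structure, no
alignment artefacts, and no neutral-tail mutations. Passing tests therefore
certify the bookkeeping and the metrics, not the real-data difficulty of
calling or deconvolution. Determinism: one seeded generator per run;
identical seed + config give identical outputs, and truth tables are
independent of the observation RNG.

## Problem sizes

Default test/acceptance scales: 2 × 100 kb (toy chains), 5 × 1 Mb (germline
rate checks), 3,000 event-level tumours for the WGD-fraction check, 20
replicates/seeds for stochastic assertions with 3-standard-error bands.
These sizes keep the full suite to a few tens of seconds while leaving
binomial standard errors well below the effect sizes being asserted.
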