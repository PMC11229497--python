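# Methods

This note documents the models and procedures `cscm-sieve` implements, the
defaults it ships with, what the synthetic data generator does and does not
emulate, and the numerical choices that were genuinely open.

## Genotype model and filtering cascades

All filters operate on a four-state genotype matrix (hom_ref / het / hom_alt
/ missing) over biallelic SNVs and small indels.  Multi-allelic records are
rejected by default because every downstream predicate is defined on a
single alternate allele; an explicit split mode decomposes them instead when
a user wants that behaviour.

The three inheritance scenarios are pure genotype predicates plus a
consequence requirement, applied as staged funnels so that each stage's
surviving count is reportable:

1. **Shared recessive** (one allele explains all cases): hom_alt in every
   case → protein-changing → alternate allele entirely absent (no het, no
   hom_alt) in all controls.
2. **Per-case recessive**: hom_alt in the case, every *sequenced* parent het
   (a duo constrains only its one sequenced parent — the strictest check
   available with the data), **private** against the first-pass control set
   (no alternate allele at all) → protein-changing → no hom_alt carrier in
   the wider global cohort.  Heterozygous carriers in the global cohort are
   expected for a segregating recessive allele and are counted, not
   disqualifying; a homozygous healthy animal is disqualifying.
3. **De novo dominant**: het in the case and the alternate allele
   certifiably absent from the sequenced parents and from every control and
   global sample.

Two cohort roles exist because real designs use a smaller deeply-genotyped
comparison cohort to define "private" and a much larger catalogue only for
carrier lookup.  The simulator models these as nested subsets of one control
cohort (first 35 of 50 controls by default); planted carrier heterozygotes
live outside the first-pass subset.

"Protein-changing" is the set {missense, stop gained, stop lost, start lost,
frameshift, in-frame indel, splice-site placeholder}; synonymous and
non-coding calls never survive.  Missing genotypes are conservative in both
directions: a missing case genotype cannot satisfy "homozygous in the case",
and a missing control genotype cannot certify absence (`missing_excludes`,
on by default).  A manual read-pileup review of artefact sites is replaced
by a programmatic callability requirement: ≥ 90 % non-missing genotypes
across the cohort at the site.

## Consequence annotation

Gene models are single-transcript: ordered CDS segments (1-based inclusive,
ascending genomic order) plus the strand-corrected coding sequence.  Genomic
↔ CDS mapping is a strand-aware cumulative walk over the segments and is a
bijection over coding positions.  For an SNV at coding position *c* the
affected codon is ⌈c/3⌉; the reference and alternate codons are translated
with the standard genetic code and classified (synonymous, missense, stop
gained/lost, start lost).  For a VCF-anchored indel the edit is first
re-expressed in CDS space (reverse-complemented for minus-strand genes);
a net length change that is not a multiple of 3 is a frameshift whose first
affected codon is ⌈(p+1)/3⌉ for an edit anchored after CDS position *p* —
the codon where the reading frame changes.  When an inserted base
coincidentally equals its right neighbour the first *sequence-visible*
change can fall later; the reported codon deliberately marks the frame
change, and the property suite verifies both the unchanged prefix and the
changed triplet under a no-coincidence condition.  Labels are HGVS-like
(`c.58G>T`, `p.Gly20Trp`, `c.10773dupC`, `p.Ser3592fs`); full HGVS
3'-normalisation is out of scope.  Deleteriousness predictions and pLI
scores are pass-through annotation columns, never computed.

## Association, relatedness and ROH

The case/control test is a two-sided **Fisher exact test** on the per-site
2×2 allele-count table (missing genotypes dropped per site).  At a dozen
cases the allele counts are far too small for the asymptotic allelic
chi-square, so exactness matters; the implementation vectorises the
hypergeometric enumeration over sites (support per site is at most
2·n_cases + 1) and matches an independent integer-combinatorics enumeration
to ~1e-9 relative error.  Genome-wide control is the Bonferroni bound
α / n_tests with α = 0.05 over the informative sites actually tested; no
genomic-control or stratification correction is applied.

Controls are pruned for relatedness before testing with a method-of-moments
IBD estimator (PI-HAT analog): per-site allele frequencies (estimated from
the whole cohort) give the expected IBS distribution under IBD states 0/1/2;
solving the moment equations per pair yields P(IBD=1), P(IBD=2) and
PI-HAT = P(IBD=2) + P(IBD=1)/2, clamped to [0,1].  Pruning is greedy —
repeatedly remove the sample in the most pairs ≥ 0.5, ties broken by sample
id — so the retained set is deterministic.

ROH detection is a consecutive-runs scanner: a run starts and ends on a
homozygous site, tolerates at most `max_het` heterozygous sites (default 1),
skips missing sites without counting them, and breaks on inter-site gaps
above `max_gap_kb` (default 250).  Runs must span ≥ `min_kb` (500) with
≥ `min_snps` (20) informative sites.  These are conventional
consecutive-run parameters of the kind detectRUNS-style scanners use; no
values are dictated by the study design itself.  Shared homozygosity across
cases is a breakpoint sweep over the per-case ROH unions, reporting maximal
constant-count intervals with count ≥ `min_cases`.

## Depth-of-coverage karyotyping

Window counts (10 kb and 200 kb tiling windows, bedcov dialect) are
normalized to the **median of per-chromosome median counts** over autosomal
full-width windows.  On a large genome this coincides with the genome-wide
average a coverage plot draws as its reference line; on the 3-chromosome
synthetic build it is the robust choice, because a whole-chromosome trisomy
would otherwise inflate the sample's own reference by ~17 % and bias every
ratio.  The corresponding limitation: if events covered half the genome the
median would break down too — acceptable for a karyotyping screen where
events are sparse.

Segment calling runs on the coarse windows: runs of ≥ 3 consecutive windows
below 0.7 (loss) or above 1.3 (gain).  The thresholds sit at the midpoints
between the copy-number ratio expectations (0.5, 1.0, 1.5) less a noise
margin; with the default noise level (~10 % per-window CV) a diploid window
crosses a threshold with probability ~1e-3, so a false run of three is
~1e-9 per position.  A chromosome whose *median* ratio is ≥ 1.35 (or
≤ 0.65) is escalated to a whole-chromosome trisomy (monosomy) call and
excluded from segment scanning, since per-window runs across a whole noisy
chromosome are fragile exactly when the chromosome-level signal is obvious.

Breakpoints of accepted segments are refined on the 10 kb profile with a
least-squares two-mean step fit over ±40 fine windows around each coarse
boundary (skipped and flagged when fewer than 5 fine windows flank the
boundary; a fit preferring no step keeps the original boundary).  Interval
sizes are reported as (end − start)/1e6 rounded half-up to 2 decimals — the
convention under which printed breakpoint pairs reproduce published Mb
figures; the 1 bp difference versus end − start + 1 is sub-rounding.
Read-level evidence (split reads, discordant pairs) is out of scope, so
copy-neutral inversions and translocations are not *detected* — their
printed breakpoints can still be fed to the interval arithmetic.

## Pedigree analysis

Pedigrees are sire/dam DAGs with optional genotype labels.  Wright's
inbreeding coefficient is computed by explicit path counting over
ancestor-disjoint path pairs with recursive, memoized ancestor F values;
unknown parents are unique non-inbred founders.  At case-series pedigree
sizes (tens of animals) path enumeration is trivially cheap, and the tabular
additive-relationship method is kept in the package as the independent
cross-check (they agree to 1e-12 on random pedigrees up to 50 animals).
An inbreeding loop is flagged when the parents share a common ancestor
within 3 generations, matching the depth of routinely available pedigrees;
carrier tracing, which follows known carriers toward a founder, uses
unlimited depth by default because founder animals typically sit many
generations up.  Carrier tracing intersects the ancestor closures of all
labeled carriers *of one allele* and keeps the most recent candidates; a
carrier whose every descent path to every candidate passes through a
confirmed hom_ref animal is flagged genotype-inconsistent.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, and records every planted event in a truth set:

* **Genome**: 3 chromosomes × 10 Mb.  Real genome scale is deliberately not
  emulated; every algorithm is scale-free in the quantities that matter
  (per-window ratios, per-site counts).
* **Background variants**: 20,000 sites, positions uniform, MAF ~ U(0.1,
  0.5), genotypes Hardy-Weinberg in founders; case genotypes arise by
  Mendelian transmission from (possibly unsequenced) parents.  Inside a
  gene's CDS the reference allele is taken from the gene model, as it would
  be from a reference genome.  No linkage disequilibrium, recombination
  maps, or genotyping error beyond an optional uniform missing rate.
* **Families**: one trio, one duo, one solo (the three sequencing designs of
  a field case series).
* **Planted small variants**: a recessive missense in the trio (12 control
  het carriers), a recessive missense in the solo (7 carriers), a de novo
  single-base duplication in the duo (0 carriers); carrier counts mirror a
  segregating-allele pattern, carriers placed outside the first-pass subset.
* **Planted chromosomal events**: heterozygous deletions of 2.94 Mb and
  2.01 Mb on chr2 (trio and duo cases) with breakpoints off window
  boundaries so refinement is actually exercised, and a chr3 trisomy (solo
  case — the same case that carries a recessive allele, the hardest
  attribution scenario).
* **Depth model**: negative binomial with mean
  `coverage × window / read_len × (copy_number/2)` (20×, 150 bp reads) and
  overdispersion φ = 0.01 (variance μ + φμ², ~10 % CV per window; φ = 0
  gives Poisson).  Poisson alone would make CNV calling unrealistically
  easy.
* **Pedigrees**: the trio's parents both descend from one carrier founder
  through a shared ancestor (founder also reachable through a labeled
  carrier side line); the solo's parents form an inbreeding loop through a
  labeled carrier sire; the duo's parents are unrelated.  Founders are
  recorded in the truth set.

Because the generator draws exactly these conditions, a green end-to-end
suite demonstrates that the pipeline recovers the planted event classes at
these effect sizes and sample sizes with zero false candidates — it does not
demonstrate robustness to alignment artefacts, LD structure, population
stratification or reference errors, none of which are simulated.

## Descriptive case statistics

`summarize_case_table` reports per-breed mean, SD, min, max and n for body
weight and gestation age, excluding missing values, with the **population
SD** (divisor n).  The bundled 14-case table yields, for the Holstein group:
BW mean 30.6 kg, SD 3.3 (n = 9); GA mean 281 days (printed as whole days),
SD 8.4 (n = 12).

## Problem sizes and determinism

Defaults (20,000 sites, ~58 samples, 150 coarse + 3,000 fine windows per
sample) run the full pipeline in under a second; the multi-seed suites (20
end-to-end seeds, 100-seed null-calibration and refinement checks) complete
in well under a minute together.  Every stochastic component takes a
`numpy.random.Generator` seeded from the run seed; identical seeds give
byte-identical VCFs, depth tables and manifests.  The synthetic gene set is
fixed reference data, independent of the run seed.
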