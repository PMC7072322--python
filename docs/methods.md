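# Methods

This note documents the statistical models, numerical conventions, and
design choices behind `earlygc`, and what the synthetic-data experiments
do and do not demonstrate.

## Somatic filtering

Both rulesets treat the read counts supplied on each record as
authoritative; upstream mapping, duplicate removal, and base-quality
masking are out of scope. All thresholds are inclusive ("at least 30"
keeps a depth of exactly 30); the strand-balance criterion excludes a
record when the *minimum* of the forward- and reverse-strand fractions of
mutant reads is strictly below 0.2. "All reads" in the allele-fraction
criterion is interpreted as the record's tumor depth. A record with zero
mutant reads fails the support criterion directly and the (undefined)
strand fraction is never evaluated. Rejected records carry every violated
criterion, not just the first: this makes filter accounting testable
(|kept| + |rejected| = |input| and each rejection lists ≥ 1 code) and
rejection reasons auditable in the sidecar TSV and VCF FILTER column.
Thresholds live in frozen dataclasses whose defaults are the study values;
passing a modified set logs a "non-paper settings" warning with the diff.

## Annotation

Internal coordinates are 0-based half-open; VCF and GFF3 I/O convert at
the boundary (a correctness test writes a record at VCF position p and
checks it annotates the same reference base as the internal
representation). Effects use the standard nuclear codon table with stop
(`*`) as an ordinary symbol, so stop gains and losses are nonsynonymous.
Indels overlapping any CDS base are `coding_indel`; frameshift vs in-frame
is not distinguished because every downstream consumer needs only
"protein-altering" (nonsynonymous SNV or coding indel). A variant
overlapping several genes is recorded against all of them for the cohort
matrix but counted once — against the lexicographically smallest gene id —
for burden tests; the simulator never emits overlapping genes, so this
path only matters for user-supplied annotations. CpG status is defined on
the genome: a site is CpG iff it is the C or the G of a CpG dinucleotide
on either strand. Trinucleotide contexts are pyrimidine-centred
(`T[C>T]G`); a purine reference base reverse-complements the triplet and
both alleles. At a chromosome edge the 96-class context is undefined and
the variant contributes only to the 6-class table.

## Background rates and the per-gene test

Background point-mutation rates are estimated from non-coding mutations
only — the coding fraction of the genome is the quantity under test, and
synonymous sites are deliberately not pooled in. Rates are split CpG /
non-CpG because spontaneous deamination of methylated cytosine makes CpG
sites roughly an order of magnitude more mutable; an indel rate per
non-coding bp is estimated alongside. Estimation runs in 1-Mb bins
(`mutations / (eligible non-coding sites × samples)`); bins with fewer
than 50 non-coding mutations (configurable) fall back to the pooled
genome-wide rates, and a gene overlapping several bins uses the
length-weighted average of its bins' rates. A category with zero eligible
sites yields rate 0 with a logged warning rather than a division error.

Per-gene mutational opportunity uses fractional site counting: each coding
position contributes 1/3 site per possible substitution, classified
synonymous/nonsynonymous by codon effect and assigned the position's CpG
category. Counts are kept as integer thirds, so the conservation identity
synonymous + nonsynonymous = coding length holds *exactly*, not to
floating-point tolerance.

The expected protein-altering count is
`E_g = n · (μ_CpG S_CpG,g + μ_nonCpG S_nonCpG,g + μ_indel L_g)`.
For the significance test, heterogeneous categories are converted to
*effective trials*: site counts are scaled by (category rate / non-CpG
point rate) — the non-CpG rate is the reference category — rounded to the
nearest integer after multiplying by the sample count, so a CpG site
counts as ~10 trials when its rate is 10-fold elevated. Each gene is then
tested one-sided (enrichment) by Fisher's exact test on
`[[obs_g, opp_g − obs_g], [obs_rest, opp_rest − obs_rest]]` against all
other genes pooled, and p-values are Benjamini–Hochberg adjusted
(significance at q < 0.05). This exact-test construction is this
package's own reduction of "the probability of the observed
protein-altering count given gene length and background rate" to a
standard conditional test; it is the only formulation implemented — one
thoroughly validated code path was preferred over alternatives behind a
switch. Its operating characteristics are established empirically by the
null-calibration and power experiments below. When the reference (non-CpG)
rate is zero the weights degenerate to pure length; observed counts
exceeding the constructed opportunity indicate a construction bug and
raise. With no non-coding mutations at all the procedure refuses to run
(the background is unidentifiable) rather than reporting rates of zero.

Non-goals: covariate-aware backgrounds (expression, replication timing),
copy-number-aware burden, and signature stratification beyond CpG.

## MSI

Classification consumes per-marker instability flags for the Bethesda
panel (BAT25, BAT26, D2S123, D5S346, D17S250); electropherogram comparison
is upstream of this package. MSI-H requires strictly more than 30% of
markers unstable; any instability at or below 30% is MSI-L; no instability
is MSS. With five markers exactly 30% is unreachable, but the
generic-panel variant fixes the convention (3/10 → MSI-L) because MSI-H
demands *more than* 30%.

## Cohort statistics

Per-gene frequencies are reported in percent, rounded half-up to one
decimal (14/49 → 28.6, never banker's rounding). Recurrence selection
requires mutation in at least 4 patients and a cohort-aggregate burden
strictly above 10 mutations per Mb of the gene's coding footprint; the
aggregate (rather than per-sample) denominator is this package's reading
of a gene-level burden filter, and both numerator and denominator are
available in the outputs for transparency. Association tests default to
two-sided (associations are reported, not directionally pre-registered);
the mutual-exclusivity helper also exposes the one-sided "less"
alternative. Cohort-vs-cohort frequency comparisons are a 2×2 Fisher test
on (mutated, unmutated) × (cohort₁, cohort₂) with user-supplied counts —
no external cohort data is bundled.

Fisher's exact test and BH adjustment are delegated to SciPy and
statsmodels, but both are continuously validated against independent
references implemented from first principles: exhaustive enumeration of
the hypergeometric support in exact integer arithmetic (the two-sided p
sums all tables no more probable than the observed one), and the literal
step-up formula `q_(i) = min_{j≥i} m·p_(j)/j`.

## The synthetic cohort generator

The generator emulates a small tumor/normal exome cohort at the level of
*candidate variant calls*, not reads. Per sample, true somatic SNVs are
Poisson per site category and uniform within it; CpG mutations are
deamination-biased (C>T / G>A with probability 0.8); indels (length 1–3,
insertion/deletion with equal probability) are Poisson per bp. Driver
genes receive additional nonsynonymous events at `(multiplier − 1)` times
the per-substitution background rate summed over their CDS, sampled
per-substitution, so the gene's total nonsynonymous rate is exactly
`multiplier ×` background. At most one record is emitted per (sample,
chromosome, position); multi-allelic sites never occur.

Read evidence for true events is drawn stochastically — depth ~
Poisson(depth_mean), alt reads ~ Binomial(depth, VAF), strand split ~
Binomial(alt, ½), normal contamination ~ Binomial — and then clipped
deterministically to the minimal values satisfying the exome criteria.
True events therefore pass the filter *by construction* and filter
sensitivity on truth is 1 by design; what the fidelity experiments
actually probe is specificity and label accounting, via artifact records
that each violate exactly one named criterion (low tumor depth,
normal-sample support, strand bias, known-variant flag). Germline/known
variants are represented only by the known-variant flag — population
databases are consumed as a membership fact, not simulated.

The toy genome draws a CpG-free background sequence and then plants CG
dinucleotides at distinct even offsets, so the realized CpG density equals
the requested value exactly (CpG positions consequently sit at even/odd
offsets — irrelevant to every consumer, which sees only the mask). Genes
are non-overlapping, optionally two-exon, with no constraint that the CDS
be an open reading frame.

Default parameters (a `SimConfig` is the study conditions):

| parameter | default | meaning |
| --- | --- | --- |
| `n_samples` | 19 | tumor/normal pairs (a screening-cohort size) |
| `chromosome_length` | 1 Mb ×2 | toy genome size |
| `cpg_density` | 0.02 | CpG dinucleotide fraction (CpG-suppressed genome) |
| `rate_noncpg` | 5.5×10⁻⁶ | point mutations / non-CpG site / sample |
| `rate_cpg` | 5.5×10⁻⁵ | point mutations / CpG site / sample (10× excess) |
| `rate_indel` | 5.5×10⁻⁷ | indels / bp / sample |
| `depth_mean` | 105 | mean read depth of tumor and normal |
| `vaf_mean` | 0.30 | mean variant allele fraction |
| `artifact_rates` | 10⁻⁶ each | filter-failing records / bp / sample / type |

The point rates imply a per-sample burden of ≈ 8 mutations/Mb — inside
the range such cohorts display (per-sample burdens spanning roughly
0.7–19/Mb), and chosen, together with the 10× CpG excess, by an a-priori
power analysis so that the package's fixed validation designs (a 50×
driver on a 1-kb gene across 30 samples; 200-gene null panels) operate
away from degenerate regimes. True per-category rates are not published
for any real cohort of this kind; these defaults are a modelling choice,
stated once and not tuned.

What the generator does **not** model: read-level errors and mapping
artifacts, subclonal VAF structure and clonal evolution, sequence-context
mutation signatures beyond the CpG dichotomy, germline population
structure, and real exome capture geometry (coding fraction here is a few
percent of a toy genome). Passing the simulation-backed tests therefore
demonstrates internal statistical correctness of the estimators and tests
under the stated model — not robustness to the artifact spectrum of real
sequencing data.

## Validation experiments and problem sizes

* **Filter fidelity** — one 10-sample, 2×1-Mb cohort: 100% of truth
  events kept, 100% of artifacts rejected under exactly their label.
* **Rate recovery** — 100 replicate 10-sample, 1-Mb cohorts sharing one
  genome: aggregate category counts within 3σ Poisson envelopes of the
  generator's rates. With three categories an occasional excursion just
  past 3σ is expected behaviour for a fresh seed (~1% of runs) and is
  reported as the measured |z|.
* **False-discovery control** — 200 replicate cohorts (200 genes of
  999 bp, 20 samples, no drivers) on one genome: ≥ 95% of replicates with
  zero genes at q < 0.05.
* **Power** — 100 replicate cohorts (200 genes, 30 samples, one 999-bp
  gene at 50× nonsynonymous rate): the driver attains the smallest q with
  q < 0.05 in ≥ 90% of replicates.
* **Oracle equivalence** — 1000 random tables with margins ≤ 200 for the
  Fisher p (all alternatives) against exact enumeration; 200 random
  vectors for BH against the step-up formula.
* **MSI** — all 2⁵ flag combinations against an enumerated oracle.

Replicate experiments reuse a single simulated genome (and its cached
per-gene site counts) and redraw cohorts, which conditions on one genome
exactly as the estimator does in practice and keeps the suite fast; all
replicate seeds derive from one parent seed via `numpy` seed sequences.
These sizes run the full suite in about two minutes on one CPU.

## Numerical conventions

* Site-count conservation is exact by integer-thirds bookkeeping.
* Effective opportunities are rounded half-to-even by `round()` once,
  after multiplying by the sample count.
* SMG results are sorted by (q, p, gene id); BH ties keep equal q.
* Frequencies round half-up via decimal arithmetic, never binary floats.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical configurations give byte-identical
  FASTA/VCF/TSV outputs (tested).
* VCF floats are single precision on disk; readers canonicalize to six
  significant digits so write→read round trips are lossless for the
  contract fields (DP, AD, ADF, ADR, KNOWN, VS, CQ, BC, MBQ). Strand
  counts of *reference*-supporting reads are not modelled and are written
  as an even split; alt-strand counts are the simulated ones.
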