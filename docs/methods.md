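# Methods

This note documents the models, rules and numerical choices behind
`pharmsv`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Scope and data model

The package operates on *cohort-level* SV summaries: each record is one
variant call with an interval, a type (DEL, DUP, INS, INV, CPX, MCNV;
unresolved breakpoint junctions and reciprocal translocations are carried
as BND/CTX only to be excluded), a filter status, a global allele
frequency, optional per-population frequencies (AFR, AMR, EAS, EUR, OTH)
and — for MCNVs — a copy-number frequency spectrum. No per-sample
genotypes are modelled; everything per-individual is derived from
frequencies under Hardy–Weinberg assumptions.

All coordinates are 0-based half-open. GTF/GFF input (1-based inclusive)
is converted on read; BED is native. Insertions are stored as 1-bp
intervals at the insertion point, with the reported insert size kept as
`length_bp`, which lets insertions take part in uniform interval overlap
while preserving size statistics.

## Record-level filters

Retained records have filter status within {PASS, MULTIALLELIC}, a
resolved SV type, and length ≥ 50 bp (the defining size threshold for
SVs). Filtering is idempotent and conserves counts: input = retained +
Σ removals-by-reason, with every removal reason-coded.

## MCNV decomposition

An MCNV spectrum maps copy-number states to frequencies. Relative to the
expected state (`expected_cn`, default diploid 2), the frequency mass of
states below the reference is the *deletion-like* component and the mass
above it the *duplication-like* component; the reference state belongs to
neither, so del + dup + ref conserves the spectrum mass. Example:
{0: 0.845, 2: 0.155} → deletion-like 0.845, duplication-like 0. Each
non-zero component is classified and counted separately (so one MCNV
locus can contribute both an LOF deletion and an IGD duplication with
distinct frequencies).

## Clustering

Calls of one SV type on one chromosome merge when the gap between their
intervals is ≤ `max_dist` (default 0), i.e. overlapping *or bookended*
intervals (end₁ = start₂ in half-open coordinates) merge; a 1-bp gap does
not. The result is independent of input order, covers exactly the union
of member intervals, and increasing `max_dist` can only reduce the
cluster count. Clustering runs genome-wide before gene assignment (the
alternative order, restrict-then-cluster, is available by filtering the
table first). The representative cluster frequency is the member maximum
(configurable to sum); the maximum avoids double-counting overlapping
fragments of the same underlying allele at the cost of undercounting
genuinely distinct overlapping alleles.

## Functional classification

Per (SV, gene) pair — SVs spanning several panel genes are annotated once
per gene:

- **coding** iff the SV interval intersects ≥ 1 exon (insertions: the
  insertion point falls inside an exon).
- **LOF**: deletions touching an exon; exonic insertions; inversions with
  ≥ 1 breakpoint strictly inside the gene span that span an exon; partial
  duplications whose duplicated exonic length mod 3 ≠ 0. The frameshift
  test assumes a tandem in-place duplication, with affected coding length
  = Σ overlap with CDS (or exons when no CDS annotation exists).
- **IGD**: duplications containing the entire gene span (span = exon
  union ± a configurable flank, default 0 bp).
- **UNKNOWN**: frame-preserving partial duplications; complex
  rearrangements touching exons; whole-gene inversions with both
  breakpoints outside the span — the transcription unit is preserved, so
  calling these LOF would overstate their impact (a deliberate design
  choice, flagged for sensitivity analysis); UTR-only exon overlap when a
  CDS annotation is supplied.
- **NONE**: non-coding (intronic or up/downstream) SVs.

Rarity uses the reported SV frequency directly with a 1% boundary — a
99.5% deletion counts as common; cohort tables report SV frequencies, not
folded minor-allele frequencies.

Gene span uses the canonical (longest by summed exon length) transcript
by default, configurable to the union over transcripts; per-kb density
normalizes by span length in kb (not flank-extended unless a flank is
configured). Group density comparisons use two-sided Wilcoxon rank-sum
tests with raw p-values at α = 0.05 (a BH option exists but is off by
default, matching the reporting convention of single pairwise contrasts).

## Regulatory inference

Non-coding SVs are intersected with TF ChIP-seq cluster peaks that pass
reproducibility filters: peak score ≥ 200 (on the 0–1000 cluster-score
scale) and observation in ≥ 2 contributing studies. Overlap is
any-overlap (≥ 1 bp; containment is a config option), and per-SV TF lists
are deduplicated. A pair is *putatively functional* when the impacted
gene and the TF are co-expressed — median expression ≥ 1 TPM (the
threshold is configurable; "expressed" is nowhere quantified in public
resources, and 1 TPM is the conventional presence cut-off) — in at least
one tissue of the panel. The default panel is nine tissues of
pharmacokinetic/pharmacodynamic relevance: liver, kidney, small
intestine, stomach, colon, lung, brain, heart, adipose. Direction hints
(deletion → ablation of TF input, duplication → gain, insertion →
disruption, inversion/complex → complex) are qualitative; no quantitative
expression change is predicted.

## Burdens, simulation, carriers

The burden metric is expected diploid allele dosage, Σ over loci of 2·AF,
grouped by population, gene-class group and functional class (LOF/IGD
only by default). A carrier-probability alternative (Σ 1−(1−AF)²) sits
behind `metric="carrier"`; whether published per-individual figures are
dosage or carrier sums is ambiguous, and dosage reproduces their scale
(e.g. a single 84.5% deletion contributes 1.69 alleles per individual).
MCNVs contribute through their decomposed component frequencies; records
lacking a population frequency are excluded from that population's burden
with a logged count.

Cohort simulation draws two alleles per locus per individual
(binomial(2, AF), loci independent — no linkage information is available
at cohort-summary level), giving carrier fractions that converge to
1−(1−p)² and homozygote fractions to p². Carrier frequencies are reported
as "1 in N" with N = round(1/fraction), and fractions ≥ 0.75 as "1 per
individual". Seeds are mandatory; library default 1.

Numerical note: at AF 0.054 the exact HWE reciprocal is 1/0.10508 = 9.52,
essentially on the 9/10 rounding boundary, so a single 100,000-individual
cohort flips between "1 in 9" and "1 in 10" from Monte-Carlo noise alone.
Where a stable reported value is needed (`scripts/acceptance.py`), the
carrier fraction is averaged over 400 replicate cohorts of 100,000 before
taking the reciprocal — pure variance reduction at unchanged model,
frequency and cohort size.

## eQTL cross-reference

Each external SV-eQTL is matched to the nearest same-chromosome cohort SV
(nearest = smallest maximum breakpoint distance). Two criteria are
computed and reported separately because they measure different things:
*near* (both breakpoint offsets ≤ 100 bp) and *included* (reciprocal
overlap > 0.99 — the intersection must exceed 99% of **both** intervals;
one-sided overlap would admit a tiny SV nested in a large eQTL interval).
Insertion eQTLs match by point distance with overlap defined as 1 when
near. The report aggregates included matches per (gene, SV type) with
coding status, affected TFBSs for non-coding entries, tissue lists and
beta/significance ranges. eQTL associations are consumed from published
tables, never estimated.

## Attribution

`func_ncSV = n_ncSV / (n_ncSV + n_SNV + n_cSV)` over per-individual
counts: non-coding functional SVs (regulatory hits), coding functional
SVs (LOF + IGD, ADME + targets), and functional SNVs. SNV counts are
configuration inputs (defaults 40.6 for ADME genes, 26.0 for drug
targets, taken from the literature), never computed — the package has no
SNV pipeline. The fraction is scale-invariant and strictly increasing in
the non-coding count.

## Synthetic data: what it does and does not emulate

The generator plants every geometry the classifier distinguishes (exonic
vs intronic deletions/insertions, whole-gene vs frame-shifting vs
in-frame partial duplications, internal-breakpoint vs whole-gene
inversions, exonic complex events, mixed MCNV spectra), at most one per
(gene, SV type) so clustering at max_dist 0 never merges planted
variants. Allele frequencies mix a rare-heavy Beta(0.2, 20) with common
point masses (default 5.4%, 15.5%, 25.9%, 84.5%) so both rarity strata
are populated; per-population frequencies jitter the global value
log-normally (σ = 0.25). TFBS decoys straddle the score-200 and
two-study boundaries; the expression design keeps baseline values
strictly below the threshold so planted co-expression recovery is exact.
Unmatched eQTL plants are displaced by max(150 bp, 5% of length), failing
both match criteria. Default sizes (50 genes, ~40 planted + 60 background
SVs) keep the full suite and pipeline in seconds on one CPU.

What passing these tests shows: the bookkeeping, geometry and filter
logic are exact on inputs satisfying the stated definitions. What they do
not show: robustness to real-data messiness — overlapping genes, multiple
discordant transcript models, call-boundary noise around exon edges,
linkage between loci, reference-build mismatches between resources, and
frequency ascertainment biases are all absent from the generator.

## Known limitations

- No star-allele nomenclature, diplotype/phenotype translation, or
  breakpoint-resolution transcript consequence prediction.
- Classification of complex rearrangements is conservative (UNKNOWN).
- Independence of loci in simulation ignores linkage disequilibrium.
- Headline counts from public resources depend on the specific gnomAD /
  ENCODE / GTEx releases and are not reproduced here; the pipeline
  reproduces the *rules* and the in-table arithmetic, not the upstream
  call sets.
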