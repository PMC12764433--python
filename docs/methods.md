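# Methods

This note documents the models and procedures implemented in `neoedit`,
the defaults chosen where the design was open, and what the synthetic
cohort does and does not establish about real data.

## Coordinate conventions and gene models

All genomic coordinates are 0-based, half-open internally; the VCF
boundary converts from 1-based positions. A gene model is a set of
sorted, non-overlapping CDS intervals plus the spliced coding sequence in
reading order (reverse-complemented for minus-strand genes), including
the terminal stop codon. Validation is strict: CDS length must be a
multiple of three, internal stops are hard errors, and the stored protein
must equal the translation. Gene models travel as a CDS FASTA plus a TSV
of intervals rather than GFF3 — the analysis needs only CDS geometry and
identity, and the simulator emits this format natively. Overlapping genes
are allowed; a variant inside two genes yields one consequence record per
gene, and burden counting collapses back to distinct variants using the
most severe consequence.

## Variant processing

VCF ingestion splits multi-allelic rows into per-ALT records and takes
allelic depths from the tumor sample's AD field, falling back to
Strelka2 tier-1 counts (AU/CU/GU/TU for SNVs, TAR/TIR for indels) when AD
is absent. The burden filter keeps PASS records with ≥ 5 alt-supporting
reads ("AD > 4"), is order-preserving and idempotent.

SNV consequences come from codon substitution in reading order; a
first-codon change that alters the residue is start_lost, a stop-codon
change that removes the stop is stop_lost. Indel consequences use the net
coding-length change modulo 3. For frameshifts (and for the oracle used
in tests) the full mutant CDS is rebuilt — substitution, deletion or
insertion applied to the spliced forward strand, re-oriented, and
translated to the first stop. Edits that cross exon boundaries are
rejected as data inconsistencies, as are reference-allele mismatches.

Mutation-burden categories (total, missense, synonymous, truncating,
indels) are reported independently, not as a partition: a frameshift
indel counts in both truncating and indels, matching the four-panel
reporting style used for such cohorts.

## Clonality mixture

Clonal/subclonal classification fits a two-component Gaussian mixture to
untransformed VAFs by EM, implemented directly (the covariance family
and posterior rule of the R package originally used for this step are
unpublished, so the simplest choice is made explicit): deterministic
initialization at the 25th/75th VAF percentiles, equal starting weights,
a variance floor of (1e-4)², convergence at 1e-8 relative log-likelihood
change, 500 iterations maximum. The higher-mean component is labeled
clonal; a variant is clonal when its posterior for that component is
≥ 0.5. Inputs need at least 10 distinct-valued VAFs; degenerate inputs
raise rather than fit. The log-likelihood trace is non-decreasing (up to
the variance floor) and is exposed for inspection. The classification is
an output table only; no downstream statistic depends on it.

## Neoantigen enumeration and scoring

Missense: for each length L ∈ {8, 9, 10}, every L-window of the mutant
protein containing the substituted position, paired with its wildtype
window (an interior site yields 8 + 9 + 10 = 27 pairs). Frameshift: the
mutant protein is rebuilt and translated in the shifted frame to the
first stop; the novel region starts at the first residue diverging from
wildtype, and every 8–10mer containing at least one novel residue is
emitted with no wildtype pair. A frameshift that stops before any novel
residue yields an empty list with a warning.

Scoring goes through a predictor interface `(peptide, allele) → IC50 nM`
so a real MHC-binding tool can be dropped in. The bundled surrogate is a
deterministic anchor-motif model built around the canonical
H-2K<sup>b</sup> ligand SIINFEKL: score s = (a + c)/2 with a = 1 if
position 5 matches the allele anchor (F/Y for H-2K<sup>b</sup>, N for
H-2D<sup>b</sup>) and c = 1 if the C-terminus is L/M/I/V; IC50 =
50000 × 10^(−3s). Only doubly anchored peptides (50 nM) pass the 150 nM
strong threshold, so "strong" is invariant to peptide context outside
the two anchor positions. The anchor position is fixed at 5 for all
lengths — the simplest deterministic motif, not a model of real
length-dependent anchor registers.

Candidate rules: variants must already be PASS/AD-filtered and have
VAF ≥ 0.2 (inclusive, the usual reading of a tumor-DNA VAF minimum);
peptides under 500 nM are candidates; under 150 nM they are strong. The
per-sample burden counts *variants* with at least one strong peptide —
counting peptides would inflate totals roughly 27-fold for missense
sites. Stop-gain/stop-loss/start-loss variants produce no peptides in
this version. Restricting candidates to commonly expressed genes
(fragments-per-million > 0 in all reference lines) is available but off
by default, since common expression is computed as a descriptive label
rather than a documented gate on neoantigen calls.

## Copy number

States are called per segment by strict thresholds: gain when
log2 > 0.6, loss when log2 < −0.6. Genome fractions divide gained/lost
length by the total called length of the profile. Minimum-consistency
segmentation takes, per chromosome, the union of all samples'
breakpoints and splits every segment at the interior cut points, each
sub-segment inheriting its parent's log2 and state — total covered
length, and hence the gain/loss fractions, are preserved exactly, and
the operation is idempotent. Region-level gain frequency uses any-overlap
(≥ 1 bp of a gain-state segment) — the simplest deterministic rule given
that no coverage fraction is published for the Myc-region analysis — and
percentages are rounded half-up to integers for report parity.
Segmentation itself (CBS) is out of scope; the module consumes
CNVkit-style segment files.

## Cohort statistics

Mann-Whitney U is exact (full enumeration, via `scipy`) when
n₁ + n₂ ≤ 20 and the pooled values are tie-free, otherwise the normal
approximation with tie and continuity corrections; identical groups
short-circuit to p = 1. For 2×2 tables the odds ratio is the
cross-product ratio with a Woolf log-interval CI (Haldane–Anscombe +0.5
on zero cells, flagged); the chi-square is Pearson without continuity
correction, and the one-tailed p is half the two-tailed p when the
observed effect lies in the pre-stated direction (regressor enrichment
in knockout strains), else its complement — this construction reproduces
the published P = 0.04 from the published counts. Fisher's exact uses
the two-sided point-probability convention. Published CIs for these
tables are not exactly reproduced by the Woolf interval (the original
interval method is unstated), so CIs are reported but not relied upon.

Growth classification fits ln(volume) against time by least squares over
positive volumes (≥ 3 required, else "unknown"); slopes within 1e-12 of
zero are snapped to zero, and r ≤ 0 classifies a line as regressor — a
deterministic boundary for the unpublished heatmap rule. Caliper volume
is 0.5 · l · w² in mm³, with swapped diameters corrected under a warning.

Across the nine gene-set contrasts the pipeline reports raw p-values
(the comparison default, matching how such panels are published) with
Holm-adjusted values alongside.

## Power model

The per-mouse probability of an FABP-exon hit is the linear form
p = burden × 334,760 / 2.7×10⁹ — the expected FABP-exon mutation count
used as a probability, exactly as the design calculation is printed —
and arm-level power is 1 − (1 − p)^N. The linear form errs high: against
the exact thinning model 1 − (1 − 334,760/2.7×10⁹)^burden the gap
reaches ≈ 0.16 in absolute power at N = 1 over burdens 3,500–5,000,
but falls below 0.08 at the arm sizes the design actually recommends
(N ≥ 4), where both models agree that 4–6 mice give ≥ 95% power. The
exact model is available behind a flag. The linear form exceeds 1 for
burdens above ~8,066 and raises there.

## Synthetic cohort

The generator emulates the study conditions: 18 WT, 14 DNGR-1KO and 11
RAG1KO samples; 350–500 mutations per tumor by default — a 1/10 scale of
the 3,500–5,000 reported for MCA fibrosarcomas, over a 600-gene coding
space (≈1.5 kb mean CDS, 1–3 exons, random strands across 19
chromosomes), keeping a full cohort simulation-plus-analysis run around
two to three minutes on one core; a `--paper-scale` flag restores the
full burden. Gene sets of 88 (FABP) and 98 (MBP) genes are sampled
disjointly.

Mutations are placed uniformly over concatenated CDS space (90% SNVs,
10% short indels of 1–3 bp), consequences derived by the same classifier
the pipeline uses, and each variant is pre-scored with the surrogate
predictor. Immunoediting then removes each strong-FABP-neoantigen
variant before observation with genotype-dependent probability — WT 0.8,
DNGR-1KO 0.15, RAG1KO 0.0 by default. These are calibration knobs
encoding the direction and ordering of the effect (no quantitative
effect size is published), chosen once to give a clearly detectable
depletion at desk scale. Coupling the editing rule to the same predictor
interface the pipeline applies makes recovery tests closed-loop: ground
truth is defined under the predictor actually used.

VAFs are drawn independently of editing status (no VAF-editing
interaction is modeled): clonal variants (70%) from Beta(20, 20),
subclonal from Beta(2, 8); depth is Poisson(120) and alt reads
Binomial(depth, VAF). Five percent of observed variants are non-PASS
decoys. Transplantation phenotype is assigned by a logistic in the
observed strong-neoantigen total, centered on the cohort median with
scale 0.15 per count — samples retaining more strong neoantigens are
more likely to regress — which induces the qualitative genotype-level
regression ordering without hard-coding it. Myc-region gains are
inserted with probability 0.59 (progressors) / 0.19 (regressors) as an
explicit chr15 segment; other segments are chromosome-scale with mostly
neutral log2 ratios and occasional arm-level events. Growth curves are
exponential with phenotype-signed rates (≈ ±0.2/day) and 5% lognormal
volume noise, serialized as caliper length/width pairs.

Everything derives from `numpy` generators seeded by (config.seed,
stream offset), so outputs are byte-identical across runs of the same
config.

What the synthetic cohort does *not* emulate: mutational signature
spectra and sequence context, subclonal phylogenies, germline variation,
purity/ploidy effects on log2 ratios, expression-linked escape, and real
MHC binding (the surrogate's motif is far simpler than a trained
predictor). Passing tests therefore demonstrate that the pipeline's
operations are correct and that the detection procedure recovers an
editing signal of the encoded form and magnitude — not that the
published biological effect size is reproduced from raw data, which
would require the deposited sequencing data and external predictors.

## Numerical and degenerate-input choices

- Mixture EM: variance floor (1e-4)², tolerance 1e-8, ≤ 500 iterations;
  < 10 VAFs or zero spread raise.
- Mann-Whitney: exact only when tie-free and n₁+n₂ ≤ 20; degenerate
  all-equal input returns p = 1 with U = n₁n₂/2.
- 2×2 tables: zero cells use +0.5 on all cells for OR/CI only (flagged);
  chi-square on degenerate margins is NaN rather than fabricated.
- Non-finite log2 ratios drop the segment with a warning.
- Percent formatting rounds half-up; burden thresholds are inclusive
  (≥ 5 reads, VAF ≥ 0.2); state thresholds strict (> 0.6, < −0.6).
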