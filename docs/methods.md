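# Methods

## Scope and data flow

`tandemdiv` analyses a gene family in a focal genome against a single
outgroup. Inputs are standard files: gene models with exon structure
(GFF3), CDS and protein sequences (FASTA), a gene tree over both species'
family members (Newick) with a two-column gene → {focal, outgroup} sidecar
TSV, an RPKM expression matrix (genes × stages, TSV), a motif-architecture
table (gene, motif id, protein offset; TSV) and optionally qPCR Ct tables.
Family identification, alignment, tree inference, motif discovery and
synteny typing are upstream of the package: their outputs are inputs here.
Coordinates are 1-based and inclusive throughout (GFF3 convention);
unanchored scaffolds are treated exactly like chromosomes; strand is never
used in tandem calls.

## Tandem detection

Two family genes form a tandem pair when they are on one chromosome, at
most `max_pair_distance_bp` apart (default 100 000) and separated by at
most `max_intervening` (default 10) non-family genes whose spans lie
strictly between them. Distance is the inner gap between gene spans,
`max(0, downstream.start − upstream.end)` — zero for overlapping genes —
because an anchor-to-anchor rule penalises long genes; start-to-start
distance is available via `distance_mode="start"`. The pair rule is
evaluated between **all** family pairs and qualifying pairs are merged by
single-linkage (union–find) into maximal repeats, which reproduces
multi-gene arrays whose consecutive members each qualify. Output order is
(chromosome, span start), independent of input order. The detector is
validated against an independent quadratic brute-force implementation on
random layouts of up to 200 genes.

## Duplicate classification

The gene tree is used as a topology only; support values are carried but
not filtered on, since the source analysis applies no support cutoff. A
basal polytomy is taken to mean the tree is unrooted and triggers midpoint
rooting with a logged warning (focal-only clade detection depends on the
root; missing branch lengths default to 1). Type I genes are members of
maximal focal-only clades with ≥ 2 focal tips; maximality means the parent
clade contains an outgroup tip. A polytomy mixing species is not a cluster,
though its purely focal children may be.

Tandem classes follow the partner-based rule described in the README. One
deliberate asymmetry: type II membership in a repeat suffices for an
ancestral call even when the gene's outgroup orthologs are not tandem,
because outgroup rearrangement (e.g. post-polyploid rediploidisation)
destroys ancestral arrays without changing the duplication's age. Ortholog
tandem arrangement — computed from the outgroup tips of the smallest
enclosing clade that has any, under the same pair rule on the outgroup
GFF3 — is therefore attached as evidence, never used as a filter. The
summary reports both gene-level tallies (lineage-specific / ancestral /
both, with inclusion–exclusion) and repeat-level counts, because the two
conventions give different totals and the report deliberately does not
reconcile them.

## Sequence divergence

Codon alignments come from threading each CDS (terminal stop stripped,
internal stops rejected) onto its aligned protein row; each residue maps to
one codon, gaps to `---`, and any translation mismatch is reported with
gene and position. Pi is the proportion of differing nucleotides over
sites where neither row is gapped.

Ka/Ks uses Nei–Gojobori (1986) counting with equal pathway weights, not a
maximum-likelihood model: the downstream comparison uses Ka/Ks only
ordinally (lineage-specific vs ancestral pairs), and the counting method is
fully specifiable and verifiable against exhaustive pathway enumeration.
Conventions: single-nucleotide changes creating a stop codon count as
nonsynonymous in the site tally (so s + n = 3 per codon exactly); pathways
through stops are excluded and the remaining ones reweighted (a codon pair
whose every pathway passes a stop is skipped and logged); site counts are
averaged over the two sequences; codon columns containing a gap or
ambiguity are deleted pairwise, not globally; the Jukes–Cantor correction
−¾ ln(1 − 4p/3) returns NA at p ≥ ¾, and Ka/Ks is NA when Ks is 0 or
undefined. The standard genetic code is the default and the table is
injectable. An adapter point exists for plugging in external (e.g. ML)
result tables as cross-checks; Biopython's independent NG86 implementation
is used this way in the test suite.

## Structural divergence

Intron count is `len(exons) − 1`; a pair is structure-divergent when the
absolute intron-count difference is positive. Motif-architecture difference
is the symmetric difference of motif-id multisets — copy-number changes
count, pure re-ordering scores 0, which matches how arrangement differences
are tallied in practice (no order-only difference is observed in the data
this mirrors); a Levenshtein edit distance over the ordered motif sequence
is available for callers who want order to count.

## Expression divergence

"RPKM lower than 0.3 means not expressed" is read as a strict inequality
for non-expression, so detection is ≥ 0.3 and boundary values are detected.
Expressed = detected in ≥ `min_expressed_stages` (2). Low expression =
RPKM < 1 in at least ⌈⅔ × n_stages⌉ stages (9 of 13; ceiling because the
rule says "at least two thirds"). Pair correlation is Pearson (Spearman
via config) over stages where both genes are detected; fewer than
`min_shared_stages` (3; the threshold is a package choice, the rule's
source is silent) co-detected stages, or a constant profile, gives r = NA
and the pair is not "correlated". Group comparisons are two-sided Welch
t-tests; a fully degenerate comparison (both groups constant, equal means)
returns p = 1 with a warning. ΔΔCt: ΔCt = Ct_target − Ct_reference per
replicate, ΔΔCt = mean ΔCt(condition, timepoint) − mean ΔCt(control,
pooled over its timepoints), fold = 2^(−ΔΔCt), significance from Welch
tests on replicate ΔCt. Heatmap export uses log2(RPKM + 1); the +1 offset
avoids −∞ at zero. Summaries print percentages at one decimal and retain
exact fractions in JSON, because rounded percentages (e.g. a fold ratio of
two rounded percentages) are otherwise irreproducible.

## Synthetic data generator

The simulator plays the two-species history forward so every downstream
module has exact ground truth. Each of `n_ancestral_genes` (default 20)
loci independently duplicates in tandem before the split with probability
0.3 (array inherited by both species), and each surviving focal copy
duplicates in tandem after the split with probability 0.3 or disperses to
another chromosome with probability 0.1; each descendant copy is lost with
`gene_loss_rate` (default 0 — the clean-recovery regime). Tandem
duplicates are inserted immediately downstream with a gap uniform in
[200, 20 000] bp and 0–3 filler genes, so the pair rule holds at default
thresholds; distinct loci are separated by 150–300 kb of filler-populated
spacer (filler density 0.25 per 10 kb) so arrays can never merge. Genes
get 1–3 introns with probability 0.25.

Codon sequences (300 codons per gene by default; 500 in estimator-recovery
runs) evolve by uniform single-nucleotide proposals: synonymous proposals
always accepted, nonsynonymous accepted with probability ω, stop-creating
proposals rejected, with Poisson(3 × codons × Ks_target) proposals per
branch so the expected accepted synonymous events per synonymous site —
the NG86 + JC estimand — equal the branch's Ks target. Pair Ks targets are
split evenly over the two branches. Defaults: Ks 0.1 / ω 0.25 for
lineage-specific pairs, and Ks 0.4 (duplication) + 0.8 (speciation) / ω
0.15 for ancestral pairs — recent duplicates conserved, ancestral pairs
deeply diverged, both under purifying selection. Expression profiles span
13 stages (mirroring a 13-stage reproductive series): per-gene log2-normal
with stage s.d. 0.6, duplicate partners generated by mixing the anchor's
log2 deviations with equal-variance noise at weight r (0.5 for both pair
classes by default), and lineage-specific pairs drawn at low abundance
(mean log2 RPKM in [−2, 0.5]) to emulate the observed low expression of
recent duplicates. Motif architectures perturb a per-locus base
architecture, more for ancestral copies (0–3 changes) than for
lineage-specific siblings (0–2, mostly 0).

What the simulator does **not** emulate: indels in CDS (pairs are
alignable by equal length), rate variation among sites and codon-usage
bias, expression correlation induced by shared regulatory context rather
than duplication, read-level noise in RPKM, and tandem arrays that
straddle assembly breaks. Passing recovery tests therefore demonstrates
algorithmic correctness under the stated generative model, not robustness
to annotation error or alignment uncertainty in real genomes.

## Numerical and design choices

- NG86 codon-pair difference counts and site counts are memoised; all
  randomness flows through one `numpy.random.Generator` per simulation, so
  outputs are byte-identical under a fixed seed.
- The classifier treats trees with loss: if an outgroup copy is lost, the
  focal clade simply attaches deeper; truth labels on lossy simulations
  are reported as accuracy, not asserted exact.
- Problem sizes in the validation suite — 500 random layouts (≤ 200
  genes), 1000 20-codon pairs for pathway enumeration, 200 estimator
  replicates of 500 codons, 50 clean families, 500 expression pairs — keep
  each check to seconds while leaving sampling error far inside the
  tolerances used (±0.05 on recovered means).
- Degenerate inputs fail loudly and early: reversed coordinates name the
  GFF line, unresolvable exon parents name the parent, translation
  mismatches name gene and codon position, tips missing from the species
  map are listed, and a config missing inputs aggregates every problem
  into one error before any stage runs.

## Known limitations

Chained single-linkage repeats can join pairs whose extreme members are
> 100 kb apart (by design — that is what makes a six-gene array one
repeat). NG86 underestimates divergence at high Ks (ancestral pairs near
saturation); the class comparison is ordinal, so this compresses but never
reverses the lineage-specific < ancestral ordering. Raw-scale Pearson
correlation of log-normally generated profiles is slightly attenuated
relative to the log-scale mixing weight; at the default stage s.d. the
attenuation is well under 0.02. The ΔΔCt model pools control timepoints;
designs with a per-timepoint control should encode the timepoint in the
condition label.
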