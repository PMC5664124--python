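# Methods

This note documents the statistical and algorithmic choices behind each
pipeline stage, the structure the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and units

All genomic coordinates are 1-based inclusive (the GTF convention); two
intervals overlap iff they share at least one base, so an exon ending at
position 200 and one starting at 201 do not overlap. Abundance is FPKM
(fragments per kilobase of transcript per million mapped reads);
simulation and testing operate on the log2 scale and convert to FPKM at
the boundary. Samples follow a tissue × stage × replicate design with
columns named `<tissue>_<stage>DAP_rep<k>`.

## lncRNA identification

The cascade applies, in order: same-strand coding-exon overlap →
expression → structure → coding-potential consensus. Each stage is a
pure predicate on a transcript, so the surviving *set* is invariant
under stage order; only the stage to which a rejection is attributed
depends on it (the order above is what the summary tables report).
Thresholds: spliced length ≥ 200 nt, ≥ 2 exons, maximum FPKM over
libraries ≥ 1. The expression comparator is configurable between `>= 1`
(default) and `> 1` because the two conventions in circulation differ
exactly at 1 FPKM.

**Coding potential.** External classifiers (CPC, CNCI, PLEK, Pfam
scans) are out of scope as programs; what the pipeline owns is the
*consensus rule*: a candidate survives only if every supplied predictor
calls it noncoding (the Venn-intersection retention rule). Predictors
are pluggable callables, and verdict tables exported from external
tools can be merged into the consensus. The built-in predictor scores
`longest ORF / sequence length` and calls coding at score ≥ 0.3 or ORF
≥ 300 nt (the classical 100-codon rule). An ORF here runs ATG → first
in-frame stop on the forward strand, stop codon included in the length;
an ATG without a downstream in-frame stop does not count. This
definition keeps the predictor exactly reproducible by a brute-force
three-frame scan, which the tests exploit.

**Classification.** Survivors are labeled with precedence antisense
(≥ 1 bp exonic overlap, opposite strand) > intronic (genomic span
contained in a single intron of a reference transcript, either strand)
> sense (same-strand exonic overlap; unreachable after the overlap
filter but defined for standalone use) > intergenic. The precedence
mirrors cuffcompare-style class-code priority. Overlap is exonic, not
gene-span: a span-level rule would make intronic lncRNAs impossible by
construction.

## Differential expression

Fold change is `(mean FPKM endosperm + c) / (mean FPKM embryo + c)`
with pseudocount `c = 0.01` FPKM, which avoids division by zero while
preserving the ordering of ratios; `fc(a,b) · fc(b,a) = 1` holds exactly
when `c = 0`. Significance comes from a two-sided Welch t-test on
log2(FPKM + 1) across replicates — chosen as the simplest defensible
test for a replicate-bearing design; the test is pluggable and the
caller exposes an optional Benjamini–Hochberg flag, but raw p-values
gate the default calls (p < 0.05 with |log2FC| ≥ 1), keeping the
conventional workflow's operating point. The degenerate zero-variance
case resolves by the limit: identical groups give p = 1, separated
constant groups give p = 0. Count-based models (negative binomial) are
out of scope: the pipeline consumes FPKM matrices, not read counts.

Stage intersection is plain set algebra over per-stage up/down sets;
tissue specificity requires detection (FPKM > 1) in at least one
library of the focal tissue and absence (FPKM < 1) in every library of
the other.

## MRE scanning

No standard algorithm exists for the "targets" relation consumed by
ceRNA analyses, so the scanner implements the widely used plant
complementarity rules explicitly: ungapped antiparallel alignment of
the miRNA against the reverse complement of each same-length window;
per-position penalties match 0 / G:U wobble 0.5 / mismatch 1.0, doubled
at miRNA positions 2–13 from the 5' end; sites are windows with total
penalty ≤ 4.0. Ungapped scanning keeps an exact brute-force oracle
feasible, and the vectorized implementation is tested for equality with
that oracle. Overlapping accepted windows collapse to the local penalty
minimum (leftmost on ties), so a single biological site is not counted
once per phase shift — MRE *counts* feed the ceRNA score, so double
counting would bias it. An optional single-bulge mode allows one
unpaired transcript nucleotide inside the duplex at a fixed penalty of
2.0. Thermodynamic (ΔG) models and degradome validation are out of
scope.

## ceRNA network

Screens: lncRNA–mRNA pairs need PCC > 0.5 at p < 0.01; a shared miRNA
must be negatively co-expressed with *both* partners at PCC < −0.5,
p < 0.01 — the negative threshold mirrors the positive one, the
least-surprising reading of "negatively co-expressed". Correlations are
computed on log2(FPKM + 1) by default (FPKM is heavy-tailed and the
planted coupling is linear on the log scale); a flag switches to the
raw scale. PCC p-values use the t-transform
`t = r·sqrt((m−2)/(1−r²))` with m−2 df.

The ceRNA score is the MRE ratio: shared-miRNA MREs on the lncRNA over
all MREs on the lncRNA, hence in [0, 1], equal to 1 iff every miRNA
targeting the lncRNA is shared with the partner, and monotone
non-decreasing in the shared set. Network assemblies elsewhere are
sometimes thresholded as "score ≥ 1", which is incompatible with a
ratio unless read as score = 1; both readings are shipped — ratio mode
with default `min_score = 1.0`, and a `count` mode where the score is
the raw number of shared-miRNA MREs — rather than silently picking one.

The hypergeometric test takes the miRNA universe N as the number of
miRNAs supplied to the run (158 in the default fixture, the size of
the known maize miRNA complement), K and n as the counts of miRNAs
targeting the lncRNA and the mRNA, and k as the shared, screen-passing
count; the upper tail is inclusive, P(X ≥ k). Retention requires k ≥ 1,
score ≥ min_score and p < 0.01, so both thresholds are monotone:
raising min_score or lowering alpha can only remove edges. Term
enrichment reuses the same tail on a user-supplied feature→term table
with fold enrichment (k/n)/(K/N) and retention at p < 0.05, FE > 4.0;
ontology retrieval and term-hierarchy handling are out of scope.

## Synthetic-data generator

The generator emulates the *downstream products* of a maize-seed-style
study, not its raw reads: transcript models on one synthetic
chromosome, spliced sequences, a miRNA complement, and FPKM matrices
over 2 tissues × 3 stages × 3 replicates (18 samples; at least three
biological replicates per condition is the field norm and the minimum
for a stable Welch test).

Defaults: 30 coding genes; 10 true lncRNAs (6 intergenic, 2 intronic,
2 antisense); 5 decoys each engineered to fail exactly one filter
(length 150 nt; mono-exonic; same-strand exon overlap; max FPKM < 1;
a planted 810-nt ORF); 158 miRNAs of 18–24 nt; 10 planted ceRNA
triplets with 2 shared miRNAs each; log2 noise SD 0.25; coupling
strength 1.5.

*Geometry.* Coding genes (3–5 exons, spliced 900–1800 nt) are laid
left to right; the first genes carry one enlarged intron (2.4–3.0 kb)
hosting the intronic candidates; antisense candidates overlap a host
gene's first exon on the opposite strand; intergenic candidates and
non-overlap decoys sit beyond the last gene. Requested counts that do
not fit a user-capped genome raise a sizing error naming the
constraint.

*Sequences.* Random bases at a target GC fraction (binomial
concentration puts a ≥ 1 kb sequence within ±5 points of the target).
Coding models get a designed ATG…stop frame covering most of the
transcript with a 3'UTR reserved for MREs; noncoding models have
incidental ORFs disrupted below the predictor's calling limits —
planting can uncover new ORFs, so disruption re-runs after planting
with the planted windows held inviolate. Planted MREs are exact reverse
complements of their miRNA (penalty 0), with optional G:U wobble edits
outside positions 2–13 to realize a planned penalty in 0.5 steps;
realized penalties are verified with the scanner's own scoring function
and recorded in the truth bundle.

*Expression.* Log-normal baselines (Normal on log2-FPKM; candidates
centered near FPKM 4, mRNAs near FPKM 11 — lncRNAs are expressed lower
than coding genes in this kind of data). Each planted triplet's shared
miRNAs follow a monotone profile z across the stage-ordered sample
groups (direction alternating between triplets), and both partners
receive `−coupling·z`, so PCC(lnc, mRNA) → +1 and PCC(miRNA, partner)
→ −1 exactly as noise → 0. miRNA expression is simulated directly:
real studies rarely document how miRNA profiles were obtained, so the
generator owns this choice and makes no attempt to match an empirical
miRNA distribution.

*What passing tests do and do not show.* The fixture has planted,
well-separated signal: perfect recovery demonstrates correctness of
the logic and statistics, not performance on real data, where
assembly artifacts, overlapping gene models, imperfect MREs, unmodeled
covariance between features and count-level noise all degrade every
stage. Read-level simulation, alignment and assembly are deliberately
not emulated.

## Determinism and problem sizes

All randomness flows through seeded NumPy generators with
per-component stream tags, so a configuration and seed reproduce the
fixture bundle byte for byte, and every CLI stage is deterministic
given its inputs (the test suite asserts byte-identical reruns).
Repeated-seed checks (network recovery, DE calibration) use the default
fixture and 10–20 seeds, with 1000-feature null panels for type-I
calibration and 200-feature panels with a planted log2 shift of 2 for
sensitivity; scanner-oracle checks draw sequences of 200–10 000 nt.
These sizes are the package's chosen study conditions and give stable
rates while keeping the suite quick on a laptop.

## Known limitations

- The scanner's ungapped model (and single-bulge option) does not score
  thermodynamic stability; site lists from energy-based tools will
  differ.
- FPKM-scale Welch testing is a pragmatic stand-in for count-model DE;
  with real libraries a negative-binomial method on counts is
  preferable.
- The hypergeometric test treats miRNA targeting as exchangeable draws
  from the universe; correlated target repertoires (miRNA families)
  violate this and make the p-values optimistic.
- Tissue specificity is a hard threshold rule, not a statistical test;
  features hovering near 1 FPKM flip classes under resampling.
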