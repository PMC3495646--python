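# Methods

## Model and procedure

The package treats promoter regulatory potential as a presence/absence
pattern of binding-site matrices over a fixed promoter window of 1200 bp
upstream and 200 bp downstream of the TSS (0-based, half-open; the TSS
sits at index 1200). Genes may own several promoters; every statistic is
first evaluated per promoter and then aggregated to the gene by
any-promoter union — except co-localization itself, which is deliberately
*not* unioned: a gene carries a motif pair or combination only if one
single promoter carries every member. This is the operational reading of
"co-localized": motifs acting together must share a regulatory region,
and counting at the gene level keeps the test units (genes) independent.

The discovery statistic is a one-sided Fisher exact test (alternative:
greater proportion in the positive class) on 2×2 per-gene presence
counts, positive class C1 ∪ C3 versus background C4, with the held-out
C2 class counted for reporting only. Multiplicity is handled by
Bonferroni throughout, with the correction factor equal to the size of
the tested family at each stage: L homotypic pairs, (L² − L)/2
heterotypic pairs, C(n, k) combinations of size k from the n selected
matrices. Bonferroni (rather than FDR) is retained for the combination
family because the downstream per-gene counting treats every significant
combination as a hard call; the family-wise guarantee is what the null
calibration test exercises.

The per-matrix score S_i sums the *corrected and capped* pair p-values
over all partners, including the homotypic diagonal term. Capping keeps
S_i bounded by the library size and makes the score insensitive to how
astronomically non-significant the worst pairs are. Selection takes the
n = 10 lowest scores; ties break lexicographically by matrix id so runs
are reproducible.

Assumptions worth stating: genes are exchangeable sampling units
(promoter count per gene is not modelled in the test); presence is
binary (occurrence multiplicity only matters for homotypic pairs, which
need two distinct strand-collapsed positions); and the two flag
annotations are taken as given at the gene level.

## Scanner

The matrix scanner implements the published Match similarity score.
Frequencies use a 0.25-per-base pseudocount, so information weights
I(i) = Σ_b f ln 4f are strictly defined (a uniform column weighs 0, a
degenerate one approaches ln 4). Matrix similarity normalizes the
window's information-weighted frequency sum between the per-position
minimum and maximum; core similarity applies the same formula on the
core window. Numerical choices:

* **Core window** = min(5, W) consecutive positions of maximal summed
  information content (chosen at parse time unless the matrix supplies
  one). Using min handles matrices narrower than the conventional 5-bp
  core.
* **Cutoffs** default to core 0.90 / matrix 0.85 and are user-settable
  per matrix. Proprietary per-matrix cutoff profiles cannot be shipped;
  these defaults give background occurrence rates comparable to
  published scan accountings (see *Limitations*).
* **N bases** contribute background frequency 0.25 at their positions
  rather than disqualifying the window, keeping masked sequence scorable
  without inventing a hard filter.
* **Degenerate matrices** (all columns uniform, Max = Min) score every
  window 1.0 rather than dividing by zero.
* **Strand handling**: both strands are scanned; hits landing at the same
  forward start on both strands collapse into one '+' record with the
  better score, because downstream occurrence counting ignores strand.

The ERE scanner reuses this machinery with a 13-bp palindromic consensus
PWM, GGTCAnnnTGACC, whose three spacer positions are uniform (zero
weight). The sensitivity setting s maps onto the score threshold
1 − 0.5·s — monotone, so raising sensitivity can only add hits; s = 0.83
(the conventional operating point) gives threshold 0.585. This is a
stand-in for a neural-network ERE finder whose internals are not
reproducible; only the role and the sensitivity knob are preserved.

## Threshold and candidate annotation

The per-gene count of significant combinations is thresholded at the
smallest t ≥ 1 maximizing the difference between the fraction of
positive-class and background genes with ≥ t combinations. t = 0 is
excluded (everyone passes); if no t separates the classes a warning is
issued and t* = 1 is used. Candidate ranks break ties lexicographically
by gene symbol. The heat map is exported as data — the binary gene ×
combination matrix, average-linkage/Euclidean leaf orders for both axes,
and Newick merge trees — with plotting optional; determinism comes from
scipy's linkage on a fixed input order, and permuting rows preserves the
merge-height multiset.

## Pathway enrichment

One-sided hypergeometric over-representation against the universe of
genes with at least one pathway annotation (unannotated genes are
discarded first), Benjamini–Hochberg step-up across all tested pathways,
retention below FDR 0.01. One-sided is the natural alternative for
over-representation; the BH implementation is statsmodels', checked in
tests against the direct step-up definition.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *shape* of the motivating study: four
categories sized 56/72/146/144 by default, 1–4 promoters per gene
(uniform), 1400-bp promoters at 50% GC, a library of random
high-information matrices (width 8–12, one dominant base per position,
distinct consensus strings), planted combinations inserted as exact
consensus strings at non-overlapping uniform positions within one
promoter of each selected gene, and ERE consensus insertions at per-
category rates (1.0 for the ERE-predicted categories C1/C2, 0 otherwise)
with flags assigned by category. Exact-consensus insertions score 1.0 by
construction, so a failed recovery implicates the statistics, not the
scanner; a noisy-insertion option mutates one position for robustness
work. Everything is deterministic under the seed (child generators for
library and cohort), to the point of byte-identical FASTA/truth files.

The recovery experiment fixes the conditions at 200 positive / 150
background genes (C1 = 50, C2 = 20, C3 = 150, C4 = 150), a 10-matrix
library, and one 4-motif combination planted at penetrance 0.15 in
positives only.

Not emulated: real promoter composition (CpG islands, repeats,
dinucleotide structure), correlated motif occurrence beyond the planted
combinations, promoter-count/gene-length biases, and any coupling
between the ERE flag and actual responsiveness. Passing tests therefore
demonstrate that the statistics recover known planted structure under
i.i.d. background sequence — not that the pipeline's calls on real
promoters are biologically correct.

## Problem sizes and observed behaviour

Tests and the acceptance script run the recovery experiment over 20
seeds (planted and null variants), each seed a full scan of ~900
promoters × 10 matrices plus 1013 combination tests — about 4 s per
seed. The Fisher oracle comparison is exhaustive over all 2×2 tables
with N ≤ 60 (~600k tables, vectorized); the scanner oracle covers 100
random sequence/matrix cases including N bases.

Under these conditions the random matrices hit background promoters at
roughly 0.2–0.35 occurrences per promoter-matrix — the same order as
published genome-scale scan accountings — so a 4-motif combination also
arises by chance in a handful of background genes. At penetrance 0.15
(≈30 of 200 positive genes) the planted combination's corrected p is
typically ≪ 0.05 and the per-seed recovery probability is ≈95%; with no
planting, Bonferroni control leaves virtually all seeds with zero
significant combinations.

## Known limitations

* Absolute hit counts from the motivating study are not recoverable:
  they depend on proprietary matrix content and per-matrix cutoff
  profiles. The pipeline's contract (which stages feed which) is
  preserved; the numbers are condition-dependent.
* The ERE stand-in shares only the consensus and the sensitivity knob
  with dedicated ERE predictors; at s = 0.83 it is deliberately
  permissive and should not be used as a precision instrument.
* Co-localization is presence-based; no distance constraint within the
  promoter is enforced (none is quantified in the source methodology).
* The homotypic-pair semantics (≥ 2 distinct positions in one promoter)
  is one defensible reading of "a pair of a matrix with itself"; the
  alternative (simple presence) would change S_i only through the
  diagonal term.
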