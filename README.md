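# ctfbs

Discovery of **co-localized transcription-factor binding site (cTFBS)
signatures** that distinguish hormone-responsive gene promoters from a
background class, and annotation of new candidate responsive genes.

## The problem

Genes that respond to a hormone (the motivating system is estrogen
response in esophageal squamous cell carcinoma) are often co-regulated
through combinations of transcription-factor binding sites that sit
together in the same promoter. Given

* promoter sequences (FASTA) mapped to genes (TSV), with per-gene flags
  for *predicted hormone response element* (e.g. an ERE) and *known
  experimental responsiveness*, and
* a TRANSFAC-format library of binding-site matrices,

the package crosses the two flags into four categories — C1 (predicted +
known), C2 (predicted only), C3 (known only), C4 (neither) — and asks:
which motif combinations are significantly over-represented in the known
responders (C1 ∪ C3) versus the background (C4)? C2 genes, which carry a
predicted response element but no experimental evidence, are held out;
those whose promoters carry enough of the discovered combinations become
ranked candidates (class C2A).

## Method

1. **Scan.** Promoters are scanned on both strands with a Match-style
   similarity score: with per-position frequencies *f(i,b)* (0.25
   pseudocount) and information weights *I(i) = Σ_b f(i,b) ln 4f(i,b)*, a
   window scores *(Current − Min)/(Max − Min)* where *Current = Σ_i
   I(i) f(i,b_i)*; a hit requires core similarity ≥ 0.90 and matrix
   similarity ≥ 0.85 (configurable). Occurrences are strand-collapsed
   distinct start positions. A 13-bp palindromic consensus
   (GGTCAnnnTGACC) PWM with a sensitivity-to-threshold mapping
   (threshold = 1 − 0.5·sensitivity) stands in for an ERE finder.
2. **Pairs.** Every unordered matrix pair M_i M_j (including M_i = M_i)
   is tested with a one-sided Fisher exact test on per-gene presence —
   a gene counts only if one single promoter carries both motifs (two
   distinct positions for a homotypic pair) — and Bonferroni-corrected:
   factor *L* for homotypic pairs, *(L² − L)/2* otherwise.
3. **Selection.** Each matrix gets the score *S_i = Σ_j corrected
   p(M_i M_j)*; the 10 matrices with the lowest S_i are kept.
4. **Combinations.** All 2¹⁰ − 10 − 1 = 1013 subsets of size 2–10 are
   Fisher-tested ((C1 ∪ C3) vs C4, C2 held out), corrected by C(10, k);
   combinations with corrected p ≤ 0.05 are the significant cTFBSs.
5. **Threshold & candidates.** Each gene is scored by the number of
   significant combinations in its promoters; the threshold t\* is the
   smallest t maximizing the positive-minus-background fraction of genes
   with ≥ t combinations. C2 genes reaching t\* are the candidates,
   ranked by count, and exported as a clustered binary heat-map matrix
   (average linkage, Euclidean distance).
6. **Enrichment.** Any gene category can be tested for pathway
   over-representation (hypergeometric test, Benjamini–Hochberg FDR
   0.01) against a user-supplied GMT file.

A synthetic-data module generates full cohorts with *known planted
structure* (motif combinations inserted at stated penetrances, ERE
consensus sites, category flags), so every stage is testable without
licensed matrix libraries or defunct databases.

## Worked example

Simulate a study-shaped cohort (56/72/146/144 genes per category, 1–4
promoters of 1400 bp each, a 10-matrix library, one 4-motif combination
planted in 15% of known responders) and run the pipeline:

```sh
ctfbs simulate --seed 3 --outdir sim
ctfbs scan    --matrices sim/matrices.transfac --promoters sim/promoters.fasta \
              --genes sim/genes.tsv --out hits.tsv
ctfbs combos  --hits hits.tsv --matrices sim/matrices.transfac \
              --promoters sim/promoters.fasta --genes sim/genes.tsv --out combos.tsv
ctfbs annotate --combos-table combos.tsv --hits hits.tsv \
               --matrices sim/matrices.transfac --promoters sim/promoters.fasta \
               --genes sim/genes.tsv --out annot.tsv --heatmap-prefix hm
```

which prints (seed 3):

```
loaded 418 genes / 1023 promoters; categories {'C1': 56, 'C2': 72, 'C3': 146, 'C4': 144}
selected matrices: V$SYN003, V$SYN001, V$SYN004, V$SYN002, ...
1013 combinations tested, 15 significant
selected threshold t* = 1
category subclass  n_genes  n_passing  pass_rate
      C1      C1A       56         19   0.339286
      C2      C2A       72          9   0.125000
      C3      C3A      146         34   0.232877
      C4      C4A      144          8   0.055556
```

The four planted motifs are selected first; the 15 significant
combinations are exactly the planted 4-mer and its sub-combinations
(supersets of a planted pair inherit its enrichment); pass rates are far
higher in the classes that received plantings (C1/C3 at penetrance 0.15)
than in the untouched background C4, and the 9 passing C2 genes would be
reported as ranked candidates in `annot.tsv`.

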