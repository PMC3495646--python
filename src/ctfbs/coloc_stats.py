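"""Co-localized motif combination enrichment statistics.

The core procedure identifies combinations of binding-site matrices
(cTFBSs) over-represented in positive-class gene promoters versus a
background class:

1. every unordered matrix pair (including a matrix with itself) is tested
   with a one-sided Fisher exact test on per-gene presence counts, and
   Bonferroni-corrected — by the library size L for homotypic pairs and
   by (L^2 - L)/2, the number of unordered heterotypic pairs, otherwise;
2. each matrix Mi receives the score S_i = sum_j corrected_p(Mi, Mj) over
   all partners j (homotypic term included); a low S_i marks a matrix that
   is both over-represented and prone to co-localize;
3. the ``top_n`` matrices with the lowest S_i are kept and every subset of
   size 2..top_n is Fisher-tested the same way, Bonferroni-corrected by
   C(top_n, k) for a k-element combination; combinations with corrected
   p <= alpha are the significant cTFBSs.

"Co-localized" is interpreted strictly: a gene counts as carrying a pair
or combination only if a single one of its promoters contains at least one
occurrence of every member (two distinct positions for a homotypic pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as iter_combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .catalog import CATEGORIES
from .motif_scan import PresenceMatrix


@dataclass(frozen=True)
class PairTestResult:
    """2x2 test of one matrix pair: positive class vs background.

    ``a`` = positive-class genes containing the pair, ``b`` = positive
    genes lacking it; ``c``, ``d`` likewise for the background class.
    """

    motif_i: str
    motif_j: str
    a: int
    b: int
    c: int
    d: int
    raw_p: float
    correction_factor: int
    corrected_p: float


@dataclass(frozen=True)
class MatrixScore:
    motif_id: str
    s_score: float


@dataclass(frozen=True)
class Combination:
    """A sorted set of 2..top_n motif ids drawn from the selected matrices."""

    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("combination members must be unique")
        if tuple(sorted(self.member_ids)) != self.member_ids:
            object.__setattr__(self, "member_ids",
                               tuple(sorted(self.member_ids)))
        if len(self.member_ids) < 2:
            raise ValueError("a combination needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def label(self) -> str:
        return "|".join(self.member_ids)


@dataclass(frozen=True)
class CombinationTestResult:
    combination: Combination
    category_counts: Mapping[str, int]  # C1..C4 and "C1+C3"
    raw_p: float
    correction_factor: int
    corrected_p: float
    significant: bool


def fisher_one_sided(a, b, c, d):
    """One-sided Fisher exact p-value, alternative: first-row proportion
    greater.

    With margins fixed, this is P(X >= a) under the hypergeometric law,
    where X is the top-left cell. Exact and deterministic. Accepts scalars
    or equally shaped integer arrays (broadcast elementwise).
    """
    a, b, c, d = (np.asarray(x) for x in (a, b, c, d))
    scalar = a.ndim == 0 and b.ndim == 0 and c.ndim == 0 and d.ndim == 0
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("all counts must be >= 0")
    if ((a + b) == 0).any() or ((c + d) == 0).any():
        raise ValueError("empty class: both row margins must be positive")
    total = a + b + c + d
    # X ~ Hypergeom(total, a+c successes, a+b draws); sf(a-1) = P(X >= a)
    p = hypergeom.sf(a - 1, total, a + c, a + b)
    return float(p) if scalar else p


def pair_correction_factors(library_size: int) -> tuple[int, int]:
    """Bonferroni factors (homotypic, heterotypic) for a library of size L:
    L and (L^2 - L)/2."""
    L = library_size
    if L < 2:
        raise ValueError("library must hold at least 2 matrices")
    return L, (L * L - L) // 2


def _bonferroni(p: float, factor: int) -> float:
    return min(1.0, p * factor)


def pair_presence(presence: PresenceMatrix, motif_i: str,
                  motif_j: str) -> np.ndarray:
    """Per-gene boolean: does some single promoter carry the pair?

    Heterotypic (i != j): a promoter must hold >= 1 occurrence of each
    motif. Homotypic (i == j): a promoter must hold >= 2 distinct
    strand-collapsed occurrence positions of the motif.
    """
    col_i = presence.motif_column(motif_i)
    if motif_i == motif_j:
        promoter_ok = col_i >= 2
    else:
        promoter_ok = (col_i >= 1) & (presence.motif_column(motif_j) >= 1)
    return presence.aggregate_to_genes(promoter_ok)


def combo_presence(presence: PresenceMatrix,
                   combination: Combination) -> np.ndarray:
    """Per-gene boolean: some single promoter carries every member motif."""
    promoter_ok = np.ones(len(presence.promoter_ids), dtype=bool)
    for m in combination.member_ids:
        promoter_ok &= presence.motif_column(m) >= 1
    return presence.aggregate_to_genes(promoter_ok)


def _class_masks(presence: PresenceMatrix, positive_genes: Sequence[str],
                 background_genes: Sequence[str]
                 ) -> tuple[np.ndarray, np.ndarray]:
    gene_index = {g: i for i, g in enumerate(presence.gene_ids)}
    pos = np.zeros(len(presence.gene_ids), dtype=bool)
    bg = np.zeros(len(presence.gene_ids), dtype=bool)
    for g in positive_genes:
        pos[gene_index[g]] = True
    for g in background_genes:
        bg[gene_index[g]] = True
    if not pos.any() or not bg.any():
        raise ValueError("positive and background classes must be non-empty")
    return pos, bg


def test_all_pairs(presence: PresenceMatrix,
                   positive_genes: Sequence[str],
                   background_genes: Sequence[str],
                   motif_ids: Sequence[str] | None = None
                   ) -> list[PairTestResult]:
    """Fisher-test every unordered matrix pair, homotypic pairs included.

    Bonferroni factors: L for Mi = Mj, (L^2 - L)/2 for Mi != Mj, with L
    the library size.
    """
    motif_ids = sorted(motif_ids if motif_ids is not None
                       else presence.motif_ids)
    L = len(motif_ids)
    homo_factor, hetero_factor = pair_correction_factors(L)
    pos_mask, bg_mask = _class_masks(presence, positive_genes,
                                     background_genes)
    n_pos, n_bg = int(pos_mask.sum()), int(bg_mask.sum())

    results = []
    for idx_i, mi in enumerate(motif_ids):
        for mj in motif_ids[idx_i:]:
            gene_has = pair_presence(presence, mi, mj)
            a = int((gene_has & pos_mask).sum())
            c = int((gene_has & bg_mask).sum())
            b, d = n_pos - a, n_bg - c
            raw = fisher_one_sided(a, b, c, d)
            factor = homo_factor if mi == mj else hetero_factor
            results.append(PairTestResult(
                motif_i=mi, motif_j=mj, a=a, b=b, c=c, d=d, raw_p=raw,
                correction_factor=factor,
                corrected_p=_bonferroni(raw, factor),
            ))
    return results


def score_matrices(pair_results: Sequence[PairTestResult]
                   ) -> list[MatrixScore]:
    """S_i = sum over partners j of corrected_p(Mi, Mj), homotypic included."""
    scores: dict[str, float] = {}
    for r in pair_results:
        scores[r.motif_i] = scores.get(r.motif_i, 0.0) + r.corrected_p
        if r.motif_j != r.motif_i:
            scores[r.motif_j] = scores.get(r.motif_j, 0.0) + r.corrected_p
    return [MatrixScore(m, s) for m, s in sorted(scores.items())]


def score_and_select(pair_results: Sequence[PairTestResult],
                     top_n: int) -> list[str]:
    """The ``top_n`` matrices with the lowest S_i score.

    Ties break lexicographically by motif id; the returned list is ordered
    by ascending score.
    """
    scores = score_matrices(pair_results)
    if top_n > len(scores):
        raise ValueError(
            f"top_n={top_n} exceeds library size {len(scores)}"
        )
    ranked = sorted(scores, key=lambda s: (s.s_score, s.motif_id))
    return [s.motif_id for s in ranked[:top_n]]


def enumerate_combinations(selected: Sequence[str]) -> list[Combination]:
    """All subsets of size 2..n of the selected motifs: 2^n - n - 1 total."""
    members = sorted(selected)
    out = []
    for k in range(2, len(members) + 1):
        for combo in iter_combinations(members, k):
            out.append(Combination(member_ids=combo))
    return out


def test_combinations(combinations: Sequence[Combination],
                      presence: PresenceMatrix,
                      cohort_categories: Mapping[str, str],
                      alpha: float = 0.05,
                      top_n: int = 10) -> list[CombinationTestResult]:
    """Fisher-test each combination: positive class C1 ∪ C3 vs background C4.

    C2 genes are held out of the test and only counted for reporting. The
    Bonferroni factor for a k-element combination is C(top_n, k);
    significance is corrected_p <= alpha.
    """
    gene_ids = presence.gene_ids
    cat = np.array([cohort_categories[g] for g in gene_ids])
    masks = {c: cat == c for c in CATEGORIES}
    pos_mask = masks["C1"] | masks["C3"]
    bg_mask = masks["C4"]
    if not pos_mask.any() or not bg_mask.any():
        raise ValueError("positive and background classes must be non-empty")
    n_pos, n_bg = int(pos_mask.sum()), int(bg_mask.sum())

    results = []
    for combination in combinations:
        gene_has = combo_presence(presence, combination)
        counts = {c: int((gene_has & masks[c]).sum()) for c in CATEGORIES}
        counts["C1+C3"] = counts["C1"] + counts["C3"]
        a = counts["C1+C3"]
        c = counts["C4"]
        raw = fisher_one_sided(a, n_pos - a, c, n_bg - c)
        factor = comb(top_n, combination.size)
        corrected = _bonferroni(raw, factor)
        results.append(CombinationTestResult(
            combination=combination,
            category_counts=counts,
            raw_p=raw,
            correction_factor=factor,
            corrected_p=corrected,
            significant=corrected <= alpha,
        ))
    return results


def combination_report(results: Sequence[CombinationTestResult],
                       category_sizes: Mapping[str, int]):
    """Tabular report of combination tests with per-category percentages."""
    import pandas as pd

    rows = []
    sizes = dict(category_sizes)
    sizes["C1+C3"] = sizes["C1"] + sizes["C3"]
    for r in sorted(results, key=lambda r: (r.corrected_p,
                                            r.combination.label)):
        row = {"label": r.combination.label, "k": r.combination.size}
        for c in ("C1+C3",) + CATEGORIES:
            n = r.category_counts[c]
            row[f"{c}_genes"] = n
            row[f"{c}_pct"] = 100.0 * n / sizes[c] if sizes[c] else 0.0
        row.update(raw_p=r.raw_p, correction_factor=r.correction_factor,
                   corrected_p=r.corrected_p, significant=r.significant)
        rows.append(row)
    return pd.DataFrame(rows)
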