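"""Gene-level signature: threshold choice, candidate annotation, heat map.

Once the significant combinations are known, each gene is scored by the
number of distinct significant combinations present in (any one of) its
promoters. The per-gene count threshold t* is chosen where the fraction of
positive-class genes with >= t combinations exceeds the background
fraction by the largest margin; held-out C2 genes reaching t* become the
candidate set (class C2A), ranked by combination count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .catalog import CATEGORIES, Cohort
from .coloc_stats import Combination, CombinationTestResult, combo_presence
from .motif_scan import PresenceMatrix

DEFAULT_THRESHOLD = 4  # fallback when no curve separates the classes


@dataclass
class ThresholdCurve:
    """Per-threshold class fractions and their difference.

    ``positive_fraction[t]`` is the fraction of positive-class genes with
    at least ``t`` significant combinations; likewise for the background.
    Both sequences are non-increasing in t and equal 1 at t = 0.
    """

    thresholds: np.ndarray
    positive_fraction: np.ndarray
    background_fraction: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.positive_fraction - self.background_fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.thresholds,
            "positive_fraction": self.positive_fraction,
            "background_fraction": self.background_fraction,
            "difference": self.difference,
        })


@dataclass
class CandidateAnnotation:
    gene_id: str
    symbol: str
    category: str
    n_significant_combos: int
    passes_threshold: bool
    rank: int | None = None  # 1..K among candidates, None otherwise


def count_combos_per_gene(
    significant_combos: Sequence[Combination | CombinationTestResult],
    presence: PresenceMatrix,
) -> pd.Series:
    """Number of distinct significant combinations present in each gene."""
    combos = [
        c.combination if isinstance(c, CombinationTestResult) else c
        for c in significant_combos
    ]
    counts = np.zeros(len(presence.gene_ids), dtype=int)
    for combination in combos:
        counts += combo_presence(presence, combination).astype(int)
    return pd.Series(counts, index=presence.gene_ids, name="n_combos")


def threshold_curve(counts: pd.Series, positive_genes: Sequence[str],
                    background_genes: Sequence[str]) -> ThresholdCurve:
    """Fractions of each class reaching every threshold 0..max(count)."""
    pos = counts.loc[list(positive_genes)].to_numpy()
    bg = counts.loc[list(background_genes)].to_numpy()
    t_max = int(counts.max()) if len(counts) else 0
    ts = np.arange(t_max + 1)
    pos_frac = np.array([(pos >= t).mean() for t in ts])
    bg_frac = np.array([(bg >= t).mean() for t in ts])
    return ThresholdCurve(ts, pos_frac, bg_frac)


def select_threshold(curve: ThresholdCurve) -> int:
    """Smallest t >= 1 maximizing the positive-minus-background fraction
    difference.

    t = 0 is excluded (every gene trivially passes). If no threshold gives
    a positive difference the classes are inseparable; a warning is issued
    and t* = 1 is returned.
    """
    mask = curve.thresholds >= 1
    if not mask.any():
        warnings.warn("threshold curve has no t >= 1; defaulting to t* = 1")
        return 1
    diffs = curve.difference[mask]
    ts = curve.thresholds[mask]
    if diffs.max() <= 0:
        warnings.warn(
            "no threshold separates positive from background "
            "(all differences <= 0); defaulting to t* = 1"
        )
        return 1
    return int(ts[int(np.argmax(diffs))])  # argmax returns the smallest t


def annotate_candidates(
    cohort: Cohort, counts: pd.Series, t_star: int
) -> tuple[list[CandidateAnnotation], pd.DataFrame]:
    """Annotate every gene against the threshold and rank the C2 candidates.

    Returns the annotation list (all genes) and a per-category pass-rate
    table ('A subclass': genes with >= t* significant combinations).
    Candidates are the C2 genes passing t*, ranked by descending
    combination count, ties broken lexicographically by gene symbol.
    """
    annotations = []
    for gid in sorted(cohort.genes):
        gene = cohort.genes[gid]
        n = int(counts.get(gid, 0))
        annotations.append(CandidateAnnotation(
            gene_id=gid,
            symbol=gene.symbol,
            category=gene.category,
            n_significant_combos=n,
            passes_threshold=n >= t_star,
        ))

    candidates = [a for a in annotations
                  if a.category == "C2" and a.passes_threshold]
    candidates.sort(key=lambda a: (-a.n_significant_combos, a.symbol))
    for rank, a in enumerate(candidates, start=1):
        a.rank = rank

    rows = []
    for c in CATEGORIES:
        in_cat = [a for a in annotations if a.category == c]
        n_pass = sum(a.passes_threshold for a in in_cat)
        rows.append({
            "category": c,
            "subclass": f"{c}A",
            "n_genes": len(in_cat),
            "n_passing": n_pass,
            "pass_rate": n_pass / len(in_cat) if in_cat else 0.0,
        })
    return annotations, pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Heat-map export
# ----------------------------------------------------------------------

@dataclass
class HeatmapData:
    """Binary gene x combination matrix with clustering orderings.

    Rows and columns are ordered by agglomerative average-linkage
    clustering on Euclidean distance; the merge trees are exportable as
    Newick strings. The acceptance surface is this data, not an image.
    """

    matrix: pd.DataFrame  # genes x combination labels, values 0/1
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None

    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]

    def row_tree_newick(self) -> str:
        return _linkage_to_newick(self.row_linkage, self.matrix.index)

    def col_tree_newick(self) -> str:
        return _linkage_to_newick(self.col_linkage, self.matrix.columns)

    def plot(self, path: str) -> None:
        """Optional rendering of the clustered matrix (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ordered = self.ordered()
        fig, ax = plt.subplots(
            figsize=(max(4, 0.3 * ordered.shape[1]),
                     max(3, 0.25 * ordered.shape[0]))
        )
        ax.imshow(ordered.to_numpy(), cmap="Reds", aspect="auto",
                  vmin=0, vmax=1)
        ax.set_xticks(range(ordered.shape[1]))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(ordered.shape[0]))
        ax.set_yticklabels(ordered.index, fontsize=6)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _linkage_to_newick(Z: np.ndarray | None, labels: Sequence[str]) -> str:
    labels = list(labels)
    if Z is None:
        return "(" + ",".join(f"{l}:0" for l in labels) + ");"

    def _height(node_id: int) -> float:
        return 0.0 if node_id < len(labels) else Z[node_id - len(labels)][2]

    def build(node_id: int, branch: float) -> str:
        if node_id < len(labels):
            return f"{labels[node_id]}:{branch:g}"
        row = Z[node_id - len(labels)]
        height = row[2]
        left = build(int(row[0]), height - _height(int(row[0])))
        right = build(int(row[1]), height - _height(int(row[1])))
        return f"({left},{right}):{branch:g}"

    root = len(labels) + len(Z) - 1
    row = Z[-1]
    height = row[2]
    left = build(int(row[0]), height - _height(int(row[0])))
    right = build(int(row[1]), height - _height(int(row[1])))
    return f"({left},{right});"


def export_heatmap(
    candidate_genes: Sequence[str],
    significant_combos: Sequence[Combination | CombinationTestResult],
    presence: PresenceMatrix,
) -> HeatmapData:
    """Binary candidate x combination presence matrix, clustered both ways.

    A cell is 1 iff the combination is present in the gene. With fewer
    than two rows or columns the matrix is emitted unclustered with a
    warning.
    """
    combos = [
        c.combination if isinstance(c, CombinationTestResult) else c
        for c in significant_combos
    ]
    candidate_genes = list(candidate_genes)
    gene_index = {g: i for i, g in enumerate(presence.gene_ids)}
    missing = [g for g in candidate_genes if g not in gene_index]
    if missing:
        raise KeyError(f"unknown candidate genes: {missing[:5]}")

    cols = {}
    for combination in combos:
        gene_has = combo_presence(presence, combination)
        cols[combination.label] = [
            int(gene_has[gene_index[g]]) for g in candidate_genes
        ]
    matrix = pd.DataFrame(cols, index=candidate_genes, dtype=int)

    def cluster(mat: np.ndarray, labels: list[str]):
        if mat.shape[0] < 2:
            warnings.warn("fewer than 2 items; emitting unclustered")
            return None, list(labels)
        Z = linkage(pdist(mat, metric="euclidean"), method="average")
        order = [labels[i] for i in leaves_list(Z)]
        return Z, order

    values = matrix.to_numpy(dtype=float)
    row_linkage, row_order = cluster(values, candidate_genes)
    col_linkage, col_order = cluster(values.T, list(matrix.columns))
    return HeatmapData(matrix=matrix, row_order=row_order,
                       col_order=col_order, row_linkage=row_linkage,
                       col_linkage=col_linkage)
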