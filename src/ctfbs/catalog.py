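"""Gene/promoter cohort loading and four-way categorization.

A cohort ties promoter sequences (FASTA) to genes (TSV mapping table) and
carries two per-gene annotation flags:

* ``ere_predicted`` — an estrogen response element was predicted in at least
  one promoter of the gene;
* ``known_responsive`` — the gene is experimentally known to respond to
  estrogen.

Crossing the two flags yields four categories:

=========  =============  ================
category   ERE predicted  known responsive
=========  =============  ================
C1         yes            yes
C2         yes            no
C3         no             yes
C4         no             no
=========  =============  ================

C1 ∪ C3 (all known responders) is the positive class for signature
discovery, C4 is the background, and C2 is held out: C2 genes carry a
predicted ERE but no experimental evidence, so they are the candidates the
signature is later used to annotate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("C1", "C2", "C3", "C4")

_VALID_BASES = frozenset("ACGTN")


class CohortError(ValueError):
    """Raised when a cohort's inputs are inconsistent or malformed."""


@dataclass(frozen=True)
class CohortConfig:
    """Analysis-wide settings.

    Parameters
    ----------
    window_upstream, window_downstream
        Promoter window relative to the TSS, in bases. Every promoter
        sequence must have length ``window_upstream + window_downstream``
        with the TSS sitting at index ``window_upstream`` (0-based,
        half-open coordinates).
    alpha
        Significance level applied to Bonferroni-corrected combination
        p-values.
    enrichment_fdr
        Benjamini–Hochberg FDR level for pathway enrichment.
    ere_sensitivity
        Sensitivity setting of the ERE scanner, mapped internally to a
        score threshold.
    top_n
        Number of matrices retained for combination testing.
    """

    window_upstream: int = 1200
    window_downstream: int = 200
    alpha: float = 0.05
    enrichment_fdr: float = 0.01
    ere_sensitivity: float = 0.83
    top_n: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.enrichment_fdr < 1:
            raise ValueError(
                f"enrichment_fdr must be in (0, 1), got {self.enrichment_fdr}"
            )
        if not 0 < self.ere_sensitivity <= 1:
            raise ValueError(
                f"ere_sensitivity must be in (0, 1], got {self.ere_sensitivity}"
            )
        if self.top_n < 2:
            raise ValueError(f"top_n must be >= 2, got {self.top_n}")
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise ValueError("window sizes must be non-negative")

    @property
    def promoter_length(self) -> int:
        return self.window_upstream + self.window_downstream

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class PromoterRecord:
    """One promoter sequence tied to a gene.

    ``tss_offset`` is the 0-based index of the TSS within ``sequence``; it
    equals the upstream window size, so the sequence covers
    ``[TSS - upstream, TSS + downstream)`` on the promoter's own axis.
    """

    promoter_id: str
    gene_id: str
    sequence: str
    tss_offset: int


@dataclass
class GeneRecord:
    gene_id: str
    symbol: str
    promoter_ids: list[str] = field(default_factory=list)
    ere_predicted: bool = False
    known_responsive: bool = False

    @property
    def category(self) -> str:
        return classify_gene(self.ere_predicted, self.known_responsive)


def classify_gene(ere_predicted: bool, known_responsive: bool) -> str:
    """Map the two annotation flags onto the four-way category.

    (True, True) → C1, (True, False) → C2, (False, True) → C3,
    (False, False) → C4.
    """
    if ere_predicted:
        return "C1" if known_responsive else "C2"
    return "C3" if known_responsive else "C4"


@dataclass
class Cohort:
    """A classified collection of genes and their promoters."""

    genes: dict[str, GeneRecord]
    promoters: dict[str, PromoterRecord]
    config: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        for gene in self.genes.values():
            if not gene.promoter_ids:
                raise CohortError(f"gene {gene.gene_id} has no promoters")
            for pid in gene.promoter_ids:
                if pid not in self.promoters:
                    raise CohortError(
                        f"gene {gene.gene_id} lists unknown promoter {pid}"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_promoters(self) -> int:
        return len(self.promoters)

    def genes_in(self, *categories: str) -> list[str]:
        """Gene ids belonging to any of the given categories, sorted."""
        wanted = set(categories)
        unknown = wanted - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        return sorted(
            g.gene_id for g in self.genes.values() if g.category in wanted
        )

    def positive_genes(self) -> list[str]:
        """The known-responder class C1 ∪ C3."""
        return self.genes_in("C1", "C3")

    def background_genes(self) -> list[str]:
        """The background class C4."""
        return self.genes_in("C4")

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for gene in self.genes.values():
            counts[gene.category] += 1
        return counts

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(p.sequence), id=pid, description="")
            for pid, p in sorted(self.promoters.items())
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_table(self, path: str | Path) -> None:
        rows = []
        for gid in sorted(self.genes):
            g = self.genes[gid]
            for pid in g.promoter_ids:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "symbol": g.symbol,
                        "promoter_id": pid,
                        "ere_predicted": int(g.ere_predicted),
                        "known_responsive": int(g.known_responsive),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_flag(value: object, column: str, gene_id: str) -> bool:
    try:
        ivalue = int(value)
    except (TypeError, ValueError):
        ivalue = -1
    if ivalue not in (0, 1):
        raise CohortError(
            f"gene {gene_id}: {column} must be 0 or 1, got {value!r}"
        )
    return bool(ivalue)


def load_cohort(
    promoter_fasta: str | Path | io.TextIOBase,
    gene_table: str | Path | io.TextIOBase,
    config: CohortConfig | None = None,
) -> Cohort:
    """Load and validate a cohort from FASTA promoters and a TSV gene table.

    The gene table must have columns ``gene_id``, ``symbol``,
    ``promoter_id``, ``ere_predicted`` and ``known_responsive`` (flags as
    0/1), one row per (gene, promoter). Every listed promoter must appear in
    the FASTA, sequences may contain only A/C/G/T/N, and each sequence must
    span exactly the configured promoter window.
    """
    config = config or CohortConfig()

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(promoter_fasta, "fasta"):
        if rec.id in seqs:
            raise CohortError(f"duplicate promoter id in FASTA: {rec.id}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise CohortError(
                f"promoter {rec.id}: invalid characters {sorted(bad)}"
            )
        if len(seq) != config.promoter_length:
            raise CohortError(
                f"promoter {rec.id}: length {len(seq)} != configured window "
                f"{config.promoter_length}"
            )
        seqs[rec.id] = seq

    table = pd.read_csv(gene_table, sep="\t", dtype=str)
    required = {"gene_id", "symbol", "promoter_id", "ere_predicted",
                "known_responsive"}
    missing = required - set(table.columns)
    if missing:
        raise CohortError(f"gene table missing columns: {sorted(missing)}")

    if table["promoter_id"].duplicated().any():
        dups = table.loc[table["promoter_id"].duplicated(), "promoter_id"]
        raise CohortError(f"duplicate promoter ids in table: {sorted(set(dups))}")

    genes: dict[str, GeneRecord] = {}
    promoters: dict[str, PromoterRecord] = {}
    for row in table.itertuples(index=False):
        gid, pid = row.gene_id, row.promoter_id
        if pid not in seqs:
            raise CohortError(
                f"promoter {pid} (gene {gid}) listed in table but absent "
                f"from FASTA"
            )
        ere = _parse_flag(row.ere_predicted, "ere_predicted", gid)
        known = _parse_flag(row.known_responsive, "known_responsive", gid)
        if gid in genes:
            g = genes[gid]
            if (g.ere_predicted, g.known_responsive) != (ere, known):
                raise CohortError(f"gene {gid}: inconsistent flags across rows")
            g.promoter_ids.append(pid)
        else:
            genes[gid] = GeneRecord(
                gene_id=gid,
                symbol=row.symbol,
                promoter_ids=[pid],
                ere_predicted=ere,
                known_responsive=known,
            )
        promoters[pid] = PromoterRecord(
            promoter_id=pid,
            gene_id=gid,
            sequence=seqs[pid],
            tss_offset=config.window_upstream,
        )

    orphans = set(seqs) - set(promoters)
    if orphans:
        raise CohortError(
            f"FASTA promoters not listed in gene table: {sorted(orphans)[:5]}"
        )

    return Cohort(genes=genes, promoters=promoters, config=config)


def category_counts(cohort: Cohort) -> dict[str, int]:
    """Number of genes per category; values sum to the cohort size."""
    return cohort.category_counts()
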