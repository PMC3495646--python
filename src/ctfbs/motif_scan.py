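"""TRANSFAC matrix parsing and Match-style promoter scanning.

The scanner implements the published Match matrix-similarity score. For a
position frequency matrix with per-column frequencies ``f(i, b)`` (0.25
pseudocount per base) and information weights

    I(i) = sum_b f(i, b) * ln(4 * f(i, b)),

a window ``b_1..b_W`` scores

    similarity = (Current - Min) / (Max - Min),
    Current    = sum_i I(i) * f(i, b_i),

with ``Min``/``Max`` substituting the per-position minimum/maximum
frequency. Core similarity applies the same formula to the (up to) five
consecutive core positions. A window is a hit when core similarity >=
``core_cutoff`` and matrix similarity >= ``matrix_cutoff``. Both strands
are scanned; hits landing at the same forward start on both strands are
collapsed to a single '+' hit, because downstream occurrence counting
ignores strand.

``N`` bases contribute background frequency 0.25 at their positions rather
than disqualifying the window.

The estrogen response element (ERE) scanner reuses the same machinery with
a 13-bp palindromic consensus (GGTCAnnnTGACC; the three ``n`` spacer
positions carry zero weight) and maps a sensitivity setting ``s`` onto the
score threshold ``1 - 0.5*s``: higher sensitivity, lower threshold, more
hits.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .catalog import Cohort

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N
CORE_LENGTH = 5

ERE_CONSENSUS = "GGTCANNNTGACC"


class TransfacParseError(ValueError):
    """Raised for malformed TRANSFAC flat files, with a line number."""


@dataclass
class MotifMatrix:
    """A position frequency matrix with Match-style scoring cutoffs.

    ``counts`` has shape (W, 4) in column order A, C, G, T. ``core_start``
    indexes the first of the (up to five) core positions; by default it is
    placed on the consecutive stretch of maximal summed information
    content.
    """

    motif_id: str
    counts: np.ndarray
    core_start: int | None = None
    core_cutoff: float = 0.90
    matrix_cutoff: float = 0.85

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(
                f"{self.motif_id}: counts must be (W, 4), got "
                f"{self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError(f"{self.motif_id}: empty matrix column")
        if not (0 <= self.core_cutoff <= 1 and 0 <= self.matrix_cutoff <= 1):
            raise ValueError(f"{self.motif_id}: cutoffs must lie in [0, 1]")
        if self.core_start is None:
            self.core_start = _default_core_start(self.counts)
        core_len = min(CORE_LENGTH, self.width)
        if not 0 <= self.core_start <= self.width - core_len:
            raise ValueError(
                f"{self.motif_id}: core_start {self.core_start} out of range"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def core_length(self) -> int:
        return min(CORE_LENGTH, self.width)

    def frequencies(self) -> np.ndarray:
        """Per-position base frequencies with a 0.25 pseudocount per base."""
        pseudo = self.counts + 0.25
        return pseudo / pseudo.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        """Highest-frequency base at each position."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


def _default_core_start(counts: np.ndarray) -> int:
    freqs = counts + 0.25
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    info = (freqs * np.log(4.0 * freqs)).sum(axis=1)
    core_len = min(CORE_LENGTH, len(info))
    sums = np.convolve(info, np.ones(core_len), mode="valid")
    return int(sums.argmax())


def information_vector(matrix: MotifMatrix) -> np.ndarray:
    """Per-position information weights I(i) = sum_b f(i,b) ln(4 f(i,b)).

    Non-negative; 0 for a uniform column, approaching ln 4 for a
    degenerate one.
    """
    f = matrix.frequencies()
    return (f * np.log(4.0 * f)).sum(axis=1)


# ----------------------------------------------------------------------
# TRANSFAC flat-file I/O
# ----------------------------------------------------------------------

def _validate_transfac_text(text: str) -> None:
    """Structural pre-check so malformed files fail with a line number."""
    in_matrix = False
    open_record_line = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        tag = stripped.split(None, 1)[0]
        if tag == "ID":
            open_record_line = lineno
        elif tag == "//":
            open_record_line = None
            in_matrix = False
        elif tag in ("P0", "PO"):
            in_matrix = True
        elif in_matrix and tag.isdigit():
            fields = stripped.split()
            # position label + 4 counts, optionally a consensus letter
            if len(fields) not in (5, 6):
                raise TransfacParseError(
                    f"line {lineno}: matrix row has {len(fields) - 1} "
                    f"columns, expected 4 counts (A C G T)"
                )
        elif in_matrix:
            in_matrix = False
    if open_record_line is not None:
        raise TransfacParseError(
            f"record opened at line {open_record_line} is missing its "
            f"'//' terminator"
        )


def parse_transfac(
    matrix_file: str | Path | io.TextIOBase,
    core_cutoff: float = 0.90,
    matrix_cutoff: float = 0.85,
) -> list[MotifMatrix]:
    """Parse a TRANSFAC flat file into :class:`MotifMatrix` objects.

    Column order is normalized to A, C, G, T. Cutoffs apply uniformly to
    every matrix; per-matrix cutoff profiles can be set on the returned
    objects afterwards.
    """
    if isinstance(matrix_file, (str, Path)):
        text = Path(matrix_file).read_text()
    else:
        text = matrix_file.read()
    _validate_transfac_text(text)
    try:
        records = bio_motifs.parse(io.StringIO(text), "TRANSFAC")
    except ValueError as exc:
        raise TransfacParseError(str(exc)) from exc
    out = []
    for rec in records:
        motif_id = rec.get("ID") or rec.get("AC") or rec.get("NA")
        if not motif_id:
            raise TransfacParseError("matrix record has no ID/AC/NA identifier")
        counts = np.column_stack([rec.counts[b] for b in BASES])
        out.append(
            MotifMatrix(
                motif_id=motif_id,
                counts=counts,
                core_cutoff=core_cutoff,
                matrix_cutoff=matrix_cutoff,
            )
        )
    return out


def write_transfac(matrices: Sequence[MotifMatrix],
                   path: str | Path) -> None:
    """Write matrices back out as a TRANSFAC flat file."""
    lines: list[str] = []
    for m in matrices:
        lines.append(f"ID  {m.motif_id}")
        lines.append("P0      A      C      G      T")
        for i, row in enumerate(m.counts, start=1):
            vals = "".join(f"{v:7g}" for v in row)
            lines.append(f"{i:02d}{vals}")
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Scanning
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    motif_id: str
    start: int  # 0-based on the forward axis
    strand: str  # '+' or '-'
    score: float


@dataclass(frozen=True)
class EreHit:
    promoter_id: str
    start: int
    strand: str
    score: float


_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _base, _code in _CODE.items():
    _ENCODE_TABLE[ord(_base)] = _code
    _ENCODE_TABLE[ord(_base.lower())] = _code


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as 0..4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[raw]
    if (codes < 0).any():
        bad = chr(raw[int(np.argmax(codes < 0))])
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


class _MatrixScorer:
    """Precomputed per-matrix scoring tables, reused across promoters.

    Built from the matrix counts once; cutoff changes on the matrix do not
    require a rebuild (cutoffs are applied by the caller), but counts are
    treated as fixed after construction.
    """

    def __init__(self, matrix: MotifMatrix) -> None:
        W = matrix.width
        f = matrix.frequencies()  # (W, 4)
        info = (f * np.log(4.0 * f)).sum(axis=1)
        # column 4 handles N: background frequency 0.25
        f5 = np.column_stack([f, np.full(W, 0.25)])
        self.width = W
        self.weighted = info[:, None] * f5  # (W, 5)
        w_min = info * f.min(axis=1)
        w_max = info * f.max(axis=1)
        self.lo, self.hi = w_min.sum(), w_max.sum()
        cs, cl = matrix.core_start, matrix.core_length
        self.core_slice = slice(cs, cs + cl)
        self.core_lo = w_min[self.core_slice].sum()
        self.core_hi = w_max[self.core_slice].sum()
        self._pos = np.arange(W)

    def window_scores(self, codes: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Matrix and core similarities for every window of one strand."""
        windows = np.lib.stride_tricks.sliding_window_view(codes, self.width)
        contrib = self.weighted[self._pos, windows]  # (n_windows, W)
        sim = _normalize(contrib.sum(axis=1), self.lo, self.hi)
        core_sim = _normalize(contrib[:, self.core_slice].sum(axis=1),
                              self.core_lo, self.core_hi)
        return sim, core_sim


def _scorer_for(matrix: MotifMatrix) -> _MatrixScorer:
    scorer = matrix.__dict__.get("_scorer")
    if scorer is None:
        scorer = matrix.__dict__["_scorer"] = _MatrixScorer(matrix)
    return scorer


def _window_scores(codes: np.ndarray, matrix: MotifMatrix
                   ) -> tuple[np.ndarray, np.ndarray]:
    return _scorer_for(matrix).window_scores(codes)


def _normalize(current: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi - lo < 1e-12:  # fully uniform matrix: every window equally good
        return np.ones_like(current)
    return (current - lo) / (hi - lo)


def scan_promoter(seq: str, matrix: MotifMatrix,
                  promoter_id: str = "") -> list[MotifHit]:
    """Scan one sequence with one matrix on both strands.

    Hits at the same forward start on both strands are collapsed into a
    single '+' record carrying the better score. Sequences shorter than
    the matrix yield an empty list.
    """
    W = matrix.width
    if len(seq) < W:
        logger.debug("sequence shorter than matrix %s; no hits",
                     matrix.motif_id)
        return []
    codes = encode_sequence(seq)
    n_win = len(seq) - W + 1

    sim_f, core_f = _window_scores(codes, matrix)
    rc_codes = _COMPLEMENT_CODE[codes][::-1]
    sim_r, core_r = _window_scores(rc_codes, matrix)
    # window p on the reverse-complement corresponds to forward start
    # len(seq) - W - p; reverse the arrays to index by forward start
    sim_r = sim_r[::-1]
    core_r = core_r[::-1]

    hit_f = (sim_f >= matrix.matrix_cutoff) & (core_f >= matrix.core_cutoff)
    hit_r = (sim_r >= matrix.matrix_cutoff) & (core_r >= matrix.core_cutoff)

    hits: list[MotifHit] = []
    for start in np.flatnonzero(hit_f | hit_r):
        start = int(start)
        if hit_f[start] and hit_r[start]:
            strand, score = "+", max(sim_f[start], sim_r[start])
        elif hit_f[start]:
            strand, score = "+", sim_f[start]
        else:
            strand, score = "-", sim_r[start]
        hits.append(MotifHit(promoter_id, matrix.motif_id, start, strand,
                             float(score)))
    return hits


def ere_matrix() -> MotifMatrix:
    """The 13-bp palindromic ERE consensus GGTCAnnnTGACC as a matrix.

    Defined positions are near-degenerate; the three spacer positions are
    uniform and therefore carry zero information weight.
    """
    counts = np.empty((len(ERE_CONSENSUS), 4))
    for i, base in enumerate(ERE_CONSENSUS):
        if base == "N":
            counts[i] = 25.0
        else:
            counts[i] = 0.0
            counts[i, BASES.index(base)] = 100.0
    return MotifMatrix(motif_id="ERE_CONSENSUS", counts=counts,
                       core_start=0, core_cutoff=0.0, matrix_cutoff=0.0)


def ere_threshold(sensitivity: float) -> float:
    """Map scanner sensitivity onto a similarity threshold, 1 - 0.5*s."""
    if not 0 < sensitivity <= 1:
        raise ValueError(f"sensitivity must be in (0, 1], got {sensitivity}")
    return 1.0 - 0.5 * sensitivity


def scan_ere(seq: str, sensitivity: float = 0.83,
             promoter_id: str = "") -> list[EreHit]:
    """Scan for estrogen response elements at the given sensitivity.

    The threshold decreases as sensitivity rises, so a higher sensitivity
    always yields a superset of hits.
    """
    threshold = ere_threshold(sensitivity)
    matrix = ere_matrix()
    matrix.matrix_cutoff = threshold
    return [
        EreHit(h.promoter_id, h.start, h.strand, h.score)
        for h in scan_promoter(seq, matrix, promoter_id=promoter_id)
    ]


def scan_cohort(cohort: Cohort, matrices: Sequence[MotifMatrix]
                ) -> list[MotifHit]:
    """Scan every promoter in a cohort with every matrix."""
    hits: list[MotifHit] = []
    for pid in sorted(cohort.promoters):
        seq = cohort.promoters[pid].sequence
        for m in matrices:
            hits.extend(scan_promoter(seq, m, promoter_id=pid))
    return hits


# ----------------------------------------------------------------------
# Presence structures
# ----------------------------------------------------------------------

class PresenceMatrix:
    """Per-promoter motif occurrences and the derived per-gene view.

    Occurrences are distinct start positions with strand collapsed. A gene
    is positive for a motif iff at least one of its promoters carries at
    least one occurrence.
    """

    def __init__(self, cohort: Cohort, motif_ids: Sequence[str]) -> None:
        self.cohort = cohort
        self.motif_ids = list(motif_ids)
        self.promoter_ids = sorted(cohort.promoters)
        self.gene_ids = sorted(cohort.genes)
        self._motif_index = {m: i for i, m in enumerate(self.motif_ids)}
        self._promoter_index = {p: i for i, p in enumerate(self.promoter_ids)}
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self.positions: dict[tuple[str, str], set[int]] = {}
        # distinct-position counts, promoters x motifs
        self.occ_counts = np.zeros(
            (len(self.promoter_ids), len(self.motif_ids)), dtype=np.int32
        )
        self.promoter_gene_idx = np.array(
            [self._gene_index[cohort.promoters[p].gene_id]
             for p in self.promoter_ids]
        )

    def add_hit(self, hit: MotifHit) -> None:
        if hit.promoter_id not in self._promoter_index:
            raise KeyError(
                f"hit references unknown promoter {hit.promoter_id!r}"
            )
        if hit.motif_id not in self._motif_index:
            raise KeyError(f"hit references unknown motif {hit.motif_id!r}")
        key = (hit.promoter_id, hit.motif_id)
        posns = self.positions.setdefault(key, set())
        if hit.start not in posns:
            posns.add(hit.start)
            self.occ_counts[
                self._promoter_index[hit.promoter_id],
                self._motif_index[hit.motif_id],
            ] += 1

    def motif_column(self, motif_id: str) -> np.ndarray:
        if motif_id not in self._motif_index:
            raise KeyError(f"unknown motif {motif_id!r}")
        return self.occ_counts[:, self._motif_index[motif_id]]

    def aggregate_to_genes(self, promoter_bool: np.ndarray) -> np.ndarray:
        """Any-promoter union of a per-promoter boolean vector."""
        out = np.zeros(len(self.gene_ids), dtype=bool)
        np.logical_or.at(out, self.promoter_gene_idx, promoter_bool)
        return out

    def gene_view(self) -> pd.DataFrame:
        """Boolean genes x motifs presence DataFrame."""
        data = {
            m: self.aggregate_to_genes(self.occ_counts[:, i] >= 1)
            for i, m in enumerate(self.motif_ids)
        }
        return pd.DataFrame(data, index=self.gene_ids)


def build_presence(hits: Iterable[MotifHit], cohort: Cohort,
                   motif_ids: Sequence[str]) -> PresenceMatrix:
    """Collect hits into a :class:`PresenceMatrix`.

    Positions are deduplicated ignoring strand; an unknown promoter or
    motif id raises.
    """
    presence = PresenceMatrix(cohort, motif_ids)
    for hit in hits:
        presence.add_hit(hit)
    return presence
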