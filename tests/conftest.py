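"""Shared fixtures: tiny cohorts, toy presence matrices, naive oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ctfbs.catalog import Cohort, CohortConfig, GeneRecord, PromoterRecord
from ctfbs.motif_scan import MotifMatrix, PresenceMatrix


def make_cohort(gene_specs, promoter_length=20, tss_offset=15):
    """Build a cohort from (gene_id, ere, known, [promoter seqs]) tuples.

    Sequences are padded/truncated to ``promoter_length`` with 'A'.
    """
    genes, promoters = {}, {}
    config = CohortConfig(window_upstream=tss_offset,
                          window_downstream=promoter_length - tss_offset)
    for gid, ere, known, seqs in gene_specs:
        pids = []
        for i, seq in enumerate(seqs, start=1):
            pid = f"{gid}_p{i}"
            seq = (seq + "A" * promoter_length)[:promoter_length]
            promoters[pid] = PromoterRecord(pid, gid, seq, tss_offset)
            pids.append(pid)
        genes[gid] = GeneRecord(gene_id=gid, symbol=f"SYM_{gid}",
                                promoter_ids=pids, ere_predicted=ere,
                                known_responsive=known)
    return Cohort(genes=genes, promoters=promoters, config=config)


def make_presence(cohort, motif_ids, occurrences):
    """PresenceMatrix populated from {(promoter_id, motif_id): [starts]}."""
    from ctfbs.motif_scan import MotifHit, build_presence

    hits = [
        MotifHit(pid, mid, start, "+", 1.0)
        for (pid, mid), starts in occurrences.items()
        for start in starts
    ]
    return build_presence(hits, cohort, motif_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_cohort():
    """Four genes, one per category, single promoters."""
    return make_cohort([
        ("g1", True, True, ["ACGTACGTACGTACGTACGT"]),
        ("g2", True, False, ["TTTTACGTACGTACGTTTTT"]),
        ("g3", False, True, ["ACGTACGTACGTACGTACGT"]),
        ("g4", False, False, ["GGGGACGTACGTACGTGGGG"]),
    ])


# ----------------------------------------------------------------------
# Independent oracles
# ----------------------------------------------------------------------

def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) by direct summation of hypergeometric probabilities.

    Exact rational arithmetic via math.comb; fully independent of scipy.
    """
    r1, r2 = a + b, c + d
    col1 = a + c
    total = r1 + r2
    denom = math.comb(total, col1)
    num = sum(
        math.comb(r1, x) * math.comb(r2, col1 - x)
        for x in range(a, min(r1, col1) + 1)
    )
    return num / denom


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq):
    return seq.translate(_COMPLEMENT)[::-1]


def naive_match_scan(seq, matrix: MotifMatrix):
    """Per-window re-evaluation of the Match similarity formula.

    Scores every window on both strands independently, then applies the
    same strand-collapsing rule; pure Python, no shared code with the
    scanner internals.
    """
    W = matrix.width
    pseudo = matrix.counts + 0.25
    f = pseudo / pseudo.sum(axis=1, keepdims=True)
    info = [
        sum(f[i][b] * math.log(4 * f[i][b]) for b in range(4))
        for i in range(W)
    ]
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def freq(i, ch):
        return 0.25 if ch == "N" else f[i][base_idx[ch]]

    def sim(window, positions):
        cur = sum(info[i] * freq(i, window[i]) for i in positions)
        lo = sum(info[i] * min(f[i]) for i in positions)
        hi = sum(info[i] * max(f[i]) for i in positions)
        if hi - lo < 1e-12:
            return 1.0
        return (cur - lo) / (hi - lo)

    cs = matrix.core_start
    core_positions = list(range(cs, cs + matrix.core_length))
    all_positions = list(range(W))

    per_strand = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for p in range(len(s) - W + 1):
            window = s[p:p + W]
            m_sim = sim(window, all_positions)
            c_sim = sim(window, core_positions)
            if m_sim >= matrix.matrix_cutoff and c_sim >= matrix.core_cutoff:
                start = p if strand == "+" else len(s) - W - p
                per_strand[(start, strand)] = m_sim

    collapsed = {}
    for (start, strand), score in sorted(per_strand.items()):
        if (start, "+") in per_strand and (start, "-") in per_strand:
            collapsed[start] = ("+", max(per_strand[(start, "+")],
                                         per_strand[(start, "-")]))
        else:
            collapsed[start] = (strand, score)
    return collapsed  # start -> (strand, score)


def random_matrix(rng, width, motif_id="M"):
    counts = rng.integers(0, 12, size=(width, 4)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1.0
    return MotifMatrix(motif_id=motif_id, counts=counts)


def random_dna(rng, length, with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))
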