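"""Gene-set pathway over-representation with Benjamini–Hochberg control.

Each pathway is tested for over-representation of a gene set against the
universe of genes carrying at least one pathway annotation (genes without
any annotation are discarded before testing). The raw p-value is the
one-sided hypergeometric tail; adjustment is Benjamini–Hochberg step-up
across all tested pathways, and pathways are retained below the
configured FDR (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PathwayTestResult:
    pathway_id: str
    overlap: int
    set_size: int
    pathway_size: int
    universe_size: int
    raw_p: float
    adjusted_p: float
    retained: bool


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes...."""
    pathways: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(),
                                  start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and "
                f">= 1 gene"
            )
        name, genes = fields[0], {g for g in fields[2:] if g}
        if name in pathways:
            raise ValueError(f"{path}:{lineno}: duplicate pathway {name!r}")
        pathways[name] = genes
    return pathways


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Monotonicity is enforced; a p-value outside (0, 1] raises.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(gene_set: Iterable[str],
           pathways: Mapping[str, set[str]] | str | Path,
           universe: Iterable[str] | None = None,
           fdr: float = 0.01) -> list[PathwayTestResult]:
    """Hypergeometric over-representation of ``gene_set`` in each pathway.

    The universe defaults to all genes annotated to at least one pathway;
    an explicit universe is intersected with that annotated set, and the
    gene set is intersected with the universe before testing. Results are
    returned for every pathway, sorted by (adjusted_p, pathway_id), with
    ``retained`` marking adjusted_p < fdr.
    """
    if isinstance(pathways, (str, Path)):
        pathways = read_gmt(pathways)
    annotated: set[str] = set().union(*pathways.values()) if pathways else set()
    universe_set = (annotated if universe is None
                    else set(universe) & annotated)
    if not universe_set:
        raise ValueError("empty universe after intersecting with annotations")
    test_set = set(gene_set) & universe_set
    if not test_set:
        raise ValueError("gene set is empty after intersection with universe")

    N = len(universe_set)
    n = len(test_set)
    names = sorted(pathways)
    raw = []
    meta = []
    for name in names:
        members = pathways[name] & universe_set
        K = len(members)
        k = len(members & test_set)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        raw.append(float(hypergeom.sf(k - 1, N, K, n)))
        meta.append((name, k, K))
    adjusted = bh_adjust(raw)

    results = [
        PathwayTestResult(
            pathway_id=name, overlap=k, set_size=n, pathway_size=K,
            universe_size=N, raw_p=p, adjusted_p=float(q),
            retained=bool(q < fdr),
        )
        for (name, k, K), p, q in zip(meta, raw, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.pathway_id))
    return results


def enrichment_table(results: Sequence[PathwayTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
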