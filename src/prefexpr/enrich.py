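"""Term enrichment: one-sided Fisher/hypergeometric test with BY and BH FDR.

Mirrors the AgriGO-style settings of the reproduced analysis: Fisher's
exact test for over-representation, the Benjamini–Yekutieli step-up
(FDR valid under arbitrary dependence) at level 0.05, and an additional
raw-p cutoff of 1e-5 used for GO terms.  KEGG-style analyses reuse the
same machinery with the BY flag only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "fisher_enrich",
    "adjust_bh",
    "adjust_by",
    "P_CUTOFF",
    "FDR_LEVEL",
]

#: raw-p significance cutoff applied to GO-style enrichment
P_CUTOFF = 1e-5
#: BY-adjusted FDR level
FDR_LEVEL = 0.05


@dataclass
class AnnotationSet:
    """One functional term and its annotated genes."""

    term_id: str
    term_name: str
    gene_ids: set[str]
    namespace: str = "custom"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"term {self.term_id} has no genes")


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def adjust_bh(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = _validate_p(np.fromiter(p_values, dtype=float))
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_by(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values.

    BH multiplied by ``c(m) = sum_{i=1..m} 1/i``, capped at 1 and
    monotone-enforced; controls FDR under arbitrary dependence.
    """
    p = _validate_p(np.fromiter(p_values, dtype=float))
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def _as_terms(
    annotations: Mapping[str, Iterable[str]] | Iterable[AnnotationSet],
) -> list[AnnotationSet]:
    if isinstance(annotations, Mapping):
        return [
            AnnotationSet(term_id=t, term_name=t, gene_ids=set(g))
            for t, g in annotations.items()
        ]
    return list(annotations)


def fisher_enrich(
    selected: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, Iterable[str]] | Iterable[AnnotationSet],
    p_cutoff: float = P_CUTOFF,
    fdr_level: float = FDR_LEVEL,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``selected`` within ``universe``.

    Per term with K annotated genes in a universe of N, of which k fall
    in the n selected genes, the upper-tail p is
    ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  Terms are
    restricted to the universe; terms with no universe gene are dropped.

    Returns a table indexed by term id with columns
    ``k, K, n, N, p, p_bh, p_by, sig_raw, sig_by``.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise ValueError("selected gene set is empty")
    if not selected <= universe:
        extra = sorted(selected - universe)[:5]
        raise ValueError(f"selected genes outside the universe: {extra}")
    terms = _as_terms(annotations)
    N = len(universe)
    n = len(selected)
    rows = []
    for term in terms:
        members = term.gene_ids & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term.term_id, term.term_name, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"]
    ).set_index("term_id")
    if len(table):
        table["p_bh"] = adjust_bh(table["p"].to_numpy())
        table["p_by"] = adjust_by(table["p"].to_numpy())
    else:
        table["p_bh"] = table["p_by"] = np.array([], dtype=float)
    table["sig_raw"] = table["p"] < p_cutoff
    table["sig_by"] = table["p_by"] <= fdr_level
    return table.sort_values("p")
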