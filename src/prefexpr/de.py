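"""Two-group differential expression and the dual-caller consensus rule.

The analysis this package reproduces takes the *intersection* of the
gene lists called differentially expressed by two independent methods,
each filtered at |log2 fold change| >= 2 and adjusted p <= 0.05.  The
consensus operator here accepts any two result tables in the common
``(gene_id, log2fc, p, q)`` layout — read from files produced by
external callers, or produced by :func:`simple_de`, a self-contained
two-group test provided so the pipeline runs end-to-end without
external software.

:func:`simple_de` computes

* log2 fold change on group-mean FPKM with a pseudocount of 1 FPKM,
  so zero-expression genes have bounded fold changes;
* a p-value from a two-group rate score test on counts: group rates
  ``lambda = sum(counts) / sum(library sizes)`` are compared with the
  model-based variance evaluated at the pooled null rate, using a
  negative-binomial variance ``mu + phi * mu^2`` with a common
  method-of-moments dispersion ``phi`` pooled across genes (Poisson,
  ``phi = 0``, when either group lacks replicates);
* q-values by Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import CountMatrix, compute_fpkm

__all__ = ["ConsensusConfig", "simple_de", "consensus_deg", "estimate_dispersion"]

#: pseudocount (FPKM) used when taking log2 of group means
LOG_PSEUDOCOUNT = 1.0


@dataclass
class ConsensusConfig:
    """Thresholds of the dual-caller consensus filter."""

    lfc_threshold: float = 2.0
    q_threshold: float = 0.05

    def validate(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")


def estimate_dispersion(counts: CountMatrix, groups: Sequence[Sequence[str]]) -> float:
    """Common NB dispersion, pooled across genes by method of moments.

    For each group with n >= 2 libraries, residuals around the group
    rate estimate contribute ``(y - mu)^2 * n/(n-1) - mu`` to the
    numerator and ``mu^2`` to the denominator; the ratio of sums over
    all genes and groups estimates ``phi`` in
    ``Var(y) = mu + phi * mu^2``.  Returns 0 when no group has
    replicates (Poisson fallback).
    """
    num = 0.0
    den = 0.0
    for members in groups:
        members = list(members)
        n = len(members)
        if n < 2:
            continue
        y = counts.counts[members].to_numpy(dtype=float)
        s = counts.library_sizes[members].to_numpy(dtype=float)
        lam = y.sum(axis=1) / s.sum()
        mu = lam[:, None] * s[None, :]
        with np.errstate(invalid="ignore"):
            resid2 = (y - mu) ** 2 * (n / (n - 1))
        num += float((resid2 - mu).sum())
        den += float((mu**2).sum())
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def simple_de(
    counts: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    dispersion: float | str = "auto",
    method_label: str = "simple_de",
) -> pd.DataFrame:
    """Per-gene two-group DE table (log2fc, p, q).

    ``dispersion`` is the NB dispersion ``phi``: a float fixes it,
    ``"auto"`` estimates a common value by method of moments from
    within-group replicates (0, i.e. Poisson, when there are none).
    """
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    missing = (set(a) | set(b)) - set(counts.sample_ids)
    if missing:
        raise ValueError(f"samples absent from count matrix: {sorted(missing)}")

    if dispersion == "auto":
        phi = estimate_dispersion(counts, [a, b])
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be non-negative")

    fpkm = compute_fpkm(counts).fpkm
    mean_a = fpkm[a].mean(axis=1).to_numpy()
    mean_b = fpkm[b].mean(axis=1).to_numpy()
    lfc = np.log2((mean_a + LOG_PSEUDOCOUNT) / (mean_b + LOG_PSEUDOCOUNT))

    y_a = counts.counts[a].to_numpy(dtype=float)
    y_b = counts.counts[b].to_numpy(dtype=float)
    s_a = counts.library_sizes[a].to_numpy(dtype=float)
    s_b = counts.library_sizes[b].to_numpy(dtype=float)
    t_a, t_b = y_a.sum(axis=1), y_b.sum(axis=1)
    S_a, S_b = s_a.sum(), s_b.sum()
    lam_a, lam_b = t_a / S_a, t_b / S_b
    lam0 = (t_a + t_b) / (S_a + S_b)

    # model-based variance of each group rate at the pooled null
    mu_a = lam0[:, None] * s_a[None, :]
    mu_b = lam0[:, None] * s_b[None, :]
    var_a = (mu_a + phi * mu_a**2).sum(axis=1) / S_a**2
    var_b = (mu_b + phi * mu_b**2).sum(axis=1) / S_b**2
    denom = np.sqrt(var_a + var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, (lam_a - lam_b) / denom, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    allzero = (t_a + t_b) == 0
    p[allzero] = 1.0
    lfc[allzero] = 0.0
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {"log2fc": lfc, "p": p, "q": q},
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    table.attrs["method_label"] = method_label
    table.attrs["dispersion"] = phi
    return table


def _passing(table: pd.DataFrame, config: ConsensusConfig) -> set[str]:
    if table.index.has_duplicates:
        raise ValueError("duplicate gene ids in DE table")
    mask = (table["log2fc"].abs() >= config.lfc_threshold) & (
        table["q"] <= config.q_threshold
    )
    return set(table.index[mask])


def consensus_deg(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    config: ConsensusConfig | None = None,
) -> set[str]:
    """Genes passing |log2fc| and q thresholds in BOTH result tables."""
    config = config or ConsensusConfig()
    config.validate()
    return _passing(results_a, config) & _passing(results_b, config)
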