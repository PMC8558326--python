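"""Two-tier stage-preferential expression screen.

Tier 1 ("preferentially expressed"): a gene passes if its FPKM exceeds
``min_fpkm`` in every target-stage sample and is at least ``fold`` times
the FPKM of every comparator sample.  Tier 2 ("specifically expressed")
keeps the tier-1 genes whose target FPKM is additionally at least
``fold`` times the FPKM of every developing-stage sample.

Two readings of "times higher than the other samples" are exposed:

* ``strict`` (default) — the *minimum* target FPKM must clear the fold
  bar against each comparator sample individually; the conservative,
  per-sample reading.
* ``mean`` — the target *mean* is used instead of the minimum, for
  sensitivity analysis.

Fold comparisons are multiplicative (``target >= fold * comparator``),
so zero-FPKM comparators are passed vacuously and no division occurs.
Ties at exactly the fold threshold pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["ScreenConfig", "ScreenResult", "preferential_screen", "refine_specific"]


@dataclass
class ScreenConfig:
    """Sample roles and thresholds for the preferential-expression screen."""

    target_samples: Sequence[str]
    comparator_samples: Sequence[str]
    developing_samples: Sequence[str] = ()
    min_fpkm: float = 1.0
    fold: float = 2.0
    aggregation_mode: str = "strict"

    def validate(self, expr: ExpressionMatrix | None = None) -> None:
        t, c, d = (
            set(self.target_samples),
            set(self.comparator_samples),
            set(self.developing_samples),
        )
        if not t or not c:
            raise ValueError("target and comparator sample lists must be non-empty")
        if t & c or t & d or c & d:
            raise ValueError("target/comparator/developing samples must be disjoint")
        if self.min_fpkm <= 0:
            raise ValueError("min_fpkm must be positive")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.aggregation_mode not in ("strict", "mean"):
            raise ValueError("aggregation_mode must be 'strict' or 'mean'")
        if expr is not None:
            present = set(expr.sample_ids)
            missing = (t | c | d) - present
            if missing:
                raise ValueError(f"samples absent from matrix: {sorted(missing)}")


@dataclass
class ScreenResult:
    """Gene sets surviving the two filter tiers, with a per-gene audit.

    ``audit`` has one row per input gene: ``tier1``/``tier2`` booleans
    and the first rule each failing gene violated
    (``low-expression in <sample>`` or ``insufficient-fold vs <sample>``).
    """

    tier1_genes: set[str]
    tier2_genes: set[str] = field(default_factory=set)
    audit: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.tier2_genes <= self.tier1_genes:
            raise ValueError("tier-2 genes must be a subset of tier-1 genes")


def _target_level(fpkm_t: np.ndarray, mode: str) -> np.ndarray:
    """The per-gene target statistic compared against the fold bar."""
    return fpkm_t.min(axis=1) if mode == "strict" else fpkm_t.mean(axis=1)


def preferential_screen(expr: ExpressionMatrix, config: ScreenConfig) -> ScreenResult:
    """Apply the tier-1 preferential-expression filter."""
    config.validate(expr)
    targets = list(config.target_samples)
    comparators = list(config.comparator_samples)
    fpkm_t = expr.fpkm[targets].to_numpy()
    fpkm_c = expr.fpkm[comparators].to_numpy()

    if config.aggregation_mode == "strict":
        expressed = fpkm_t > config.min_fpkm  # every target sample
        low_ok = expressed.all(axis=1)
    else:
        low_ok = fpkm_t.mean(axis=1) > config.min_fpkm
        expressed = np.repeat(low_ok[:, None], len(targets), axis=1)
    level = _target_level(fpkm_t, config.aggregation_mode)
    fold_ok_per = level[:, None] >= config.fold * fpkm_c
    fold_ok = fold_ok_per.all(axis=1)
    passed = low_ok & fold_ok

    reasons = np.full(len(expr.gene_ids), "pass", dtype=object)
    low_fail = ~low_ok
    if low_fail.any():
        first_low = np.argmax(~expressed, axis=1)
        reasons[low_fail] = [
            f"low-expression in {targets[j]}" for j in first_low[low_fail]
        ]
    fold_fail = low_ok & ~fold_ok
    if fold_fail.any():
        first_cmp = np.argmax(~fold_ok_per, axis=1)
        reasons[fold_fail] = [
            f"insufficient-fold vs {comparators[j]}" for j in first_cmp[fold_fail]
        ]
    audit = pd.DataFrame(
        {"tier1": passed, "tier1_fail_reason": reasons},
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    tier1 = set(np.asarray(expr.gene_ids, dtype=object)[passed].tolist())
    return ScreenResult(tier1_genes=tier1, tier2_genes=set(), audit=audit)


def refine_specific(
    result: ScreenResult, expr: ExpressionMatrix, config: ScreenConfig
) -> ScreenResult:
    """Apply the tier-2 specificity filter against developing-stage samples."""
    config.validate(expr)
    developing = list(config.developing_samples)
    if not developing:
        raise ValueError("developing_samples must be non-empty for tier 2")
    targets = list(config.target_samples)
    fpkm_t = expr.fpkm[targets].to_numpy()
    fpkm_d = expr.fpkm[developing].to_numpy()
    level = _target_level(fpkm_t, config.aggregation_mode)
    fold_ok_per = level[:, None] >= config.fold * fpkm_d
    fold_ok = fold_ok_per.all(axis=1)

    gene_arr = np.asarray(expr.gene_ids, dtype=object)
    in_tier1 = np.array([g in result.tier1_genes for g in gene_arr])
    passed = in_tier1 & fold_ok

    audit = (
        result.audit.copy()
        if result.audit is not None
        else pd.DataFrame(index=pd.Index(expr.gene_ids, name="gene_id"))
    )
    reasons = np.full(len(gene_arr), "pass", dtype=object)
    reasons[~in_tier1] = "not in tier 1"
    fold_fail = in_tier1 & ~fold_ok
    if fold_fail.any():
        first_dev = np.argmax(~fold_ok_per, axis=1)
        reasons[fold_fail] = [
            f"insufficient-fold vs {developing[j]}" for j in first_dev[fold_fail]
        ]
    audit["tier2"] = passed
    audit["tier2_fail_reason"] = reasons
    tier2 = set(gene_arr[passed].tolist())
    return ScreenResult(
        tier1_genes=set(result.tier1_genes), tier2_genes=tier2, audit=audit
    )
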