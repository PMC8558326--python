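"""Relative quantification of qRT-PCR data by the Livak 2^-ddCt method.

Cycle-threshold (Ct) replicates are averaged in Ct space; each gene is
normalised against a reference gene within its sample
(dCt = Ct_gene - Ct_ref), then against a calibrator sample
(ddCt = dCt_sample - dCt_calibrator); relative expression is 2^-ddCt,
assuming perfect amplification efficiency (a doubling per cycle).  The
replicate standard deviation of the sample's dCt is carried into a
fold range by exponentiating ddCt ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtTable", "DdctResult", "ddct", "relative_expression_table"]

#: reference gene of the reproduced assay (a pineapple Tubulin)
DEFAULT_REFERENCE_GENE = "Aco023422"


@dataclass
class CtTable:
    """Long-format Ct measurements with reference gene and calibrator.

    ``data`` columns: ``sample``, ``gene``, ``replicate``, ``ct``.
    The reference gene must be measured in every sample.
    """

    data: pd.DataFrame
    reference_gene: str = DEFAULT_REFERENCE_GENE
    calibrator_sample: str | None = None

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("empty Ct table")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        samples = set(self.data["sample"])
        with_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        if samples - with_ref:
            raise ValueError(
                f"reference gene {self.reference_gene} not measured in samples: "
                f"{sorted(samples - with_ref)}"
            )
        if self.calibrator_sample is None:
            self.calibrator_sample = sorted(samples)[0]
        elif self.calibrator_sample not in samples:
            raise ValueError(f"calibrator sample absent: {self.calibrator_sample}")

    def _ct_stats(self, gene: str, sample: str) -> tuple[float, float]:
        rows = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        if len(rows) == 0:
            raise ValueError(f"gene {gene} not measured in sample {sample}")
        ct = rows["ct"].to_numpy(dtype=float)
        return float(ct.mean()), float(ct.std(ddof=1)) if len(ct) > 1 else 0.0

    def delta_ct(self, gene: str, sample: str) -> tuple[float, float]:
        """(dCt, SD): gene Ct minus reference Ct, replicate-averaged.

        SD combines gene and reference replicate SDs in quadrature.
        """
        m_gene, s_gene = self._ct_stats(gene, sample)
        m_ref, s_ref = self._ct_stats(self.reference_gene, sample)
        return m_gene - m_ref, float(np.hypot(s_gene, s_ref))


@dataclass
class DdctResult:
    """Relative expression (fold) with its dCt-SD-derived fold range."""

    gene: str
    sample: str
    fold: float
    fold_low: float
    fold_high: float
    sd_ct: float


def ddct(table: CtTable, gene: str, sample: str) -> DdctResult:
    """Relative expression of ``gene`` in ``sample`` vs the calibrator."""
    d_sample, sd = table.delta_ct(gene, sample)
    d_cal, _ = table.delta_ct(gene, table.calibrator_sample)
    dd = d_sample - d_cal
    return DdctResult(
        gene=gene,
        sample=sample,
        fold=2.0 ** (-dd),
        fold_low=2.0 ** (-(dd + sd)),
        fold_high=2.0 ** (-(dd - sd)),
        sd_ct=sd,
    )


def relative_expression_table(table: CtTable) -> pd.DataFrame:
    """ddCt folds for every (gene, sample) pair in the table."""
    rows = []
    for gene in sorted(set(table.data["gene"])):
        for sample in sorted(set(table.data["sample"])):
            measured = (
                (table.data["gene"] == gene) & (table.data["sample"] == sample)
            ).any()
            if not measured:
                continue
            r = ddct(table, gene, sample)
            rows.append((gene, sample, r.fold, r.fold_low, r.fold_high, r.sd_ct))
    return pd.DataFrame(
        rows, columns=["gene", "sample", "fold", "fold_low", "fold_high", "sd_ct"]
    )
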