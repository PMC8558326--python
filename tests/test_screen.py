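"""Unit and property tests for the two-tier preferential-expression screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefexpr import (
    ExpressionMatrix,
    ScreenConfig,
    ScreenResult,
    SimulationConfig,
    compute_fpkm,
    preferential_screen,
    refine_specific,
    simulate_experiment,
)

from conftest import make_expr

SAMPLES = ["T1", "T2", "C1", "C2", "D1"]
CFG = ScreenConfig(
    target_samples=["T1", "T2"],
    comparator_samples=["C1", "C2"],
    developing_samples=["D1"],
)


def brute_force_screen(expr, cfg):
    """Independent per-gene re-evaluation of the written screening rules."""
    tier1, tier2 = set(), set()
    for gene in expr.gene_ids:
        row = expr.fpkm.loc[gene]
        t = [row[s] for s in cfg.target_samples]
        level = min(t) if cfg.aggregation_mode == "strict" else sum(t) / len(t)
        if cfg.aggregation_mode == "strict":
            expressed = all(v > cfg.min_fpkm for v in t)
        else:
            expressed = level > cfg.min_fpkm
        fold_ok = all(level >= cfg.fold * row[s] for s in cfg.comparator_samples)
        if expressed and fold_ok:
            tier1.add(gene)
            if all(level >= cfg.fold * row[s] for s in cfg.developing_samples):
                tier2.add(gene)
    return tier1, tier2


class TestTier1Rules:
    def test_clear_pass(self):
        expr = make_expr({"g": [4, 4, 2, 1, 1]}, SAMPLES)
        assert preferential_screen(expr, CFG).tier1_genes == {"g"}

    def test_low_expression_fails_with_audit(self):
        expr = make_expr({"g": [0.9, 4, 0, 0, 0]}, SAMPLES)
        result = preferential_screen(expr, CFG)
        assert result.tier1_genes == set()
        assert result.audit.loc["g", "tier1_fail_reason"] == "low-expression in T1"

    def test_insufficient_fold_names_comparator(self):
        expr = make_expr({"g": [4, 4, 1, 2.5, 0]}, SAMPLES)
        result = preferential_screen(expr, CFG)
        assert result.tier1_genes == set()
        assert result.audit.loc["g", "tier1_fail_reason"] == "insufficient-fold vs C2"

    def test_tie_at_exact_fold_passes(self):
        expr = make_expr({"g": [4, 4, 2, 2, 0]}, SAMPLES)
        assert preferential_screen(expr, CFG).tier1_genes == {"g"}

    def test_zero_comparators_pass_vacuously(self):
        expr = make_expr({"g": [1.5, 1.2, 0, 0, 0]}, SAMPLES)
        assert preferential_screen(expr, CFG).tier1_genes == {"g"}

    def test_mean_mode_uses_target_mean(self):
        # min target 3 < 2*2 fails strict; mean 4 >= 2*2 passes mean mode
        expr = make_expr({"g": [3, 5, 2, 1, 0]}, SAMPLES)
        assert preferential_screen(expr, CFG).tier1_genes == set()
        mean_cfg = ScreenConfig(
            target_samples=["T1", "T2"], comparator_samples=["C1", "C2"],
            developing_samples=["D1"], aggregation_mode="mean",
        )
        assert preferential_screen(expr, mean_cfg).tier1_genes == {"g"}

    def test_missing_sample_errors(self):
        expr = make_expr({"g": [1, 2, 3]}, ["T1", "T2", "C1"])
        with pytest.raises(ValueError, match="absent"):
            preferential_screen(expr, CFG)

    def test_overlapping_roles_error(self):
        with pytest.raises(ValueError, match="disjoint"):
            ScreenConfig(target_samples=["a"], comparator_samples=["a"]).validate()


class TestTier2Rules:
    def test_retained_when_developing_low(self):
        expr = make_expr({"g": [4, 4, 1, 1, 2]}, SAMPLES)
        result = refine_specific(preferential_screen(expr, CFG), expr, CFG)
        assert result.tier2_genes == {"g"}

    def test_dropped_when_developing_equal(self):
        expr = make_expr({"g": [4, 4, 1, 1, 4]}, SAMPLES)
        result = refine_specific(preferential_screen(expr, CFG), expr, CFG)
        assert result.tier1_genes == {"g"}
        assert result.tier2_genes == set()
        assert result.audit.loc["g", "tier2_fail_reason"] == "insufficient-fold vs D1"

    def test_empty_tier1_gives_empty_tier2(self):
        expr = make_expr({"g": [0.5, 0.5, 0, 0, 0]}, SAMPLES)
        result = refine_specific(preferential_screen(expr, CFG), expr, CFG)
        assert result.tier2_genes == set()

    def test_tier2_requires_developing_samples(self):
        cfg = ScreenConfig(target_samples=["T1"], comparator_samples=["C1"])
        expr = make_expr({"g": [4, 1]}, ["T1", "C1"])
        with pytest.raises(ValueError, match="developing"):
            refine_specific(preferential_screen(expr, cfg), expr, cfg)

    def test_subset_invariant_enforced(self):
        with pytest.raises(ValueError, match="subset"):
            ScreenResult(tier1_genes={"a"}, tier2_genes={"a", "b"})


@st.composite
def expr_matrices(draw):
    n_genes = draw(st.integers(1, 12))
    rows = {
        f"g{i}": [
            draw(st.floats(0, 10, allow_nan=False, width=32)) for _ in SAMPLES
        ]
        for i in range(n_genes)
    }
    return make_expr(rows, SAMPLES)


class TestScreenProperties:
    @given(expr=expr_matrices(), mode=st.sampled_from(["strict", "mean"]))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_oracle(self, expr, mode):
        cfg = ScreenConfig(
            target_samples=["T1", "T2"], comparator_samples=["C1", "C2"],
            developing_samples=["D1"], aggregation_mode=mode,
        )
        result = refine_specific(preferential_screen(expr, cfg), expr, cfg)
        oracle1, oracle2 = brute_force_screen(expr, cfg)
        assert result.tier1_genes == oracle1
        assert result.tier2_genes == oracle2

    @given(expr=expr_matrices(),
           fold=st.floats(1.0, 5.0), tighter=st.floats(0.1, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_anti_monotone_in_thresholds(self, expr, fold, tighter):
        loose = ScreenConfig(target_samples=["T1", "T2"],
                             comparator_samples=["C1", "C2"], fold=fold)
        tight = ScreenConfig(target_samples=["T1", "T2"],
                             comparator_samples=["C1", "C2"], fold=fold + tighter,
                             min_fpkm=1.0 + tighter)
        assert (preferential_screen(expr, tight).tier1_genes
                <= preferential_screen(expr, loose).tier1_genes)

    @given(expr=expr_matrices())
    @settings(max_examples=50, deadline=None)
    def test_tier2_subset_of_tier1(self, expr):
        result = refine_specific(preferential_screen(expr, CFG), expr, CFG)
        assert result.tier2_genes <= result.tier1_genes
        assert set(result.audit.index) == set(expr.gene_ids)


def test_organ_swap_yields_disjoint_sets():
    """Swapping ovule/stamen roles must not re-call organ-exclusive genes."""
    sim = SimulationConfig(n_genes=300, n_planted_preferential=20,
                           n_planted_specific=10, dispersion=0.0, seed=5)
    counts, truth = simulate_experiment(sim)
    expr = compute_fpkm(counts)
    mmc = ScreenConfig(
        target_samples=["Ovule_1", "Ovule_2"],
        comparator_samples=["Leaf", "Root", "Flower", "Stamen_1", "Stamen_2",
                            "Stamen_6", "Ovule_7"],
    )
    pmc = ScreenConfig(
        target_samples=["Stamen_1", "Stamen_2"],
        comparator_samples=["Leaf", "Root", "Flower", "Ovule_1", "Ovule_2",
                            "Ovule_7", "Stamen_6"],
    )
    mmc_genes = preferential_screen(expr, mmc).tier1_genes
    pmc_genes = preferential_screen(expr, pmc).tier1_genes
    assert mmc_genes == truth.preferential_gene_ids
    assert mmc_genes.isdisjoint(pmc_genes)
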