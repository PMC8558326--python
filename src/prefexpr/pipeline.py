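"""End-to-end pipeline: counts → FPKM → two-tier screen → DE consensus → enrichment.

``run_pipeline`` sequences the tested stages on either supplied files
or a freshly simulated experiment, writes every artifact as TSV/plain
text, and records a deterministic JSON manifest of the thresholds
applied and the SHA-256 of every output, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .de import ConsensusConfig, consensus_deg, simple_de
from .enrich import fisher_enrich
from .expression import compute_fpkm
from .screen import ScreenConfig, preferential_screen, refine_specific
from .simulate import SimulationConfig, simulate_experiment

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("prefexpr")


@dataclass
class PipelineConfig:
    """Paths, sample roles and thresholds of a full pipeline run."""

    outdir: str | Path = "prefexpr_out"
    # either provide counts+lengths files...
    counts_path: str | Path | None = None
    lengths_path: str | Path | None = None
    libsizes_path: str | Path | None = None
    design_path: str | Path | None = None
    gmt_path: str | Path | None = None
    # ...or simulate
    simulate: SimulationConfig | None = None
    target_samples: list[str] = field(default_factory=list)
    comparator_samples: list[str] = field(default_factory=list)
    developing_samples: list[str] = field(default_factory=list)
    min_fpkm: float = 1.0
    fold: float = 2.0
    aggregation_mode: str = "strict"
    lfc_threshold: float = 2.0
    q_threshold: float = 0.05
    p_cutoff: float = 1e-5
    fdr_level: float = 0.05
    run_de: bool = True
    intersect_consensus: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None:
            if self.counts_path is None or self.lengths_path is None:
                raise ValueError("provide counts/lengths paths or a simulate config")
            for p in (self.counts_path, self.lengths_path, self.design_path, self.gmt_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(str(p))
        roles = (
            set(self.target_samples),
            set(self.comparator_samples),
            set(self.developing_samples),
        )
        if roles[0] & roles[1] or roles[0] & roles[2] or roles[1] & roles[2]:
            raise ValueError("pipeline sample roles must be disjoint")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full screen pipeline; returns the manifest dict.

    Stage order: load/simulate counts → FPKM → tier-1 screen → tier-2
    refinement → (optional) dual DE + consensus → (optional) enrichment
    of the tier-1 and tier-2 lists.  Any stage failure aborts with a
    stage-labelled error.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("input")
        if config.simulate is not None:
            sim = config.simulate
            counts, truth = simulate_experiment(sim)
            truth_df = truth.mean_fpkm.copy()
            truth_df["label"] = truth.labels
            truth_df.index.name = "gene_id"
            truth_df.to_csv(outdir / "truth.tsv", sep="\t")
            artifacts["truth"] = outdir / "truth.tsv"
            design = {s: g for s, g in sim.expanded_design()}
            if not config.target_samples:
                config.target_samples = [
                    s for s, g in sim.expanded_design() if g in sim.target_groups
                ]
                config.comparator_samples = [
                    s for s, g in sim.expanded_design() if g in sim.comparator_groups
                ]
                config.developing_samples = [
                    s for s, g in sim.expanded_design() if g in sim.developing_groups
                ]
            pio.write_counts(counts, outdir / "counts.tsv", outdir / "lengths.tsv")
            artifacts["counts"] = outdir / "counts.tsv"
            artifacts["lengths"] = outdir / "lengths.tsv"
        else:
            counts = pio.read_counts(
                config.counts_path, config.lengths_path, config.libsizes_path
            )
            design = pio.read_design(config.design_path) if config.design_path else {}
    except Exception as e:  # noqa: BLE001 - relabel with stage name
        raise RuntimeError(f"[input] {e}") from e

    try:
        stage("fpkm")
        expr = compute_fpkm(counts)
        pio.write_expression(expr, outdir / "fpkm.tsv")
        artifacts["fpkm"] = outdir / "fpkm.tsv"
    except Exception as e:
        raise RuntimeError(f"[fpkm] {e}") from e

    try:
        stage("screen")
        sconf = ScreenConfig(
            target_samples=config.target_samples,
            comparator_samples=config.comparator_samples,
            developing_samples=config.developing_samples,
            min_fpkm=config.min_fpkm,
            fold=config.fold,
            aggregation_mode=config.aggregation_mode,
        )
        result = preferential_screen(expr, sconf)
        if config.developing_samples:
            result = refine_specific(result, expr, sconf)
        pio.write_gene_list(result.tier1_genes, outdir / "tier1_preferential.txt")
        pio.write_gene_list(result.tier2_genes, outdir / "tier2_specific.txt")
        result.audit.to_csv(outdir / "screen_audit.tsv", sep="\t")
        artifacts["tier1"] = outdir / "tier1_preferential.txt"
        artifacts["tier2"] = outdir / "tier2_specific.txt"
        artifacts["audit"] = outdir / "screen_audit.tsv"
    except Exception as e:
        raise RuntimeError(f"[screen] {e}") from e

    consensus: set[str] | None = None
    if config.run_de and config.comparator_samples:
        try:
            stage("de")
            # two caller settings: replicate-estimated NB vs Poisson variance
            de_a = simple_de(
                counts, config.target_samples, config.comparator_samples,
                dispersion="auto", method_label="nb_score",
            )
            de_b = simple_de(
                counts, config.target_samples, config.comparator_samples,
                dispersion=0.0, method_label="poisson_score",
            )
            pio.write_de_table(de_a, outdir / "de_a.tsv")
            pio.write_de_table(de_b, outdir / "de_b.tsv")
            consensus = consensus_deg(
                de_a, de_b,
                ConsensusConfig(config.lfc_threshold, config.q_threshold),
            )
            pio.write_gene_list(consensus, outdir / "consensus_deg.txt")
            artifacts["de_a"] = outdir / "de_a.tsv"
            artifacts["de_b"] = outdir / "de_b.tsv"
            artifacts["consensus"] = outdir / "consensus_deg.txt"
            if config.intersect_consensus:
                inter = result.tier1_genes & consensus
                pio.write_gene_list(inter, outdir / "tier1_x_consensus.txt")
                artifacts["tier1_x_consensus"] = outdir / "tier1_x_consensus.txt"
        except Exception as e:
            raise RuntimeError(f"[de] {e}") from e

    if config.gmt_path is not None:
        try:
            stage("enrich")
            terms = pio.read_gmt(config.gmt_path)
            annotated = set().union(*terms.values())
            universe = annotated & set(expr.gene_ids)
            for tier, genes in (("tier1", result.tier1_genes), ("tier2", result.tier2_genes)):
                sel = genes & universe
                if not sel:
                    continue
                table = fisher_enrich(
                    sel, universe, terms,
                    p_cutoff=config.p_cutoff, fdr_level=config.fdr_level,
                )
                table.to_csv(outdir / f"enrichment_{tier}.tsv", sep="\t")
                artifacts[f"enrichment_{tier}"] = outdir / f"enrichment_{tier}.tsv"
        except Exception as e:
            raise RuntimeError(f"[enrich] {e}") from e

    manifest = {
        "thresholds": {
            "min_fpkm": config.min_fpkm,
            "fold": config.fold,
            "aggregation_mode": config.aggregation_mode,
            "lfc_threshold": config.lfc_threshold,
            "q_threshold": config.q_threshold,
            "p_cutoff": config.p_cutoff,
            "fdr_level": config.fdr_level,
        },
        "seed": config.seed,
        "n_tier1": len(result.tier1_genes),
        "n_tier2": len(result.tier2_genes),
        "n_consensus": None if consensus is None else len(consensus),
        "design": design,
        "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    log.info(
        "pipeline done: %d tier-1, %d tier-2 genes",
        len(result.tier1_genes), len(result.tier2_genes),
    )
    return manifest
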