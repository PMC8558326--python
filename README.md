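# prefexpr

Stage-preferential gene-expression screening for plant reproductive
transcriptomics.

## The problem

Germline specification in flowering plants — the differentiation of the
megaspore mother cell (MMC) in the ovule and the pollen mother cell (PMC)
in the anther — involves a small number of cells buried inside developing
floral organs. A practical way to find candidate regulators from bulk
RNA-seq is a *stage-preferential expression screen*: compare the
transcriptome of the stage of interest against a panel of other tissues
and stages, and keep the genes that are both expressed and strongly
elevated at that stage.

`prefexpr` implements this screen and the analysis stages around it as a
tested, reusable pipeline:

* **Two-tier FPKM screen** (the core). A gene is *preferentially
  expressed* at the target stage if its FPKM exceeds 1 in the target
  samples and is at least 2× the FPKM of **every** comparator sample
  (leaf, root, mature flower, the opposite organ, mature stages). It is
  *specifically expressed* if its target FPKM is additionally at least
  2× every developing-stage sample. Both the per-sample ("strict") and
  target-mean ("mean") readings of the fold rule are available, with a
  full per-gene audit trail of which rule failed.
* **FPKM normalisation** — FPKM[g,s] = counts[g,s]·10⁹ / (libsize[s]·length[g]).
* **Dual-caller DE consensus** — genes with |log₂ fold change| ≥ 2 and
  adjusted p ≤ 0.05 in *both* of two differential-expression tables
  (any external callers, or the built-in two-group NB/Poisson score test).
* **Term enrichment** — one-sided hypergeometric (Fisher) test per
  GO/KEGG-style term with Benjamini–Yekutieli (FDR under dependence) and
  Benjamini–Hochberg adjustments, GMT input.
* **Nearest-homolog assignment** — p-distance + Saitou–Nei
  neighbor-joining over candidate hits; the homolog is the leaf with the
  smallest patristic distance to the query.
* **qPCR quantification** — the Livak 2^−ΔΔCT method with replicate
  handling and a reference gene (Tubulin, `Aco023422`, by default).
* **Morphometric staging** — an embedded 12-stage floral-bud timeline
  (width × height, then petal length) mapping bud measurements to ovule
  and anther germline events.
* **Synthetic data with planted truth** — a negative-binomial simulator
  of the full multi-tissue sample panel whose planted preferential /
  specific gene sets are recoverable by construction, so every stage of
  the pipeline can be validated end-to-end.

## Worked example

```python
from prefexpr import (
    ScreenConfig, SimulationConfig, compute_fpkm,
    preferential_screen, refine_specific, simulate_experiment,
)

sim = SimulationConfig(n_genes=1000, n_planted_preferential=50,
                       n_planted_specific=20, planted_fold=4.0,
                       dispersion=0.05, seed=42)
counts, truth = simulate_experiment(sim)
expr = compute_fpkm(counts)

cfg = ScreenConfig(
    target_samples=["Ovule_1", "Ovule_2"],          # MMC-stage ovules
    comparator_samples=["Leaf", "Root", "Flower", "Stamen_1",
                        "Stamen_2", "Stamen_6", "Ovule_7"],
    developing_samples=["Ovule_3", "Ovule_4", "Ovule_5", "Ovule_6"],
    aggregation_mode="mean",
)
result = refine_specific(preferential_screen(expr, cfg), expr, cfg)
print(f"tier 1 (preferential): {len(result.tier1_genes)} genes")
print(f"tier 2 (specific):     {len(result.tier2_genes)} genes")
print(f"planted preferential recovered: "
      f"{len(result.tier1_genes & truth.preferential_gene_ids)}/50")
print(f"planted specific recovered:     "
      f"{len(result.tier2_genes & truth.specific_gene_ids)}/20")
```

prints

```
tier 1 (preferential): 51 genes
tier 2 (specific):     19 genes
planted preferential recovered: 47/50
planted specific recovered:     19/20
```

i.e. at dispersion 0.05 the screen recalls 47 of the 50 genes planted as
MMC-preferential (and 19 of 20 planted as MMC-specific) while picking up
4 background genes; with `dispersion=0` recovery is exact. The
`result.audit` table reports, for every gene, which rule it failed and
against which sample:

```
           tier1          tier1_fail_reason  tier2 tier2_fail_reason
gene_id
gene00000   True                       pass   True              pass
gene00055  False  insufficient-fold vs Leaf  False     not in tier 1
```

The same pipeline is available from the shell:

```bash
prefexpr simulate --outdir sim --seed 42
prefexpr fpkm --counts sim/counts.tsv --lengths sim/lengths.tsv --out fpkm.tsv
prefexpr screen --expr fpkm.tsv --design sim/design.tsv \
    --role-target Ovule_1,Ovule_2 \
    --role-comparator Leaf,Root,Flower,Stamen_1,Stamen_2,Stamen_6,Ovule_7 \
    --role-developing Ovule_3,Ovule_4,Ovule_5,Ovule_6 \
    --outdir screen_out
prefexpr stage --width 5 --height 4
```

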