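"""Synthetic multi-tissue RNA-seq experiments with planted signal.

The generator emulates the sample panel of a bulk RNA-seq survey of
pineapple reproductive development: two early-ovule libraries in which
the megaspore-mother-cell (MMC) stage signal is planted (``Ovule_1``,
``Ovule_2``), a panel of comparator tissues (leaf, root, mature flower,
early/mature stamen, mature ovule) and four developing-ovule libraries
(``Ovule_3``..``Ovule_6``) used by the tier-2 specificity filter.

True expression is specified in FPKM per sample group; counts are then
obtained by inverting the FPKM formula for each library and perturbing
with a negative-binomial observation model
(variance = mu + dispersion * mu^2).  Stating truth in FPKM keeps it in
the same units as the downstream screen, and makes the planted gene sets
exactly recoverable when dispersion is zero.

Background genes are made non-preferential by explicit rule violation
(low target expression, a flat profile, or a comparator within
fold/1.2 of the target) rather than by chance, so truth labels are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "DEFAULT_SAMPLE_DESIGN",
    "SimulationConfig",
    "PlantedTruth",
    "simulate_experiment",
    "simulate_annotation",
]

#: One library per developmental stage / tissue, as in the emulated survey.
#: Pairs of (sample_name, group_label); the default uses the group label as
#: the sample name.
DEFAULT_SAMPLE_DESIGN: tuple[tuple[str, str], ...] = tuple(
    (name, name)
    for name in (
        "Ovule_1",
        "Ovule_2",
        "Ovule_3",
        "Ovule_4",
        "Ovule_5",
        "Ovule_6",
        "Ovule_7",
        "Stamen_1",
        "Stamen_2",
        "Stamen_6",
        "Leaf",
        "Root",
        "Flower",
    )
)

DEFAULT_TARGET_GROUPS = ("Ovule_1", "Ovule_2")
DEFAULT_COMPARATOR_GROUPS = (
    "Leaf",
    "Root",
    "Flower",
    "Stamen_1",
    "Stamen_2",
    "Stamen_6",
    "Ovule_7",
)
DEFAULT_DEVELOPING_GROUPS = ("Ovule_3", "Ovule_4", "Ovule_5", "Ovule_6")

_BACKGROUND_CLASSES = ("flat", "low", "near")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic stage-preferential expression experiment.

    Attributes
    ----------
    n_genes
        Total genes simulated (planted + background).
    sample_design
        ``(sample_name, group_label)`` pairs; one library per group by
        default.  Set ``n_replicates`` > 1 to expand each entry into
        ``<name>_r1`` .. ``<name>_rK`` replicate libraries.
    target_groups, comparator_groups, developing_groups
        Group labels playing the three screening roles.
    n_planted_preferential
        Genes planted to satisfy the tier-1 (preferential) rules.
    n_planted_specific
        Subset of the preferential genes additionally satisfying the
        tier-2 (specific) rule against the developing groups.
    planted_fold
        True FPKM ratio of target over comparator groups for planted
        genes (unitless, >= the downstream screen fold).
    baseline_mean
        Expected FPKM of background genes (and of comparator groups for
        planted genes).
    dispersion
        Negative-binomial dispersion; variance = mu + dispersion * mu^2.
        Zero gives deterministic (rounded-mean) counts.
    library_size_range, gene_length_range
        Uniform ranges for per-library mapped reads and gene length (bp).
    screen_fold
        Fold threshold the downstream screen will use; configs whose
        ``planted_fold`` falls below it are rejected because the planted
        truth would be unrecoverable.
    """

    n_genes: int = 2000
    sample_design: Sequence[tuple[str, str]] = DEFAULT_SAMPLE_DESIGN
    target_groups: Sequence[str] = DEFAULT_TARGET_GROUPS
    comparator_groups: Sequence[str] = DEFAULT_COMPARATOR_GROUPS
    developing_groups: Sequence[str] = DEFAULT_DEVELOPING_GROUPS
    n_planted_preferential: int = 50
    n_planted_specific: int = 20
    planted_fold: float = 4.0
    baseline_mean: float = 20.0
    dispersion: float = 0.05
    library_size_range: tuple[int, int] = (20_000_000, 30_000_000)
    gene_length_range: tuple[int, int] = (500, 3000)
    n_replicates: int = 1
    screen_fold: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (
            0 <= self.n_planted_specific <= self.n_planted_preferential <= self.n_genes
        ):
            raise ValueError(
                "need n_planted_specific <= n_planted_preferential <= n_genes"
            )
        if self.planted_fold < self.screen_fold:
            raise ValueError(
                "planted_fold below the downstream screen fold threshold: "
                "the planted truth would be unrecoverable"
            )
        if self.planted_fold < 2:
            raise ValueError("planted_fold must be >= 2")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        names = [s for s, _ in self.sample_design]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        groups = {g for _, g in self.sample_design}
        roles = (
            set(self.target_groups),
            set(self.comparator_groups),
            set(self.developing_groups),
        )
        for role in roles:
            missing = role - groups
            if missing:
                raise ValueError(f"role groups absent from sample_design: {missing}")
        if roles[0] & roles[1] or roles[0] & roles[2] or roles[1] & roles[2]:
            raise ValueError("target/comparator/developing groups must be disjoint")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid library_size_range")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid gene_length_range")

    def expanded_design(self) -> list[tuple[str, str]]:
        """Sample design after replicate expansion."""
        if self.n_replicates == 1:
            return list(self.sample_design)
        return [
            (f"{name}_r{k}", group)
            for name, group in self.sample_design
            for k in range(1, self.n_replicates + 1)
        ]


@dataclass
class PlantedTruth:
    """Ground truth of a simulated experiment.

    ``mean_fpkm`` is the true per-gene mean FPKM by sample *group*;
    ``labels`` records each gene's construction class (``specific``,
    ``preferential``, or a background class).
    """

    preferential_gene_ids: set[str]
    specific_gene_ids: set[str]
    mean_fpkm: pd.DataFrame
    labels: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.specific_gene_ids <= self.preferential_gene_ids:
            raise ValueError("specific genes must be a subset of preferential genes")
        missing = (self.preferential_gene_ids | self.specific_gene_ids) - set(
            self.mean_fpkm.index
        )
        if missing:
            raise ValueError(f"truth table does not cover genes: {sorted(missing)[:5]}")


def _true_mean_table(config: SimulationConfig, gene_ids: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    groups = list(dict.fromkeys(g for _, g in config.sample_design))
    mean = pd.DataFrame(
        config.baseline_mean, index=gene_ids, columns=groups, dtype=float
    )
    labels = pd.Series("flat", index=gene_ids, dtype=object)

    n_spec = config.n_planted_specific
    n_pref = config.n_planted_preferential
    target_fpkm = config.baseline_mean * config.planted_fold

    spec_ids = gene_ids[:n_spec]
    pref_only_ids = gene_ids[n_spec:n_pref]
    background_ids = gene_ids[n_pref:]

    # specific: high in targets, baseline everywhere else (incl. developing)
    mean.loc[spec_ids, list(config.target_groups)] = target_fpkm
    labels.loc[spec_ids] = "specific"
    # preferential-only: high in targets AND developing -> fails tier 2
    mean.loc[pref_only_ids, list(config.target_groups)] = target_fpkm
    mean.loc[pref_only_ids, list(config.developing_groups)] = target_fpkm
    labels.loc[pref_only_ids] = "preferential"

    # background classes cycle; each violates a tier-1 rule by construction
    for i, gid in enumerate(background_ids):
        cls = _BACKGROUND_CLASSES[i % len(_BACKGROUND_CLASSES)]
        labels.loc[gid] = cls
        if cls == "low":
            # fails the FPKM > 1 rule in the target samples
            mean.loc[gid, list(config.target_groups)] = 0.5
        elif cls == "near":
            # target elevated, but a comparator sits within fold/1.2 of it
            mean.loc[gid, list(config.target_groups)] = (
                config.baseline_mean * config.screen_fold / 1.2
            )
        # "flat": all groups at baseline; every comparator ties the target
    return mean, labels


def simulate_experiment(config: SimulationConfig) -> tuple[CountMatrix, PlantedTruth]:
    """Draw a synthetic count matrix with planted preferential genes.

    Returns the counts (with the nominal library sizes and gene lengths
    attached) and the :class:`PlantedTruth` describing which genes were
    planted and their true group-level mean FPKM.  Fully deterministic
    for a fixed config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    design = config.expanded_design()
    sample_names = [s for s, _ in design]
    sample_groups = [g for _, g in design]

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes
    )
    lib_sizes = rng.integers(
        config.library_size_range[0],
        config.library_size_range[1] + 1,
        size=len(design),
    )

    mean_fpkm, labels = _true_mean_table(config, gene_ids)
    # invert the FPKM formula per library to get expected counts
    mu = (
        mean_fpkm[sample_groups].to_numpy()
        * lib_sizes[None, :]
        * lengths[:, None]
        / 1e9
    )
    if config.dispersion == 0:
        counts = np.rint(mu).astype(np.int64)
    else:
        shape = 1.0 / config.dispersion
        p = shape / (shape + mu)
        counts = rng.negative_binomial(shape, p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_names),
        gene_lengths=pd.Series(lengths, index=gene_ids),
        library_sizes=pd.Series(lib_sizes.astype(float), index=sample_names),
    )
    n_pref = config.n_planted_preferential
    truth = PlantedTruth(
        preferential_gene_ids=set(gene_ids[:n_pref]),
        specific_gene_ids=set(gene_ids[: config.n_planted_specific]),
        mean_fpkm=mean_fpkm,
        labels=labels,
    )
    return cm, truth


def simulate_annotation(
    genes: int | Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    enriched_term: tuple[str, Iterable[str], float] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random GMT-style term sets over a gene universe.

    ``genes`` is either a gene-id list or a count (ids are generated).
    Term sizes are uniform in ``term_size_range``.  If ``enriched_term``
    is given as ``(term_id, favored_gene_ids, odds_ratio)``, that term's
    members are drawn with sampling weight ``odds_ratio`` for the favored
    genes and 1 for the rest, planting a known over-representation.
    """
    if isinstance(genes, int):
        universe = [f"gene{i:05d}" for i in range(genes)]
    else:
        universe = list(genes)
    if not universe:
        raise ValueError("empty gene universe")
    lo, hi = term_size_range
    if lo <= 0 or hi < lo:
        raise ValueError("term sizes must be positive")
    if hi > len(universe):
        raise ValueError("term sizes exceed the gene universe")
    rng = np.random.default_rng(seed)
    arr = np.asarray(universe, dtype=object)
    terms: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(arr, size=size, replace=False)
        terms[f"TERM:{t:04d}"] = set(members.tolist())
    if enriched_term is not None:
        term_id, favored, odds_ratio = enriched_term
        favored = set(favored) & set(universe)
        if odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        w = np.array([odds_ratio if g in favored else 1.0 for g in universe])
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(arr, size=size, replace=False, p=w / w.sum())
        terms[term_id] = set(members.tolist())
    return terms
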