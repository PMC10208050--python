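"""Recovery and calibration studies against the simulator's planted truth.

These routines run the real pipeline stages on synthetic data and score
them against the ground truth: sensitivity and false-discovery proportion
of the DE stage, uniformity of null p-values, hub-lncRNA recovery in the
ceRNA network, and planted gene-set recovery. They are the quantitative
backbone of the test suite and of ``scripts/acceptance.py``.

All helpers accept a base seed and derive per-replicate seeds from it, so
a whole study is reproducible from one integer.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from . import de as de_mod
from . import enrichment as enr_mod
from . import interactions as int_mod
from . import network as net_mod
from .expression import collapse_probes, log2_transform
from .synthetic import (
    SynthConfig,
    generate_expression_dataset,
    generate_gene_set_library,
    generate_interaction_tables,
)

#: The reference DE regime: 10% planted effects of 2.0 log2-units against
#: noise_sd 0.5 with 20 samples per group.
DE_STUDY_CONFIG = SynthConfig(
    n_genes=1000,
    frac_lncrna=0.05,
    probes_per_gene=1,
    n_samples_per_group=20,
    n_de_mrna=95,
    n_de_lncrna=5,
    effect_size=2.0,
    noise_sd=0.5,
    n_hub_lncrnas=3,
    hub_degree=10,
)


def _seed(base: int, i: int) -> int:
    # keep derived seeds in the signed 32-bit range
    return (base * 100003 + i) % (2**31 - 1)


def gene_level_log2(config: SynthConfig):
    """Generate a dataset and return (gene-level log2 matrix, truth)."""
    mat, annot, truth = generate_expression_dataset(config)
    mat = log2_transform(mat, offset=0.0)  # exact inverse of the simulator's 2**x
    mat = collapse_probes(mat, annot)
    return mat, annot, truth


def de_recovery(
    config: SynthConfig = DE_STUDY_CONFIG,
    n_seeds: int = 50,
    base_seed: int = 0,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> dict[str, float]:
    """Mean sensitivity and false-discovery proportion of the DE stage.

    FDP is scored on the FDR rule alone (q < fdr_max), the quantity BH
    controls; sensitivity is scored on the full reporting rule
    (|logFC| > lfc_min and q < fdr_max).
    """
    sens, fdp = [], []
    for i in range(n_seeds):
        cfg = dataclasses.replace(config, seed=_seed(base_seed, i))
        mat, _annot, truth = gene_level_log2(cfg)
        table = de_mod.differential_expression(mat, "day0", "day8")
        truth_set = set(truth.de_genes)
        discoveries = set(table.index[table["q"] < fdr_max])
        if discoveries:
            fdp.append(len(discoveries - truth_set) / len(discoveries))
        else:
            fdp.append(0.0)
        passed, _, _ = de_mod.apply_thresholds(table, lfc_min, fdr_max)
        reported = set(passed.index[passed["passed"]])
        sens.append(len(reported & truth_set) / len(truth_set))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_discovery_proportion": float(np.mean(fdp)),
        "n_seeds": n_seeds,
    }


def null_pvalue_ks(n_genes: int = 5000, n_per_group: int = 20, base_seed: int = 0) -> float:
    """KS test p-value for uniformity of DE p-values with nothing planted."""
    cfg = SynthConfig(
        n_genes=n_genes,
        frac_lncrna=0.05,
        probes_per_gene=1,
        n_samples_per_group=n_per_group,
        n_de_mrna=0,
        n_de_lncrna=0,
        n_hub_lncrnas=0,
        seed=_seed(base_seed, 777),
    )
    mat, _annot, _truth = gene_level_log2(cfg)
    table = de_mod.differential_expression(mat, "day0", "day8")
    return float(stats.kstest(table["p"].to_numpy(), "uniform").pvalue)


def null_enrichment_fraction(
    n_seeds: int = 20,
    n_sets: int = 200,
    set_size: tuple[int, int] = (40, 120),
    query_size: int = 200,
    base_seed: int = 0,
) -> float:
    """Fraction of gene sets with p < 0.05 for random queries (expected ~5%)."""
    fracs = []
    for i in range(n_seeds):
        cfg = SynthConfig(
            n_genes=2000,
            frac_lncrna=0.05,
            probes_per_gene=1,
            n_samples_per_group=2,
            n_de_mrna=0,
            n_de_lncrna=0,
            n_hub_lncrnas=0,
            n_gene_sets=n_sets,
            set_size_range=set_size,
            n_enriched_sets=0,
            seed=_seed(base_seed, i),
        )
        mat, annot, truth = generate_expression_dataset(cfg)
        library = generate_gene_set_library(cfg, truth, annot)
        universe = sorted(g for g in annot["gene_symbol"].unique() if g.startswith("MRNA"))
        rng = np.random.default_rng(_seed(base_seed, 10_000 + i))
        query = rng.choice(universe, size=query_size, replace=False).tolist()
        table = enr_mod.enrich(query, library, universe, fdr_threshold=0.01)
        fracs.append(float((table["p"] < 0.05).mean()))
    return float(np.mean(fracs))


def _network_from_truth(cfg: SynthConfig):
    """Build the ceRNA network for one simulated study, restricted to planted DE genes."""
    mat, annot, truth = generate_expression_dataset(cfg)
    lnc_mi, db1, db2 = generate_interaction_tables(cfg, truth, annot)
    lnc_mi = int_mod.deduplicate(
        int_mod.restrict_to_de(lnc_mi, set(truth.de_lncrnas), side="regulator")
    )
    mi_m = int_mod.intersect_databases(db1, db2)
    mi_m = int_mod.deduplicate(
        int_mod.restrict_to_de(mi_m, set(truth.de_mrnas), side="target")
    )
    return net_mod.build_cerna_network(lnc_mi, mi_m), truth


def hub_recovery(
    config: SynthConfig | None = None, n_seeds: int = 20, base_seed: int = 0
) -> float:
    """Fraction of seeds whose top-(n_hub) degree ranks are exactly the planted hubs."""
    if config is None:
        config = SynthConfig(
            n_genes=1000, frac_lncrna=0.1, probes_per_gene=1, n_samples_per_group=4,
            n_de_mrna=100, n_de_lncrna=20, n_hub_lncrnas=5, hub_degree=10,
            n_mirnas=60, bg_interaction_prob=0.02,
        )
    hits = 0
    for i in range(n_seeds):
        cfg = dataclasses.replace(config, seed=_seed(base_seed, i))
        net, truth = _network_from_truth(cfg)
        top = net_mod.rank_lncrnas(net, top_k=cfg.n_hub_lncrnas)
        if {name for name, _ in top} == set(truth.hub_lncrnas):
            hits += 1
    return hits / n_seeds


def enrichment_recovery(
    config: SynthConfig | None = None,
    n_seeds: int = 20,
    base_seed: int = 0,
    fdr_threshold: float = 0.01,
) -> float:
    """Fraction of seeds where the planted set attains the smallest q and passes."""
    if config is None:
        config = SynthConfig(
            n_genes=1000, frac_lncrna=0.05, probes_per_gene=1, n_samples_per_group=4,
            n_de_mrna=95, n_de_lncrna=5, n_hub_lncrnas=3,
            n_gene_sets=50, set_size_range=(20, 60), n_enriched_sets=1,
        )
    hits = 0
    for i in range(n_seeds):
        cfg = dataclasses.replace(config, seed=_seed(base_seed, i))
        mat, annot, truth = generate_expression_dataset(cfg)
        library = generate_gene_set_library(cfg, truth, annot)
        universe = sorted(g for g in annot["gene_symbol"].unique() if g.startswith("MRNA"))
        table = enr_mod.enrich(truth.de_mrnas, library, universe, fdr_threshold=fdr_threshold)
        top = table.iloc[0]
        (planted,) = truth.enriched_sets
        if top["set_name"] == planted and top["passed"] and top["q"] == table["q"].min():
            hits += 1
    return hits / n_seeds
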