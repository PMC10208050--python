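"""Planted-signal simulator for every input of the ceRNA pipeline.

Emulates the data regime of a two-timepoint (day0/day8) bone-marrow
microarray study: a probe-level intensity matrix over a lncRNA/mRNA
mixture with a known set of differentially expressed genes, miRcode-style
lncRNA-miRNA and two miRNA-mRNA interaction tables with planted hub
lncRNAs, a GMT gene-set library with planted enriched sets, and an
RT-qPCR Ct table whose 2^-dCt recovers planted fold changes. The planted
structure (``GroundTruth``) is the recovery surface for every downstream
stage, standing in for raw data that cannot ship with the package.

Noise is Gaussian on the log2 scale; the emitted expression matrix is
linear-scale (2**x) so the preprocessing chain (filter, quantile
normalization, log2) is exercised end to end. All randomness derives from
``SynthConfig.seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .interactions import InteractionTable

_CHROMS = [str(i) for i in range(1, 23)] + ["X"]


@dataclass
class SynthConfig:
    """Parameters of the simulated study.

    Defaults describe the reference condition used throughout the test
    suite: 2000 genes of which 5% are lncRNAs (the approximate lncRNA share
    of an hgu133Plus2-style array after filtering), 20 samples per
    timepoint, planted log2 effects of 2.0 against residual noise of 0.5,
    60 miRNAs, 6 hub lncRNAs of degree 10 over a 0.02 background
    interaction rate, and a 50-set library with 5 planted enriched sets.
    """

    n_genes: int = 2000
    frac_lncrna: float = 0.05
    probes_per_gene: int | tuple[int, int] = 2
    n_samples_per_group: int = 20
    n_de_mrna: int = 180
    n_de_lncrna: int = 10
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    n_mirnas: int = 60
    n_hub_lncrnas: int = 6
    hub_degree: int = 10
    bg_interaction_prob: float = 0.02
    db_overlap_frac: float = 0.3
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (20, 60)
    n_enriched_sets: int = 5
    seed: int = 0

    @property
    def n_lncrna(self) -> int:
        return int(round(self.frac_lncrna * self.n_genes))

    @property
    def n_mrna(self) -> int:
        return self.n_genes - self.n_lncrna

    def validate(self) -> None:
        """Raise ValueError naming the first violated bound."""
        if not 0 < self.frac_lncrna < 1:
            raise ValueError(f"frac_lncrna must be in (0,1), got {self.frac_lncrna}")
        for name in ("bg_interaction_prob", "db_overlap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_de_mrna > self.n_mrna:
            raise ValueError(f"n_de_mrna={self.n_de_mrna} exceeds mRNA count {self.n_mrna}")
        if self.n_de_lncrna > self.n_lncrna:
            raise ValueError(f"n_de_lncrna={self.n_de_lncrna} exceeds lncRNA count {self.n_lncrna}")
        if self.n_hub_lncrnas > self.n_de_lncrna:
            raise ValueError(
                f"n_hub_lncrnas={self.n_hub_lncrnas} exceeds n_de_lncrna={self.n_de_lncrna}"
            )
        if self.hub_degree > self.n_mirnas:
            raise ValueError(f"hub_degree={self.hub_degree} exceeds n_mirnas={self.n_mirnas}")
        if isinstance(self.probes_per_gene, tuple):
            lo, hi = self.probes_per_gene
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid probes_per_gene range {self.probes_per_gene}")
        elif self.probes_per_gene < 1:
            raise ValueError(f"probes_per_gene must be >= 1, got {self.probes_per_gene}")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid set_size_range {self.set_size_range}")
        if hi > self.n_mrna:
            raise ValueError(f"set_size_range max {hi} exceeds mRNA universe size {self.n_mrna}")
        if self.noise_sd < 0 or self.n_samples_per_group < 2:
            raise ValueError("need noise_sd >= 0 and n_samples_per_group >= 2")


@dataclass
class GroundTruth:
    """What the generators planted: the downstream recovery surface."""

    de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    hub_lncrnas: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)
    lnc_mi_pairs: list[tuple[str, str]] = field(default_factory=list)
    mi_m_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def de_mrnas(self) -> list[str]:
        return sorted(g for g in self.de_genes if g.startswith("MRNA"))

    @property
    def de_lncrnas(self) -> list[str]:
        return sorted(g for g in self.de_genes if g.startswith("LNC"))

    def to_json(self, path) -> None:
        payload = {
            "de_genes": {g: list(v) for g, v in self.de_genes.items()},
            "hub_lncrnas": self.hub_lncrnas,
            "enriched_sets": self.enriched_sets,
            "lnc_mi_pairs": [list(p) for p in self.lnc_mi_pairs],
            "mi_m_pairs": [list(p) for p in self.mi_m_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_genes={g: (d, float(f)) for g, (d, f) in payload["de_genes"].items()},
            hub_lncrnas=payload["hub_lncrnas"],
            enriched_sets=payload["enriched_sets"],
            lnc_mi_pairs=[tuple(p) for p in payload["lnc_mi_pairs"]],
            mi_m_pairs=[tuple(p) for p in payload["mi_m_pairs"]],
        )


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent stream per generator so call order cannot matter
    return np.random.default_rng([config.seed, stream])


def gene_symbols(config: SynthConfig) -> tuple[list[str], list[str]]:
    mrnas = [f"MRNA{i:04d}" for i in range(1, config.n_mrna + 1)]
    lncs = [f"LNC{i:04d}" for i in range(1, config.n_lncrna + 1)]
    return mrnas, lncs


def mirna_names(config: SynthConfig) -> list[str]:
    return [f"MIR{i:04d}" for i in range(1, config.n_mirnas + 1)]


def generate_expression_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Probe-level linear-scale matrix, probe annotation, and ground truth.

    Planted DE genes get a ±effect_size shift of the day8 group mean on the
    log2 scale; all probes of a gene share its group mean; per-probe,
    per-sample Gaussian noise of sd noise_sd on the log2 scale.
    """
    config.validate()
    rng = _rng(config, 1)
    mrnas, lncs = gene_symbols(config)
    genes = mrnas + lncs

    de_mrna = sorted(rng.choice(mrnas, size=config.n_de_mrna, replace=False).tolist())
    de_lnc = sorted(rng.choice(lncs, size=config.n_de_lncrna, replace=False).tolist())
    truth = GroundTruth()
    for g in de_mrna + de_lnc:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.de_genes[g] = ("up" if sign > 0 else "down", sign * config.effect_size)
    truth.hub_lncrnas = sorted(
        rng.choice(de_lnc, size=config.n_hub_lncrnas, replace=False).tolist()
    )

    if isinstance(config.probes_per_gene, tuple):
        lo, hi = config.probes_per_gene
        n_probes = rng.integers(lo, hi + 1, size=len(genes))
    else:
        n_probes = np.full(len(genes), config.probes_per_gene)

    n = config.n_samples_per_group
    samples = [f"D0_{i:03d}" for i in range(1, n + 1)] + [f"D8_{i:03d}" for i in range(1, n + 1)]
    groups = {s: ("day0" if s.startswith("D0") else "day8") for s in samples}

    probe_ids, annot_rows, mean_rows = [], [], []
    for gi, gene in enumerate(genes):
        biotype = "mRNA" if gene.startswith("MRNA") else "lncRNA"
        shift = truth.de_genes.get(gene, (None, 0.0))[1]
        m0 = config.baseline_mean
        m8 = config.baseline_mean + shift
        chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
        arm = "p" if rng.random() < 0.5 else "q"
        band = f"{chrom}{arm}{int(rng.integers(11, 35))}"
        start = int(rng.integers(10_000, 100_000_000))
        end = start + int(rng.integers(500, 200_000))
        for j in range(int(n_probes[gi])):
            pid = f"{gene}_P{j + 1}"
            probe_ids.append(pid)
            annot_rows.append((pid, gene, biotype, band, start, end))
            mean_rows.append((m0, m8))
    means = np.asarray(mean_rows)  # (n_probes_total, 2)
    log2_vals = np.repeat(means, [n, n], axis=1)
    log2_vals = log2_vals + rng.normal(0.0, config.noise_sd, size=log2_vals.shape)
    values = pd.DataFrame(np.exp2(log2_vals), index=probe_ids, columns=samples)

    annot = pd.DataFrame(
        annot_rows,
        columns=["probe_id", "gene_symbol", "biotype", "chromosome_band", "start", "end"],
    ).set_index("probe_id")
    mat = ExpressionMatrix(values=values, sample_groups=groups, scale="linear", level="probe")
    return mat, annot, truth


def generate_interaction_tables(
    config: SynthConfig, truth: GroundTruth, annot: pd.DataFrame
) -> tuple[InteractionTable, InteractionTable, InteractionTable]:
    """lncRNA-miRNA table plus two miRNA-mRNA tables with planted hubs.

    Each planted hub lncRNA gets exactly ``hub_degree`` distinct miRNA
    partners; every such miRNA targets at least one planted DE mRNA in BOTH
    target databases (so hubs survive the validated-by-both rule by
    construction). Background pairs are Bernoulli(bg_interaction_prob);
    background miRNA-mRNA pairs land in both databases with probability
    ``db_overlap_frac``, otherwise in exactly one.
    """
    config.validate()
    if config.n_mirnas < config.hub_degree:
        raise ValueError(f"n_mirnas={config.n_mirnas} < hub_degree={config.hub_degree}")
    rng = _rng(config, 2)
    mirnas = mirna_names(config)
    genes = annot["gene_symbol"].unique()
    lncs = sorted(g for g in genes if g.startswith("LNC"))
    mrnas = sorted(g for g in genes if g.startswith("MRNA"))
    de_mrnas = truth.de_mrnas

    lnc_mi: list[tuple[str, str]] = []
    hub_mirnas: list[str] = []
    for hub in truth.hub_lncrnas:
        partners = sorted(rng.choice(mirnas, size=config.hub_degree, replace=False).tolist())
        lnc_mi.extend((hub, m) for m in partners)
        hub_mirnas.extend(m for m in partners if m not in hub_mirnas)

    db1: list[tuple[str, str]] = []
    db2: list[tuple[str, str]] = []
    planted_mi_m: set[tuple[str, str]] = set()
    if de_mrnas:
        for m in hub_mirnas:
            n_targets = int(rng.integers(5, 16))
            n_targets = min(n_targets, len(de_mrnas))
            targets = sorted(rng.choice(de_mrnas, size=n_targets, replace=False).tolist())
            for g in targets:
                planted_mi_m.add((m, g))
                db1.append((m, g))
                db2.append((m, g))

    # background lncRNA-miRNA pairs; hubs keep exactly hub_degree partners
    hub_set = set(truth.hub_lncrnas)
    mask = rng.random((len(lncs), len(mirnas))) < config.bg_interaction_prob
    for i, j in zip(*np.nonzero(mask)):
        if lncs[i] not in hub_set:
            lnc_mi.append((lncs[i], mirnas[j]))

    # background miRNA-mRNA pairs with partial database overlap
    mask = rng.random((len(mirnas), len(mrnas))) < config.bg_interaction_prob
    for i, j in zip(*np.nonzero(mask)):
        pair = (mirnas[i], mrnas[j])
        if pair in planted_mi_m:
            continue
        u = rng.random()
        if u < config.db_overlap_frac:
            db1.append(pair)
            db2.append(pair)
        elif u < config.db_overlap_frac + (1 - config.db_overlap_frac) / 2:
            db1.append(pair)
        else:
            db2.append(pair)

    truth.lnc_mi_pairs = sorted(set(lnc_mi))
    truth.mi_m_pairs = sorted(set(db1) | set(db2))

    def table(pairs: list[tuple[str, str]], kind: str, source: str) -> InteractionTable:
        df = pd.DataFrame(pairs, columns=["regulator", "target"]).drop_duplicates()
        df["source_db"] = source
        return InteractionTable(df=df.reset_index(drop=True), kind=kind)

    return (
        table(lnc_mi, "lncRNA-miRNA", "mircode"),
        table(db1, "miRNA-mRNA", "targetscan"),
        table(db2, "miRNA-mRNA", "mirtarbase"),
    )


def generate_gene_set_library(
    config: SynthConfig, truth: GroundTruth, annot: pd.DataFrame
) -> dict[str, tuple[str, list[str]]]:
    """GMT-style library over the mRNA universe with planted enriched sets.

    Planted sets draw >= 70% of their members from the planted DE mRNAs,
    the rest uniformly from the non-DE remainder; background sets are
    uniform over the whole mRNA universe.
    """
    config.validate()
    rng = _rng(config, 3)
    universe = sorted(g for g in annot["gene_symbol"].unique() if g.startswith("MRNA"))
    de = truth.de_mrnas
    non_de = sorted(set(universe) - set(de))
    lo, hi = config.set_size_range

    names = [f"GS{i:03d}" for i in range(1, config.n_gene_sets + 1)]
    enriched = sorted(rng.choice(names, size=config.n_enriched_sets, replace=False).tolist())
    truth.enriched_sets = enriched

    library: dict[str, tuple[str, list[str]]] = {}
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        if name in enriched:
            n_from_de = int(np.ceil(0.7 * size))
            if n_from_de > len(de):
                raise ValueError(
                    f"cannot plant enriched set of size {size}: only {len(de)} DE mRNAs"
                )
            members = rng.choice(de, size=n_from_de, replace=False).tolist()
            members += rng.choice(non_de, size=size - n_from_de, replace=False).tolist()
            description = "planted_enriched"
        else:
            members = rng.choice(universe, size=size, replace=False).tolist()
            description = "background"
        library[name] = (description, sorted(members))
    return library


def generate_ct_table(
    config: SynthConfig,
    truth: GroundTruth,
    group_sizes: dict[str, int] | None = None,
    control_group: str = "control",
    reference_gene: str = "GAPDH",
    replicates: int = 3,
    ct_noise_sd: float = 0.2,
    reference_ct: float = 20.0,
    target_base_ct: float = 25.0,
) -> pd.DataFrame:
    """Triplicate Ct table for the planted hub lncRNAs plus a reference gene.

    Default cohort mirrors a small validation study: 15 controls and three
    leukemia subgroups (9 + 17 + 7 cases). Case-group target Ct is shifted
    by -logFC of the planted DE effect, so 2^-dCt recovers the planted fold
    change relative to controls.
    """
    config.validate()
    if group_sizes is None:
        group_sizes = {"control": 15, "ph_pos": 9, "ph_neg": 17, "t_all": 7}
    if control_group not in group_sizes:
        raise ValueError(f"control group {control_group!r} not in group_sizes")
    rng = _rng(config, 4)
    genes = truth.hub_lncrnas
    rows = []
    for group, size in group_sizes.items():
        for i in range(1, size + 1):
            sample = f"{group}_{i:02d}"
            for rep in range(1, replicates + 1):
                rows.append(
                    (sample, group, reference_gene, rep,
                     reference_ct + rng.normal(0.0, ct_noise_sd))
                )
            for gene in genes:
                logfc = truth.de_genes.get(gene, (None, 0.0))[1]
                mean_ct = target_base_ct - (logfc if group != control_group else 0.0)
                for rep in range(1, replicates + 1):
                    rows.append((sample, group, gene, rep, mean_ct + rng.normal(0.0, ct_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])


def write_synthetic_inputs(config: SynthConfig, outdir) -> dict[str, Path]:
    """Generate and serialize all six pipeline inputs plus the ground truth.

    Returns a dict of logical input name -> written path.
    """
    from .enrichment import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat, annot, truth = generate_expression_dataset(config)
    lnc_mi, db1, db2 = generate_interaction_tables(config, truth, annot)
    library = generate_gene_set_library(config, truth, annot)
    ct = generate_ct_table(config, truth)

    paths = {
        "expression": outdir / "expression.tsv",
        "group_map": outdir / "groups.tsv",
        "annotation": outdir / "annotation.tsv",
        "lnc_mi": outdir / "lncrna_mirna.tsv",
        "mi_m_db1": outdir / "mirna_mrna_targetscan.tsv",
        "mi_m_db2": outdir / "mirna_mrna_mirtarbase.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "ct_table": outdir / "ct_values.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    mat.write_tsv(paths["expression"])
    pd.DataFrame(
        {"sample": mat.samples, "group": [mat.sample_groups[s] for s in mat.samples]}
    ).to_csv(paths["group_map"], sep="\t", index=False)
    annot.to_csv(paths["annotation"], sep="\t", index_label="probe_id")
    lnc_mi.write_tsv(paths["lnc_mi"])
    db1.write_tsv(paths["mi_m_db1"])
    db2.write_tsv(paths["mi_m_db2"])
    write_gmt(library, paths["gene_sets"])
    ct.to_csv(paths["ct_table"], sep="\t", index=False, float_format="%.6g")
    truth.to_json(paths["ground_truth"])
    return paths


def config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from a plain dict (e.g. parsed YAML), tolerating lists for ranges."""
    kwargs = dict(d)
    for key in ("probes_per_gene", "set_size_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    unknown = set(kwargs) - set(SynthConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown synthetic-data parameters: {sorted(unknown)}")
    return SynthConfig(**kwargs)


def config_to_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    for key in ("probes_per_gene", "set_size_range"):
        if isinstance(d[key], tuple):
            d[key] = list(d[key])
    return d
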