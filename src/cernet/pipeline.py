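"""End-to-end orchestration: config, staged execution, run manifest.

A run reads six inputs (or generates them synthetically), performs
expression preprocessing, differential expression of mRNAs and lncRNAs,
database integration, ceRNA network construction with hub ranking and
per-lncRNA subnetworks, over-representation analysis, and (if a Ct table
is supplied) qPCR relative quantification. Every stage appends its row
counts to a manifest that is written even on failure, and all outputs are
deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import de as de_mod
from . import enrichment as enr_mod
from . import expression as expr_mod
from . import interactions as int_mod
from . import network as net_mod
from . import qpcr as qpcr_mod
from .synthetic import SynthConfig, config_from_dict, config_to_dict, write_synthetic_inputs

logger = logging.getLogger(__name__)

INPUT_KEYS = ("expression", "group_map", "annotation", "lnc_mi", "mi_m_db1", "mi_m_db2", "gene_sets")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative description of one run.

    ``mode`` is ``synthetic`` (inputs generated from ``synth``) or ``files``
    (all paths in ``inputs`` must exist). Threshold defaults follow the
    analysis conventions of the study design: |logFC| > 1 with FDR < 0.05
    for differential expression, BH-corrected p < 0.01 for enrichment, and
    six top-ranked lncRNAs.
    """

    mode: str = "synthetic"
    inputs: dict[str, str] = field(default_factory=dict)
    ct_table: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    group_a: str = "day0"
    group_b: str = "day8"
    paired: bool = False
    filter_min_value: float = 0.0
    filter_min_fraction: float = 1.0
    log2_offset: float = 1.0
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    enrichment_fdr: float = 0.01
    top_k: int = 6
    export_formats: tuple[str, ...] = ("sif", "graphml", "tsv")
    reference_gene: str = "GAPDH"
    outdir: str = "cernet_run"
    seed: int = 0

    def violations(self) -> list[str]:
        """Every constraint violation, not just the first."""
        problems = []
        if self.mode not in ("synthetic", "files"):
            problems.append(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if not 0 < self.fdr_max <= 1:
            problems.append(f"fdr_max must be in (0, 1], got {self.fdr_max}")
        if self.lfc_min < 0:
            problems.append(f"lfc_min must be >= 0, got {self.lfc_min}")
        if not 0 < self.enrichment_fdr <= 1:
            problems.append(f"enrichment_fdr must be in (0, 1], got {self.enrichment_fdr}")
        if self.top_k < 1:
            problems.append(f"top_k must be >= 1, got {self.top_k}")
        if not 0 <= self.filter_min_fraction <= 1:
            problems.append(f"filter_min_fraction must be in [0, 1], got {self.filter_min_fraction}")
        if self.log2_offset < 0:
            problems.append(f"log2_offset must be >= 0, got {self.log2_offset}")
        bad_fmt = set(self.export_formats) - {"sif", "graphml", "tsv"}
        if bad_fmt:
            problems.append(f"unknown export formats: {sorted(bad_fmt)}")
        if self.mode == "files":
            missing = [k for k in INPUT_KEYS if k not in self.inputs]
            if missing:
                problems.append(f"missing input paths: {missing}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    problems.append(f"input {key!r}: path {path} does not exist")
        try:
            self.synth.validate()
        except ValueError as exc:
            problems.append(f"synth: {exc}")
        return problems


def validate_config(path) -> PipelineConfig:
    """Load a YAML config; raise ValueError listing every violation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "synth" in raw and isinstance(raw["synth"], dict):
        raw["synth"] = config_from_dict(raw["synth"])
    if "export_formats" in raw:
        raw["export_formats"] = tuple(raw["export_formats"])
    config = PipelineConfig(**raw)
    problems = config.violations()
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {p}" for p in problems))
    return config


def write_config(config: PipelineConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["synth"] = config_to_dict(config.synth)
    d["export_formats"] = list(config.export_formats)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages into ``config.outdir``; returns the run directory.

    The manifest (``manifest.json``) echoes the config and accumulates
    per-stage counts; it is written even when a stage fails, up to the
    failing stage.
    """
    problems = config.violations()
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {p}" for p in problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cernet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "counts": {},
        "timestamps": {"started": time.strftime("%Y-%m-%dT%H:%M:%S")},
        "status": "running",
    }

    def save_manifest() -> None:
        manifest["timestamps"]["updated"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    def fail(stage: str, exc: Exception) -> PipelineError:
        manifest["status"] = f"failed at {stage}"
        save_manifest()
        handler.close()
        root.removeHandler(handler)
        return PipelineError(stage, str(exc))

    try:
        # ---- stage: inputs -------------------------------------------------
        try:
            if config.mode == "synthetic":
                synth = dataclasses.replace(config.synth, seed=config.seed)
                paths = write_synthetic_inputs(synth, outdir / "inputs")
                inputs = {k: str(paths[k]) for k in INPUT_KEYS}
                ct_path: str | None = str(paths["ct_table"])
            else:
                inputs = dict(config.inputs)
                ct_path = config.ct_table
        except Exception as exc:
            raise fail("inputs", exc) from exc

        # ---- stage: expression --------------------------------------------
        try:
            mat = expr_mod.read_expression_matrix(inputs["expression"], inputs["group_map"])
            annot = expr_mod.read_probe_annotation(inputs["annotation"])
            n_probes_in = mat.values.shape[0]
            mat = expr_mod.filter_unexpressed(
                mat, config.filter_min_value, config.filter_min_fraction
            )
            manifest["counts"]["probes_input"] = n_probes_in
            manifest["counts"]["probes_kept"] = mat.values.shape[0]
            mat = expr_mod.quantile_normalize(mat)
            mat = expr_mod.log2_transform(mat, offset=config.log2_offset)
            mat = expr_mod.collapse_probes(mat, annot)
            mrna_mat, lnc_mat = expr_mod.split_by_biotype(mat, annot)
            manifest["counts"]["genes"] = mat.values.shape[0]
            manifest["counts"]["mrnas"] = mrna_mat.values.shape[0]
            manifest["counts"]["lncrnas"] = lnc_mat.values.shape[0]
            logger.info(
                "expression: %d genes (%d mRNA, %d lncRNA)",
                mat.values.shape[0], mrna_mat.values.shape[0], lnc_mat.values.shape[0],
            )
        except Exception as exc:
            raise fail("expression", exc) from exc
        save_manifest()

        # ---- stage: de -----------------------------------------------------
        try:
            results = {}
            for label, m in (("mrna", mrna_mat), ("lncrna", lnc_mat)):
                table = de_mod.differential_expression(
                    m, config.group_a, config.group_b, paired=config.paired
                )
                table, n_up, n_down = de_mod.apply_thresholds(
                    table, config.lfc_min, config.fdr_max
                )
                de_mod.write_de_table(table, outdir / f"de_{label}.tsv")
                manifest["counts"][f"de_{label}_up"] = n_up
                manifest["counts"][f"de_{label}_down"] = n_down
                results[label] = table
                logger.info("de (%s): %d up, %d down", label, n_up, n_down)
            dem_ids = set(results["mrna"].index[results["mrna"]["passed"]])
            del_ids = set(results["lncrna"].index[results["lncrna"]["passed"]])
        except Exception as exc:
            raise fail("de", exc) from exc
        save_manifest()

        # ---- stage: network (interaction integration + graph) -------------
        try:
            lnc_mi = int_mod.read_interaction_table(
                inputs["lnc_mi"], "lncRNA-miRNA", source_db="mircode"
            )
            db1 = int_mod.read_interaction_table(
                inputs["mi_m_db1"], "miRNA-mRNA", source_db="targetscan"
            )
            db2 = int_mod.read_interaction_table(
                inputs["mi_m_db2"], "miRNA-mRNA", source_db="mirtarbase"
            )
            manifest["counts"]["interactions_lnc_mi"] = len(lnc_mi)
            manifest["counts"]["interactions_db1"] = len(db1)
            manifest["counts"]["interactions_db2"] = len(db2)
            if not del_ids:
                raise ValueError("empty DE list: no differentially expressed lncRNAs")
            if not dem_ids:
                raise ValueError("empty DE list: no differentially expressed mRNAs")
            lnc_mi = int_mod.deduplicate(
                int_mod.restrict_to_de(lnc_mi, del_ids, side="regulator")
            )
            mi_m = int_mod.intersect_databases(db1, db2)
            mi_m = int_mod.deduplicate(int_mod.restrict_to_de(mi_m, dem_ids, side="target"))
            manifest["counts"]["interactions_merged"] = len(lnc_mi) + len(mi_m)
            pd.concat(
                [lnc_mi.df.assign(kind="lnc-mi"), mi_m.df.assign(kind="mi-m")],
                ignore_index=True,
            ).to_csv(outdir / "interactions_merged.tsv", sep="\t", index=False)

            net = net_mod.build_cerna_network(lnc_mi, mi_m)
            net_mod.validate_network(net)
            summary = net_mod.network_summary(net)
            manifest["counts"]["network"] = summary
            (outdir / "network_summary.json").write_text(json.dumps(summary, indent=1))
            for fmt in config.export_formats:
                net_mod.export_network(net, fmt, outdir / f"network.{fmt}")
            ranking = net_mod.rank_lncrnas(net, top_k=config.top_k)
            with open(outdir / "lncrna_ranking.tsv", "w") as fh:
                fh.write("lncrna\tdegree\n")
                for name, degree in ranking:
                    fh.write(f"{name}\t{degree}\n")
            logger.info("network: %s; top lncRNAs: %s", summary, [r[0] for r in ranking])
        except Exception as exc:
            raise fail("network", exc) from exc
        save_manifest()

        # ---- stage: enrichment ---------------------------------------------
        try:
            library = enr_mod.read_gmt(inputs["gene_sets"])
            universe = set(mrna_mat.values.index)
            network_mrnas = net.nodes_of_type("mRNA")
            global_table = enr_mod.enrich(
                network_mrnas, library, universe, fdr_threshold=config.enrichment_fdr
            )
            global_table.to_csv(
                outdir / "enrichment_global.tsv", sep="\t", index=False, float_format="%.6g"
            )
            manifest["counts"]["enriched_sets_global"] = int(global_table["passed"].sum())
            for name, _deg in ranking:
                subnet = net_mod.extract_subnetwork(net, name)
                net_mod.export_network(subnet, "sif", outdir / f"subnet_{name}.sif")
                sub_mrnas = subnet.nodes_of_type("mRNA")
                sub_table = enr_mod.enrich(
                    sub_mrnas, library, universe, fdr_threshold=config.enrichment_fdr
                )
                sub_table.to_csv(
                    outdir / f"enrichment_{name}.tsv", sep="\t", index=False, float_format="%.6g"
                )
        except Exception as exc:
            raise fail("enrichment", exc) from exc
        save_manifest()

        # ---- stage: qpcr ----------------------------------------------------
        if ct_path is not None:
            try:
                ct = qpcr_mod.read_ct_table(ct_path)
                rel = qpcr_mod.relative_expression(ct, config.reference_gene)
                rel.to_csv(
                    outdir / "qpcr_relative_expression.tsv",
                    sep="\t", index=False, float_format="%.6g",
                )
                summary_df = qpcr_mod.summarize_genes(rel, config.reference_gene)
                summary_df.to_csv(
                    outdir / "qpcr_results.tsv", sep="\t", index=False, float_format="%.6g"
                )
                manifest["counts"]["qpcr_genes"] = len(summary_df)
            except Exception as exc:
                raise fail("qpcr", exc) from exc

        manifest["status"] = "ok"
        save_manifest()
    finally:
        handler.close()
        root.removeHandler(handler)
    return outdir
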