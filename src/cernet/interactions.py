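"""Regulator-target interaction tables (lncRNA-miRNA and miRNA-mRNA).

Covers the database-integration step of ceRNA analysis: read miRcode-style
lncRNA-miRNA pairs and two miRNA-mRNA target tables (TargetScan-style
predictions, miRTarBase-style validations), keep only pairs present in both
target databases, restrict either side to differentially expressed genes,
and drop redundant pairs.

Identifier matching is exact string equality after whitespace trimming.
Because miRNA naming differs between resources (family labels vs mature
names), an optional alias map (alias -> canonical) can be applied at read
time; an optional fold-case flag lower-cases identifiers for messy inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("lncRNA-miRNA", "miRNA-mRNA")


@dataclass
class InteractionTable:
    """Typed regulator->target pairs with database provenance.

    ``df`` has columns (regulator, target, source_db); ``kind`` is one of
    ``lncRNA-miRNA`` (regulator = lncRNA) or ``miRNA-mRNA`` (regulator = miRNA).
    """

    df: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        required = {"regulator", "target", "source_db"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"interaction table needs columns {sorted(required)}")
        if ((self.df["regulator"] == "") | (self.df["target"] == "")).any():
            raise ValueError("empty identifiers in interaction table")

    def __len__(self) -> int:
        return len(self.df)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.df["regulator"], self.df["target"]))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_alias_map(path) -> dict[str, str]:
    """Two-column TSV alias -> canonical identifier."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"alias map {path} needs two columns (alias, canonical)")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def read_interaction_table(
    path,
    kind: str,
    source_db: str,
    regulator_col: str = "regulator",
    target_col: str = "target",
    alias_map: dict[str, str] | None = None,
    fold_case: bool = False,
) -> InteractionTable:
    """Read a regulator/target TSV into a typed InteractionTable.

    Column names are configurable per database dialect. Identifiers are
    whitespace-trimmed and case-preserved unless ``fold_case``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (regulator_col, target_col):
        if col not in df.columns:
            raise ValueError(
                f"{path}: column {col!r} not found; available columns: {list(df.columns)}"
            )
    out = pd.DataFrame(
        {
            "regulator": df[regulator_col].str.strip(),
            "target": df[target_col].str.strip(),
        }
    )
    if fold_case:
        out = out.apply(lambda s: s.str.lower())
    if alias_map:
        out = out.apply(lambda s: s.map(lambda x: alias_map.get(x, x)))
    out["source_db"] = source_db
    if out.empty:
        logger.warning("interaction table %s is empty", path)
    return InteractionTable(df=out.reset_index(drop=True), kind=kind)


def deduplicate(table: InteractionTable) -> InteractionTable:
    """Unique (regulator, target) pairs, keeping the first occurrence; stable order."""
    df = table.df.drop_duplicates(subset=["regulator", "target"], keep="first")
    return replace(table, df=df.reset_index(drop=True))


def intersect_databases(db1: InteractionTable, db2: InteractionTable) -> InteractionTable:
    """Pairs present in both miRNA-mRNA databases, provenance set to ``both``."""
    if db1.kind != "miRNA-mRNA" or db2.kind != "miRNA-mRNA":
        raise ValueError("intersect_databases expects two miRNA-mRNA tables")
    d1 = deduplicate(db1).df
    shared = d1.merge(db2.df[["regulator", "target"]].drop_duplicates(), on=["regulator", "target"])
    out = shared[["regulator", "target"]].copy()
    out["source_db"] = "both"
    if out.empty:
        logger.warning("database intersection is empty")
    return InteractionTable(df=out.reset_index(drop=True), kind="miRNA-mRNA")


def restrict_to_de(table: InteractionTable, de_ids, side: str) -> InteractionTable:
    """Keep rows whose ``side`` ('regulator' or 'target') identifier is differentially expressed."""
    if side not in ("regulator", "target"):
        raise ValueError(f"side must be 'regulator' or 'target', got {side!r}")
    de_ids = set(de_ids)
    if not de_ids:
        raise ValueError("empty DE list: upstream differential expression produced no genes")
    df = table.df[table.df[side].isin(de_ids)]
    return replace(table, df=df.reset_index(drop=True))
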