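"""Readers and writers for the pipeline's plain-text formats.

On disk the ASV table follows the amplicon convention (features as rows,
samples as columns, tab-separated integer counts); in memory every module
works samples-as-rows. The transpose happens here and only here.

Readers validate strictly and reject malformed input rather than coercing:
negative or non-integer counts, duplicate ids, whitespace in ids, and
missing metadata columns are all hard errors naming the offending entry.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
import yaml

from .exceptions import FormatError, ReconciliationError, SchemaError

__all__ = [
    "AnalysisConfig",
    "read_asv_table",
    "write_asv_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "load_bundle",
    "write_results",
]

ANCHOR_TAGS = {"BBB", "P_copri", "P_stercorea", "CMO", "none"}
METADATA_REQUIRED = ("sample_id", "ethnicity", "generation")


@dataclass
class AnalysisConfig:
    """All printed pipeline constants, overridable from YAML."""

    rarefaction_depth: int = 15221
    agglomeration_height: float = 0.10
    top_n_heatmap: int = 200
    consensus_min_support: int = 6
    ml_n_subsets: int = 20
    ml_fraction: float = 0.5
    ml_top_abundance: int = 1000
    ml_top_f: int = 100
    ml_n_param_settings: int = 10
    permutations: int = 999
    enterotype_k_pam: int = 3
    enterotype_k_dmm: int = 4
    dmm_detection: float = 0.001
    dmm_prevalence: float = 0.5
    age_cutoff: float = 42.0
    seed: int = 0

    def __post_init__(self):
        for name in ("rarefaction_depth", "top_n_heatmap", "consensus_min_support",
                     "ml_n_subsets", "ml_top_abundance", "ml_top_f",
                     "ml_n_param_settings", "permutations",
                     "enterotype_k_pam", "enterotype_k_dmm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.ml_fraction <= 1:
            raise ValueError("ml_fraction must lie in (0, 1]")
        if self.agglomeration_height <= 0:
            raise ValueError("agglomeration_height must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _check_ids(ids, what: str) -> None:
    seen = set()
    for i in ids:
        s = str(i)
        if any(c.isspace() for c in s):
            raise FormatError(f"{what} id contains whitespace: {s!r}")
        if s in seen:
            raise FormatError(f"duplicate {what} id: {s!r}")
        seen.add(s)


def read_asv_table(path) -> pd.DataFrame:
    """Read a features-as-rows TSV count table into samples-as-rows form."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_ids(df.index, "ASV")
    _check_ids(df.columns, "sample")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() | (num % 1 != 0)
    if bad.to_numpy().any():
        row = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise FormatError(
            f"non-integer count at ASV {row!r}, sample {col!r}: {df.loc[row, col]!r}"
        )
    if (num < 0).to_numpy().any():
        neg = num < 0
        row = neg.index[neg.any(axis=1)][0]
        col = neg.columns[neg.loc[row]][0]
        raise FormatError(
            f"negative count at ASV {row!r}, sample {col!r}: {df.loc[row, col]!r}"
        )
    table = num.astype(np.int64).T
    table.index.name = "sample_id"
    table.columns.name = None
    return table


def write_asv_table(table: pd.DataFrame, path) -> None:
    """Write the in-memory samples-as-rows table as features-as-rows TSV."""
    disk = table.T
    disk.index = disk.index.rename("asv_id")
    disk.to_csv(path, sep="\t")


def read_tree(path) -> skbio.TreeNode:
    tree = skbio.TreeNode.read(str(path))
    for node in tree.postorder(include_self=False):
        if node.length is None:
            raise FormatError(f"tree node {node.name!r} lacks a branch length")
    if len(tree.children) == 0:
        raise FormatError("newick file holds a single node, not a rooted tree")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path))


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing required columns: {missing}")
    _check_ids(meta["sample_id"], "sample")
    meta = meta.set_index("sample_id")
    if not set(pd.unique(meta["generation"])) <= {1, 2}:
        raise SchemaError("generation column must contain only 1 and 2")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=True)


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"asv_id", "genus"}
    missing = required - set(tax.columns)
    if missing:
        raise SchemaError(f"taxonomy missing columns: {sorted(missing)}")
    _check_ids(tax["asv_id"], "ASV")
    tax = tax.set_index("asv_id")
    if "anchor" in tax.columns:
        bad = set(tax["anchor"].replace("", "none")) - ANCHOR_TAGS
        if bad:
            raise SchemaError(f"unknown anchor tags: {sorted(bad)}")
        tax["anchor"] = tax["anchor"].replace("", "none")
    else:
        tax["anchor"] = "none"
    if "species" not in tax.columns:
        tax["species"] = ""
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    out = tax.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def load_bundle(table_path, tree_path, meta_path, taxonomy_path=None,
                prune_to_table: bool = False):
    """Load and reconcile (table, tree, metadata[, taxonomy]).

    Tree tips must cover the table's ASVs (extra tips pruned when
    ``prune_to_table``); every table sample must appear in the metadata.
    """
    table = read_asv_table(table_path)
    tree = read_tree(tree_path)
    meta = read_metadata(meta_path)
    tips = {t.name for t in tree.tips()}
    asvs = set(map(str, table.columns))
    if asvs - tips:
        raise ReconciliationError(
            f"table ASVs missing from tree: {sorted(asvs - tips)[:5]}"
        )
    if tips - asvs:
        if prune_to_table:
            tree = tree.shear(sorted(asvs))
        else:
            raise ReconciliationError(
                f"tree has tips absent from table: {sorted(tips - asvs)[:5]} "
                "(pass prune_to_table=True to drop them)"
            )
    missing_meta = set(map(str, table.index)) - set(map(str, meta.index))
    if missing_meta:
        raise ReconciliationError(
            f"samples missing from metadata: {sorted(missing_meta)[:5]}"
        )
    meta = meta.loc[table.index]
    if taxonomy_path is not None:
        tax = read_taxonomy(taxonomy_path)
        missing_tax = asvs - set(map(str, tax.index))
        if missing_tax:
            raise ReconciliationError(
                f"ASVs missing from taxonomy: {sorted(missing_tax)[:5]}"
            )
        return table, tree, meta, tax
    return table, tree, meta


def write_results(out_dir, objects: dict) -> list[str]:
    """Emit result objects as TSV/JSON files plus a manifest.json index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            obj.to_csv(out / fname, sep="\t")
        elif isinstance(obj, pd.Series):
            fname = f"{name}.tsv"
            obj.to_frame().to_csv(out / fname, sep="\t")
        else:
            fname = f"{name}.json"
            with open(out / fname, "w") as fh:
                json.dump(obj, fh, indent=1, default=_jsonify)
        manifest[name] = fname
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return sorted(manifest.values())


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
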