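"""Tabular readers/writers and pipeline configuration.

Canonical interchange is TSV (tab-separated, UTF-8, header row, "."
decimal) with opaque string sample/feature identifiers; run metadata is
JSON; configuration is a YAML nested document.  Writers emit a
deterministic column order, readers tolerate arbitrary row order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_table",
    "read_asv_table",
    "read_taxonomy",
    "read_metadata",
    "read_gene_abundance",
    "write_annotation_maps",
    "read_annotation_maps",
    "write_pathways",
    "read_pathways",
    "default_config",
    "load_config",
    "write_json",
    "read_json",
]

TAXONOMY_RANKS = ("Domain", "Phylum", "Class", "Order", "Family", "Genus")


class ParseError(ValueError):
    """A file failed validation; the message names the offending item."""


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def _read_tsv(path: str | Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = index_name
    return df


def read_asv_table(path: str | Path) -> pd.DataFrame:
    """Samples x ASVs count table; duplicate samples and non-numeric
    counts raise descriptive errors."""
    df = _read_tsv(path, "sample_id")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"duplicated sample rows in {path}: {dup}")
    try:
        out = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric counts in {path}: {exc}") from exc
    if (out.to_numpy() < 0).any():
        raise ParseError(f"negative counts in {path}")
    return out


def read_taxonomy(path: str | Path, asv_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-ASV taxonomy with Domain..Genus columns; optionally checks
    consistency against an ASV table."""
    tax = _read_tsv(path, "asv_id")
    missing_cols = [r for r in TAXONOMY_RANKS if r not in tax.columns]
    if missing_cols:
        raise ParseError(f"taxonomy {path} missing rank columns: {missing_cols}")
    if asv_table is not None:
        extra = [a for a in tax.index if a not in asv_table.columns]
        if extra:
            raise ParseError(
                f"taxonomy rows absent from the ASV table: {extra[:5]}"
                + ("..." if len(extra) > 5 else "")
            )
    return tax


def read_metadata(path: str | Path, require: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-sample metadata; ``require`` lists columns a stage needs."""
    meta = _read_tsv(path, "animal_id")
    dup = meta.index[meta.index.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"duplicated sample rows in {path}: {dup}")
    missing = [c for c in require if c not in meta.columns]
    if missing:
        raise ParseError(f"metadata {path} missing required columns: {missing}")
    return meta


def read_gene_abundance(path: str | Path) -> pd.DataFrame:
    """Genes x samples abundance matrix."""
    df = _read_tsv(path, "gene_id")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"duplicated gene rows in {path}: {dup}")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric abundances in {path}: {exc}") from exc


def write_annotation_maps(
    gene2ko: dict[str, str], gene2cazy: dict[str, str], genes, path: str | Path
) -> None:
    """Gene map TSV with columns gene_id, ko, cazy (empty fields allowed)."""
    rows = [
        {"gene_id": g, "ko": gene2ko.get(g, ""), "cazy": gene2cazy.get(g, "")}
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_maps(path: str | Path) -> dict:
    """Read the gene map; genes without KO/CAZy keep empty annotation.

    Returns ``{"gene2ko", "gene2cazy", "genes", "ko_coverage"}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("gene_id", "ko", "cazy"):
        if col not in df.columns:
            raise ParseError(f"gene map {path} missing column {col!r}")
    gene2ko = {g: k for g, k in zip(df["gene_id"], df["ko"]) if k}
    gene2cazy = {g: c for g, c in zip(df["gene_id"], df["cazy"]) if c}
    return {
        "gene2ko": gene2ko,
        "gene2cazy": gene2cazy,
        "genes": df["gene_id"].tolist(),
        "ko_coverage": f"{len(gene2ko)}/{len(df)}",
    }


def write_pathways(pathway2kos: dict[str, set[str]], path: str | Path) -> None:
    """One line per pathway: ``pathway_id TAB comma-separated KO list``."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(pathway2kos):
            fh.write(f"{pid}\t{','.join(sorted(pathway2kos[pid]))}\n")


def read_pathways(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ParseError(f"malformed pathway line {lineno} in {path}: {line!r}")
            out[parts[0]] = {k for k in parts[1].split(",") if k}
    return out


def default_config() -> dict:
    """Pipeline defaults; every stochastic stage carries an explicit seed."""
    return {
        "seed": 0,
        "simulate": {
            "n_animals": 87,
            "n_asvs": 400,
            "n_components": 5,
            "module_sizes": [20, 20, 15, 15, 10],
            "within_module_assoc": 0.8,
            "noise_sd": 5.0,
            "n_days": 98,
            "genes": {
                "n_genes": 1000,
                "group_sizes": [11, 10, 11],
                "effect": 1.0,
                "ordered_fraction": 0.1,
            },
        },
        "phenotype": {"dim_window": [3, 100], "smooth_window": 15},
        "community": {"min_rel": 0.001, "min_prev": 0.5, "n_perm": 999},
        "archetypes": {"n_components": "auto", "max_iter": 200, "tol": 1e-7},
        "predict": {
            "eta": 0.05,
            "depth": 2,
            "min_node": 2,
            "row_subsample": 0.8,
            "col_subsample": 1.0,
            "n_rounds": 26,
            "tune": False,
            "tune_rounds": 200,
        },
        "interpret": {"n_bins": 40, "ale_highlight": 1.5,
                      "surrogate": {"max_inner_nodes": 5, "alpha": 0.05, "n_perm": 999}},
        "network": {"n_lambda": 100, "gamma": 0.5, "n_top_components": 5,
                    "min_module_size": 10, "deep_split": 2},
        "metagenome": {"filter_q": 0.95, "ko_sig_p": 0.1, "fdr": 0.05, "n_perm": 2000},
    }


def _deep_update(base: dict, extra: dict) -> dict:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with a YAML config document (if given)."""
    cfg = default_config()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ParseError(f"config {path} must be a mapping")
        _deep_update(cfg, user)
    return cfg


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, set):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
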