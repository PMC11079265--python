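"""Tab-separated I/O for registries, summary statistics, panels and gene sets."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

REGISTRY_COLUMNS = ["participant_id", "date", "icd_version", "code", "role"]
VITAL_COLUMNS = ["participant_id", "death_date", "cause_codes"]
SUMMARY_COLUMNS = ["CHR", "POS", "REF", "ALT", "BETA", "SE", "PVAL", "MAF", "MAC", "INFO", "N"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_registry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "code": str})
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry file missing columns {missing}")
    return df


def read_vitals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"participant_id": str, "cause_codes": str}, keep_default_na=False
    )
    missing = [c for c in VITAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"vital file missing columns {missing}")
    return df


def read_summary_stats(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a METAL-style summary table, optionally renaming via ``column_map``
    (mapping from the file's column names to the canonical names)."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file missing columns {missing}")
    return df


def read_gene_intervals(path: str | Path, convention: str = "tsv1") -> pd.DataFrame:
    """Gene intervals as a 1-based TSV (gene, chrom, start, end) or BED.

    ``convention="bed"`` reads 0-based half-open BED (chrom, start, end, name)
    and converts to 1-based inclusive internally.
    """
    if convention == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "gene"], usecols=range(4))
        df["start"] = df["start"].astype(int) + 1
        df["end"] = df["end"].astype(int)
    elif convention == "tsv1":
        df = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown gene-interval convention {convention!r}")
    df["chrom"] = pd.to_numeric(df["chrom"], errors="coerce").astype("Int64")
    return df[["gene", "chrom", "start", "end"]]


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Gene × sample matrix; a GCT-style two-line preamble is tolerated."""
    with open(path) as fh:
        first = fh.readline()
    skip = 2 if first.startswith("#1.2") or first.strip() == "#1.2" else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    return df.astype(float)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set file: term, description, then member genes per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(term_sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term in sorted(term_sets):
            fh.write("\t".join([term, description, *term_sets[term]]) + "\n")


def write_json(obj: object, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
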