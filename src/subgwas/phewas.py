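"""Phenome-wide association scanning of genome-wide-significant SNP sets.

Each SNP set (e.g. the significant SNPs of the regions found in common for
single and recurrent events, or uniquely for one group) is scanned against a
phenome association table — a grid of per-(phenocode, SNP) effects and
p-values such as the Pan-UKBB summaries over 1,326 phenocodes.  Significance
uses a Bonferroni threshold scaled by both dimensions of the scan,
``0.05 / (n_phenocodes × n_set)``, and only the lowest-p SNP per phenotype is
kept for reporting.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_N_PHENOCODES = 1326


def phewas_threshold(n_set: int, n_phenocodes: int = DEFAULT_N_PHENOCODES, alpha: float = 0.05) -> float:
    """Bonferroni threshold 0.05 / (n_phenocodes × n_set) for one SNP set."""
    if n_set < 1:
        raise ValueError("n_set must be at least 1")
    if n_phenocodes < 1:
        raise ValueError("n_phenocodes must be at least 1")
    return alpha / (n_phenocodes * n_set)


def scan_snp_set(
    snp_set: Sequence[str],
    phenome: pd.DataFrame,
    n_phenocodes: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (SNP, phenocode) associations below the set-scaled threshold.

    ``n_set`` is the number of unique SNP identifiers in the set.  SNPs
    absent from the phenome table are logged as missing, not errors.  The
    phenome table is long-format with columns PHENOCODE, CATEGORY, SNP, PVAL.
    """
    if phenome.empty:
        raise ValueError("empty phenome table")
    snps = sorted(set(snp_set))
    if n_phenocodes is None:
        n_phenocodes = phenome["PHENOCODE"].nunique()
    threshold = phewas_threshold(len(snps), n_phenocodes, alpha=alpha)
    present = set(phenome["SNP"].unique())
    missing = [s for s in snps if s not in present]
    if missing:
        logger.info("scan_snp_set: %d/%d SNPs missing from the phenome table", len(missing), len(snps))
    sub = phenome[phenome["SNP"].isin(snps) & (phenome["PVAL"] < threshold)].copy()
    sub["THRESHOLD"] = threshold
    sub["PASSED"] = True
    sub = sub.sort_values(["PVAL", "PHENOCODE", "SNP"], kind="mergesort").reset_index(drop=True)
    sub.attrs["missing_snps"] = missing
    sub.attrs["threshold"] = threshold
    return sub


def best_per_phenotype(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep only the lowest-p SNP per phenocode (ties: smallest SNP id, logged)."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(["PHENOCODE", "PVAL", "SNP"], kind="mergesort")
    ties = ordered.duplicated(["PHENOCODE", "PVAL"], keep=False) & ~ordered.duplicated(
        ["PHENOCODE"], keep="first"
    )
    if ties.any():
        logger.info("best_per_phenotype: %d phenocodes with tied minimum p", int(ties.sum()))
    out = ordered.drop_duplicates("PHENOCODE", keep="first").reset_index(drop=True)
    return out


def summarize_categories(reduced_hits: pd.DataFrame) -> pd.DataFrame:
    """Count distinct phenocodes per category, sorted descending."""
    if reduced_hits.empty:
        return pd.DataFrame(columns=["CATEGORY", "N_PHENOCODES"])
    counts = (
        reduced_hits.groupby("CATEGORY")["PHENOCODE"]
        .nunique()
        .sort_values(ascending=False)
        .reset_index()
        .rename(columns={"PHENOCODE": "N_PHENOCODES"})
    )
    return counts
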