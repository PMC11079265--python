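"""Per-cohort association, QC, harmonization, IVW meta-analysis and regions.

The meta-analysis is the standard fixed-effect inverse-variance-weighted
combination: with per-cohort effects :math:`\\beta_i` and standard errors
:math:`se_i`, weights are :math:`w_i = 1/se_i^2`,

.. math::

    \\beta_{meta} = \\frac{\\sum_i w_i \\beta_i}{\\sum_i w_i}, \\qquad
    se_{meta} = \\frac{1}{\\sqrt{\\sum_i w_i}}, \\qquad
    z = \\beta_{meta}/se_{meta}, \\qquad p = 2\\,\\Phi(-|z|).

Variants present in only one cohort after QC pass through that cohort's
statistics with a ``?`` in the direction string.  Genome-wide-significant
variants (p < 5e-8) are chained into regions: consecutive variants on a
chromosome belong to the same region while less than 500 kb apart, and the
lead SNP is the lowest-p member.  Regions found for the single-event and
recurrent-event analyses are classified as common when they share SNPs or
overlap under the same 500-kb rule, otherwise as group-unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8
REGION_GAP_BP = 500_000

SUMMARY_COLUMNS = ["CHR", "POS", "REF", "ALT", "BETA", "SE", "PVAL", "MAF", "MAC", "INFO", "N"]


# ---------------------------------------------------------------------------
# Per-cohort association (covariate-adjusted logistic regression)
# ---------------------------------------------------------------------------


def run_cohort_gwas(
    genotypes: np.ndarray,
    labels: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    variant_meta: pd.DataFrame | None = None,
    cohort: str = "A",
) -> pd.DataFrame:
    """Covariate-adjusted logistic association, one Wald test per SNP.

    Genotypes are additive dosages in {0, 1, 2}.  Each SNP is fitted with a
    logistic regression of case status on dosage plus all covariate columns;
    the reported effect is the per-alt-allele log-odds with its Wald standard
    error and two-sided p-value.  Monomorphic SNPs and fits that fail to
    converge (e.g. quasi-separation) are dropped and counted in the log.
    """
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=float)
    X_cov = np.column_stack([np.ones(len(y)), covariates.to_numpy(dtype=float)])
    n, n_snps = genotypes.shape
    rows = []
    n_dropped = 0
    for j in range(n_snps):
        g = genotypes[:, j].astype(float)
        if g.min() == g.max():
            n_dropped += 1
            continue
        X = np.column_stack([X_cov, g])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", False):
                raise ValueError("did not converge")
            beta = fit.params[-1]
            se = fit.bse[-1]
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
                raise ValueError("degenerate fit")
        except Exception:
            n_dropped += 1
            continue
        p = 2 * stats.norm.sf(abs(beta / se))
        af = g.mean() / 2.0
        maf = min(af, 1 - af)
        mac = int(round(2 * n * maf))
        rows.append((j, beta, se, max(p, np.finfo(float).tiny), maf, mac))
    if n_dropped:
        logger.info("run_cohort_gwas: dropped %d of %d SNPs", n_dropped, n_snps)
    out = pd.DataFrame(rows, columns=["snp_index", "BETA", "SE", "PVAL", "MAF", "MAC"])
    out["INFO"] = 1.0  # hard calls
    out["N"] = n
    out["COHORT"] = cohort
    if variant_meta is not None:
        meta = variant_meta.iloc[out["snp_index"]].reset_index(drop=True)
        for col in ("CHR", "POS", "REF", "ALT"):
            out[col] = meta[col].to_numpy()
    out.attrs["n_dropped"] = n_dropped
    return out


# ---------------------------------------------------------------------------
# QC and harmonization
# ---------------------------------------------------------------------------


def qc_filter(
    summary: pd.DataFrame,
    mac_min: int = 3,
    info_min: float = 0.3,
    combine: str = "union",
) -> pd.DataFrame:
    """Drop low-confidence variants: MAC below 3 or imputation info below 0.3.

    Both thresholds are strict exclusions (MAC < 3 removed, MAC = 3 kept).
    ``combine="union"`` (the default, standard QC practice) removes a row
    failing either criterion; ``"intersection"`` removes only rows failing
    both.
    """
    low_mac = summary["MAC"] < mac_min
    low_info = summary["INFO"] < info_min
    if combine == "union":
        bad = low_mac | low_info
    elif combine == "intersection":
        bad = low_mac & low_info
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    logger.info(
        "qc_filter: removed %d/%d rows (mac<%s: %d, info<%s: %d)",
        int(bad.sum()), len(summary), mac_min, int(low_mac.sum()), info_min, int(low_info.sum()),
    )
    return summary.loc[~bad].reset_index(drop=True)


def harmonize_and_join(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame) -> pd.DataFrame:
    """Join two cohorts on chromosome + position with allele reconciliation.

    If cohort B stores the alleles swapped relative to A, B's effect is
    re-signed to A's alt allele (MAF is minor-allele based and unchanged).
    Irreconcilable allele pairs are dropped and logged; variants present in
    only one cohort are retained with the other slot absent (NaN).
    """
    for name, df in (("A", cohort_a), ("B", cohort_b)):
        if df.duplicated(["CHR", "POS"]).any():
            raise ValueError(f"duplicate variant key within cohort {name}")
    a = cohort_a.rename(columns={c: f"{c}_A" for c in cohort_a.columns if c not in ("CHR", "POS")})
    b = cohort_b.rename(columns={c: f"{c}_B" for c in cohort_b.columns if c not in ("CHR", "POS")})
    joined = a.merge(b, on=["CHR", "POS"], how="outer", sort=True)
    both = joined["REF_A"].notna() & joined["REF_B"].notna()
    same = both & (joined["REF_A"] == joined["REF_B"]) & (joined["ALT_A"] == joined["ALT_B"])
    swapped = both & (joined["REF_A"] == joined["ALT_B"]) & (joined["ALT_A"] == joined["REF_B"])
    mismatch = both & ~same & ~swapped
    ambiguous = same & joined["REF_A"].isin(["A", "T", "C", "G"]) & (
        joined["REF_A"].map({"A": "T", "T": "A", "C": "G", "G": "C"}) == joined["ALT_A"]
    )
    if ambiguous.any():
        logger.warning(
            "harmonize_and_join: %d strand-ambiguous (A/T or C/G) variants kept",
            int(ambiguous.sum()),
        )
    if swapped.any():
        joined.loc[swapped, "BETA_B"] = -joined.loc[swapped, "BETA_B"]
        joined.loc[swapped, ["REF_B", "ALT_B"]] = joined.loc[swapped, ["ALT_B", "REF_B"]].to_numpy()
    if mismatch.any():
        logger.info("harmonize_and_join: dropped %d allele-mismatched variants", int(mismatch.sum()))
    joined = joined.loc[~mismatch].reset_index(drop=True)
    joined.attrs["n_swapped"] = int(swapped.sum())
    joined.attrs["n_mismatched"] = int(mismatch.sum())
    return joined


def maf_inclusion(joined: pd.DataFrame, maf_min: float = 0.01) -> pd.Series:
    """True where MAF exceeds the threshold in at least one present cohort."""
    a = joined.get("MAF_A")
    b = joined.get("MAF_B")
    ok_a = (a > maf_min).fillna(False) if a is not None else False
    ok_b = (b > maf_min).fillna(False) if b is not None else False
    return ok_a | ok_b


# ---------------------------------------------------------------------------
# Fixed-effect inverse-variance-weighted meta-analysis
# ---------------------------------------------------------------------------


def ivw_meta(joined: pd.DataFrame, maf_min: float = 0.01) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect meta-analysis of a joined table.

    Rows failing the MAF inclusion rule (MAF <= 1% in every present cohort)
    are dropped.  Single-cohort rows pass that cohort's beta and SE through
    unchanged, with ``?`` marking the absent cohort in the direction string.
    """
    keep = maf_inclusion(joined, maf_min=maf_min)
    df = joined.loc[keep].reset_index(drop=True)
    beta_a = df.get("BETA_A", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
    beta_b = df.get("BETA_B", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
    se_a = df.get("SE_A", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
    se_b = df.get("SE_B", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
    if np.any(se_a[np.isfinite(se_a)] <= 0) or np.any(se_b[np.isfinite(se_b)] <= 0):
        raise ValueError("standard errors must be positive")
    has_a = np.isfinite(beta_a) & np.isfinite(se_a)
    has_b = np.isfinite(beta_b) & np.isfinite(se_b)
    w_a = np.where(has_a, 1.0 / np.square(np.where(has_a, se_a, 1.0)), 0.0)
    w_b = np.where(has_b, 1.0 / np.square(np.where(has_b, se_b, 1.0)), 0.0)
    w_sum = w_a + w_b
    beta_meta = (w_a * np.where(has_a, beta_a, 0.0) + w_b * np.where(has_b, beta_b, 0.0)) / w_sum
    se_meta = 1.0 / np.sqrt(w_sum)
    z = beta_meta / se_meta
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    def _dir(has: np.ndarray, beta: np.ndarray) -> np.ndarray:
        out = np.where(has, np.where(beta >= 0, "+", "-"), "?")
        return out

    direction = np.char.add(_dir(has_a, np.nan_to_num(beta_a)), _dir(has_b, np.nan_to_num(beta_b)))
    out = pd.DataFrame(
        {
            "CHR": df["CHR"].to_numpy(),
            "POS": df["POS"].to_numpy(),
            "REF": df["REF_A"].where(df["REF_A"].notna(), df.get("REF_B")),
            "ALT": df["ALT_A"].where(df["ALT_A"].notna(), df.get("ALT_B")),
            "BETA_META": beta_meta,
            "SE_META": se_meta,
            "Z": z,
            "P_META": p,
            "DIR": direction,
            "NSTUDIES": (has_a.astype(int) + has_b.astype(int)),
        }
    )
    return out


def flag_significant(meta: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
    """Rows reaching genome-wide significance (strictly p < alpha)."""
    return meta.loc[meta["P_META"] < alpha].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Region clumping and classification
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """A clump of genome-wide-significant variants less than 500 kb apart."""

    chromosome: int
    start: int
    end: int
    members: list[tuple[int, int]]  # (chrom, pos), sorted by position
    lead: tuple[int, int]
    lead_p: float
    n_snps: int
    study_label: str = ""  # common | single | recurrent
    in_full_gwas: bool | None = None
    nearest_gene: str | None = None
    member_p: dict[tuple[int, int], float] = field(default_factory=dict, repr=False)


def cluster_regions(significant: pd.DataFrame, max_gap: int = REGION_GAP_BP) -> list[Region]:
    """Chain significant variants into regions per chromosome.

    A variant joins the current region when its distance to the previous
    member is strictly less than ``max_gap``; the lead SNP is the lowest-p
    member (ties broken by lowest position).  The output is invariant to the
    input row order.
    """
    pcol = "P_META" if "P_META" in significant.columns else "PVAL"
    regions: list[Region] = []
    df = significant.sort_values(["CHR", "POS"], kind="mergesort")
    for chrom, grp in df.groupby("CHR", sort=True):
        pos = grp["POS"].to_numpy(dtype=int)
        pvals = grp[pcol].to_numpy(dtype=float)
        start_idx = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] >= max_gap:
                members = [(int(chrom), int(p)) for p in pos[start_idx:i]]
                mp = {m: float(pv) for m, pv in zip(members, pvals[start_idx:i])}
                lead = min(members, key=lambda m: (mp[m], m[1]))
                regions.append(
                    Region(
                        chromosome=int(chrom),
                        start=int(pos[start_idx]),
                        end=int(pos[i - 1]),
                        members=members,
                        lead=lead,
                        lead_p=mp[lead],
                        n_snps=len(members),
                        member_p=mp,
                    )
                )
                start_idx = i
    return regions


def _regions_overlap(r1: Region, r2: Region, max_gap: int = REGION_GAP_BP) -> bool:
    if r1.chromosome != r2.chromosome:
        return False
    if set(r1.members) & set(r2.members):
        return True
    gap = max(r1.start, r2.start) - min(r1.end, r2.end)
    return gap < max_gap


def _merge_regions(rs: Sequence[Region], label: str) -> Region:
    members = sorted(set(m for r in rs for m in r.members), key=lambda m: m[1])
    mp: dict[tuple[int, int], float] = {}
    for r in rs:
        for m, p in r.member_p.items():
            mp[m] = min(p, mp.get(m, np.inf))
    lead = min(members, key=lambda m: (mp[m], m[1]))
    return Region(
        chromosome=rs[0].chromosome,
        start=members[0][1],
        end=members[-1][1],
        members=members,
        lead=lead,
        lead_p=mp[lead],
        n_snps=len(members),
        study_label=label,
        member_p=mp,
    )


def compare_region_sets(
    regions_single: Sequence[Region],
    regions_recurrent: Sequence[Region],
    regions_full: Sequence[Region] = (),
    max_gap: int = REGION_GAP_BP,
) -> list[Region]:
    """Label regions common to both subgroup analyses or unique to one.

    A single-analysis region and a recurrent-analysis region are merged as
    ``common`` when they share at least one SNP or any members lie less than
    500 kb apart; the rest keep their subgroup label.  Every labelled region
    is also flagged with whether it overlaps (same rule) a region of the full
    all-cases analysis.
    """
    # connected components of the overlap graph between the two analyses
    nodes = [("single", r) for r in regions_single] + [("recurrent", r) for r in regions_recurrent]
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i][0] != nodes[j][0] and _regions_overlap(nodes[i][1], nodes[j][1], max_gap):
                parent[find(i)] = find(j)
    components: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        components.setdefault(find(i), []).append(i)
    out: list[Region] = []
    for comp in components.values():
        kinds = {nodes[i][0] for i in comp}
        label = "common" if len(kinds) == 2 else kinds.pop()
        out.append(_merge_regions([nodes[i][1] for i in comp], label))
    for r in out:
        r.in_full_gwas = any(_regions_overlap(r, rf, max_gap) for rf in regions_full)
    out.sort(key=lambda r: (r.chromosome, r.start))
    return out


# ---------------------------------------------------------------------------
# Nearest-gene annotation
# ---------------------------------------------------------------------------


def nearest_gene(region: Region, gene_intervals: pd.DataFrame) -> tuple[str | None, int | None]:
    """Gene containing the lead SNP, else the minimal-distance gene boundary.

    ``gene_intervals`` needs columns ``gene, chrom, start, end`` (1-based,
    inclusive).  Ties on distance go to the alphabetically first gene name
    (logged).  Returns ``(gene, distance)``; distance 0 means the lead lies
    inside the gene.  An empty gene table for the chromosome yields
    ``(None, None)``.
    """
    chrom, pos = region.lead
    genes = gene_intervals[gene_intervals["chrom"] == chrom]
    if genes.empty:
        return None, None
    starts = genes["start"].to_numpy(dtype=int)
    ends = genes["end"].to_numpy(dtype=int)
    dist = np.maximum(0, np.maximum(starts - pos, pos - ends))
    best = dist.min()
    candidates = sorted(genes.loc[dist == best, "gene"])
    if len(candidates) > 1:
        logger.info(
            "nearest_gene: tie at distance %d for region chr%d:%d (%s); taking %s",
            int(best), chrom, pos, ",".join(candidates), candidates[0],
        )
    return candidates[0], int(best)


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    """Flatten a region list into the tabular output schema."""
    return pd.DataFrame(
        {
            "CHR": [r.chromosome for r in regions],
            "START": [r.start for r in regions],
            "END": [r.end for r in regions],
            "LEAD_CHR": [r.lead[0] for r in regions],
            "LEAD_POS": [r.lead[1] for r in regions],
            "LEAD_P": [r.lead_p for r in regions],
            "NSNPS": [r.n_snps for r in regions],
            "STUDY_LABEL": [r.study_label for r in regions],
            "IN_FULL": [r.in_full_gwas for r in regions],
            "NEAREST_GENE": [r.nearest_gene for r in regions],
        }
    )
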