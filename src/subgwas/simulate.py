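"""Synthetic inputs with known ground truth for every pipeline stage.

Five generators emulate the data the pipeline consumes:

* :func:`gen_registry` — longitudinal hospital diagnosis and death registries
  with participants planted as control / single / recurrent / excluded;
* :func:`gen_cohort_pair_summaries` — two cohorts of GWAS summary statistics
  with planted causal regions on a realistic allele-frequency spectrum;
* :func:`gen_phenome_table` — a phenome-wide association grid with planted
  cross-phenotype hits;
* :func:`gen_expression_panels` — per-tissue expression matrices with planted
  co-expression modules around chosen target genes;
* :func:`gen_genotype_cohort` — individual-level genotypes, case/control
  labels and covariates from a logistic disease model.

All generators are deterministic given their seed.  Truth is recorded at
construction time, never re-derived by running the pipeline being tested.
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .phenotyping import TRAITS, add_years

# ---------------------------------------------------------------------------
# Registry simulation
# ---------------------------------------------------------------------------

_TRAIT_EVENT_CODES = {
    # (icd_version, code) alternatives; chosen at random per record
    "AF": [(10, "I48.0"), (10, "I48.9"), (9, "427.31")],
    "MI": [(10, "I21.0"), (10, "I22.1"), (9, "410.1")],
}
_BACKGROUND_CODES = [(10, "J18.9"), (10, "K52.9"), (10, "M54.5"), (9, "780.6")]
_OTHER_CAUSE_CODES = [(10, "C34.9"), (10, "J44.1")]


@dataclass
class RegistrySimConfig:
    """Conditions for a synthetic diagnosis + death registry.

    Event hazards are per participant-year over the follow-up span; the
    recurrence gap and death delay are uniform draws between their bounds.
    ``boundary_fraction`` plants participants sitting exactly on the 30-day
    event gap and on the relapse-window censoring boundary, where
    classification rules are most fragile.
    """

    n_participants: int = 2000
    trait: str = "AF"
    followup_start: dt.date = dt.date(1995, 1, 1)
    followup_end: dt.date = dt.date(2017, 4, 6)
    p_first_event: float = 0.01
    p_recurrence: float = 0.5
    recurrence_gap_days: tuple[int, int] = (45, 1500)
    p_bi_diagnosis: float = 0.3
    p_death_after_event: float = 0.15
    p_death_cause_trait: float = 0.5
    death_delay_days: tuple[int, int] = (30, 2000)
    censor_date: dt.date = dt.date(2017, 4, 6)
    gap_days: int = 30
    background_rate: float = 0.2  # unrelated diagnoses per participant-year
    p_noise_trait_record: float = 0.3
    boundary_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        for p in (self.p_first_event, self.p_recurrence, self.p_bi_diagnosis,
                  self.p_death_after_event, self.p_death_cause_trait,
                  self.p_noise_trait_record, self.boundary_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.followup_end <= self.followup_start:
            raise ValueError("follow-up span is empty")
        if self.censor_date < self.followup_start:
            raise ValueError("censor_date precedes follow-up")
        if self.recurrence_gap_days[0] <= self.gap_days:
            raise ValueError("recurrence gap lower bound must exceed the event gap")


def _trait_code(rng: np.random.Generator, trait: str) -> tuple[int, str]:
    return _TRAIT_EVENT_CODES[trait][rng.integers(len(_TRAIT_EVENT_CODES[trait]))]


def gen_registry(
    config: RegistrySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate diagnosis and death registries with planted truth labels.

    Returns ``(diagnoses, vitals, truth)``.  Truth labels are in
    ``{control, single, recurrent, excluded_death, excluded_censor}`` and are
    assigned from the planted event structure, not by re-running the
    classifier.  Noise records (secondary-role duplicates within the event
    gap, unrelated background diagnoses) are placed so they can never create
    or destroy a counted event.
    """
    rng = np.random.default_rng(config.seed)
    trait_def = TRAITS[config.trait]
    window = trait_def.relapse_window_years
    span_days = (config.followup_end - config.followup_start).days
    years = span_days / 365.25
    p_any_first = 1.0 - (1.0 - config.p_first_event) ** years

    diag_rows: list[tuple] = []
    vital_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    n_boundary = int(round(config.boundary_fraction * config.n_participants))

    for i in range(config.n_participants):
        pid = f"P{i:06d}"
        forbidden_days: set[dt.date] = set()  # sole-diagnosis days; keep clear
        event_days: list[dt.date] = []
        death_date: dt.date | None = None
        death_of_trait = False

        if i < n_boundary:
            kind = i % 4
            base = config.followup_start + dt.timedelta(
                days=int(rng.integers(0, max(span_days - 40 * 365, 365)))
            )
            if kind == 0:
                # exactly-30-day gap: second record must NOT count
                event_days = [base]
                extra = [(base + dt.timedelta(days=config.gap_days), "main")]
            elif kind == 1:
                # gap of exactly gap_days+1: second record counts
                event_days = [base, base + dt.timedelta(days=config.gap_days + 1)]
                extra = []
            elif kind == 2:
                # single event exactly at the relapse-window boundary: survives
                first = config.censor_date
                for _ in range(window):  # invert add_years, watching 29 Feb
                    first = add_years(first, -1)
                while add_years(first, window) > config.censor_date:
                    first -= dt.timedelta(days=1)
                while add_years(first + dt.timedelta(days=1), window) <= config.censor_date:
                    first += dt.timedelta(days=1)
                event_days = [first]
                extra = []
            else:
                # single event one day inside the window: excluded (censored)
                first = config.censor_date
                for _ in range(window):
                    first = add_years(first, -1)
                while add_years(first, window) > config.censor_date:
                    first -= dt.timedelta(days=1)
                event_days = [first + dt.timedelta(days=1)]
                extra = []
            for day, role in extra:
                ver, code = _trait_code(rng, config.trait)
                diag_rows.append((pid, day, ver, code, role))
        elif rng.random() < p_any_first:
            first = config.followup_start + dt.timedelta(days=int(rng.integers(0, span_days + 1)))
            event_days = [first]
            if rng.random() < config.p_recurrence:
                gap = int(rng.integers(*config.recurrence_gap_days))
                second = first + dt.timedelta(days=gap)
                if second <= config.followup_end:
                    event_days.append(second)
            if rng.random() < config.p_death_after_event:
                delay = int(rng.integers(*config.death_delay_days))
                cand = event_days[-1] + dt.timedelta(days=delay)
                if cand <= config.censor_date:
                    death_date = cand
                    death_of_trait = rng.random() < config.p_death_cause_trait

        # emit counted-event records
        for j, day in enumerate(event_days):
            ver, code = _trait_code(rng, config.trait)
            if j == 0:
                role = "bi" if rng.random() < config.p_bi_diagnosis else "main"
                diag_rows.append((pid, day, ver, code, role))
                if role == "bi" and rng.random() < 0.5:
                    bver, bcode = _BACKGROUND_CODES[rng.integers(len(_BACKGROUND_CODES))]
                    diag_rows.append((pid, day, bver, bcode, "bi"))
                else:
                    forbidden_days.add(day)
            else:
                if rng.random() < config.p_bi_diagnosis:
                    diag_rows.append((pid, day, ver, code, "bi"))
                    forbidden_days.add(day)  # must stay the sole record that day
                else:
                    diag_rows.append((pid, day, ver, code, "main"))

        # inert noise trait records: within the gap after a counted event,
        # never before the first event, never on a protected sole day
        if event_days and rng.random() < config.p_noise_trait_record:
            anchor = event_days[rng.integers(len(event_days))]
            day = anchor + dt.timedelta(days=int(rng.integers(1, config.gap_days + 1)))
            if day not in forbidden_days and (death_date is None or day <= death_date):
                ver, code = _trait_code(rng, config.trait)
                diag_rows.append((pid, day, ver, code, "main" if rng.random() < 0.5 else "bi"))

        # background diagnoses of unrelated conditions
        n_bg = rng.poisson(config.background_rate * years)
        end = death_date or config.followup_end
        bg_span = (end - config.followup_start).days
        for _ in range(n_bg):
            day = config.followup_start + dt.timedelta(days=int(rng.integers(0, bg_span + 1)))
            if day in forbidden_days:
                continue
            ver, code = _BACKGROUND_CODES[rng.integers(len(_BACKGROUND_CODES))]
            diag_rows.append((pid, day, ver, code, "bi" if rng.random() < 0.5 else "main"))

        # vital registry row
        if death_date is not None:
            if death_of_trait:
                ver, code = _trait_code(rng, config.trait)
                causes = f"{ver}:{code}"
            else:
                ver, code = _OTHER_CAUSE_CODES[rng.integers(len(_OTHER_CAUSE_CODES))]
                causes = f"{ver}:{code}"
            vital_rows.append((pid, death_date.isoformat(), causes))
        else:
            vital_rows.append((pid, "", ""))

        # truth label by construction
        n_events = len(event_days)
        if n_events == 0:
            label = "control"
        elif n_events >= 2:
            label = "recurrent"
        else:
            boundary = add_years(event_days[0], window)
            if death_date is not None and death_of_trait:
                label = "excluded_death"
            elif death_date is not None and death_date < boundary:
                label = "excluded_death"
            elif config.censor_date < boundary:
                label = "excluded_censor"
            else:
                label = "single"
        truth_rows.append(
            (pid, label, n_events, event_days[0].isoformat() if event_days else "")
        )

    diagnoses = pd.DataFrame(
        diag_rows, columns=["participant_id", "date", "icd_version", "code", "role"]
    )
    diagnoses["date"] = diagnoses["date"].astype(str)
    diagnoses = diagnoses.sort_values(
        ["participant_id", "date", "role", "code"], kind="mergesort"
    ).reset_index(drop=True)
    vitals = pd.DataFrame(vital_rows, columns=["participant_id", "death_date", "cause_codes"])
    truth = pd.DataFrame(
        truth_rows, columns=["participant_id", "label", "n_events", "first_event_date"]
    )
    return diagnoses, vitals, truth


# ---------------------------------------------------------------------------
# Two-cohort GWAS summary statistics
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class SummarySimConfig:
    """Conditions for a pair of cohort summary-statistics tables.

    Planted regions are ``(chromosome, position, beta, n_causal)`` tuples.
    Causal variants of a region sit within 50 kb of its position.
    ``rare_in_b_fraction`` of causal variants are made effectively
    monomorphic in cohort B (minor allele count below the QC threshold), so
    downstream they survive only through cohort A — the single-cohort
    pattern a meta-analysis reports with a ``?`` in its direction string.
    """

    n_variants: int = 5000
    n_chromosomes: int = 4
    chrom_length: int = 200_000_000
    shared_regions: Sequence[tuple[int, int, float, int]] = ()
    single_only_regions: Sequence[tuple[int, int, float, int]] = ()
    recurrent_only_regions: Sequence[tuple[int, int, float, int]] = ()
    maf_range: tuple[float, float] = (0.01, 0.5)
    causal_maf_range: tuple[float, float] = (0.1, 0.5)
    n_cases_a: int = 4000
    n_controls_a: int = 20000
    n_cases_b: int = 8000
    n_controls_b: int = 40000
    rare_in_b_fraction: float = 0.0
    allele_swap_fraction: float = 0.15
    low_info_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be non-negative")
        for n in (self.n_cases_a, self.n_controls_a, self.n_cases_b, self.n_controls_b):
            if n <= 0:
                raise ValueError("case/control counts must be positive")
        if not (0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        regions = self.all_regions()
        for (c1, p1, *_), (c2, p2, *_) in itertools.combinations(regions, 2):
            if c1 == c2 and abs(p1 - p2) < 1_000_000:
                raise ValueError(
                    f"planted regions at chr{c1}:{p1} and chr{c2}:{p2} are closer "
                    "than 1 Mb; truth regions would not be separable"
                )
        for chrom, pos, beta, _ in regions:
            if not (1 <= chrom <= self.n_chromosomes) or not (1 <= pos <= self.chrom_length):
                raise ValueError(f"region chr{chrom}:{pos} outside chromosome bounds")
            if not np.isfinite(beta):
                raise ValueError("effect sizes must be finite")

    def all_regions(self) -> list[tuple[int, int, float, int]]:
        return (
            list(self.shared_regions)
            + list(self.single_only_regions)
            + list(self.recurrent_only_regions)
        )


def _n_eff(n_cases: int, n_controls: int) -> float:
    return n_cases * n_controls / (n_cases + n_controls)


def _variant_scaffold(config: SummarySimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Positions, alleles, base MAFs and true effects shared by both cohorts."""
    rows = []
    regions = (
        [(r, "shared") for r in config.shared_regions]
        + [(r, "single") for r in config.single_only_regions]
        + [(r, "recurrent") for r in config.recurrent_only_regions]
    )
    per_chrom = max(config.n_variants // max(config.n_chromosomes, 1), 0)
    for chrom in range(1, config.n_chromosomes + 1):
        pos = np.sort(rng.integers(1, config.chrom_length, size=per_chrom))
        for p in pos:
            rows.append((chrom, int(p), 0.0, "", -1))
    for ridx, ((chrom, center, beta, n_causal), label) in enumerate(regions):
        offsets = np.linspace(-50_000, 50_000, max(n_causal, 1)).astype(int)
        for off in offsets[:n_causal]:
            rows.append((chrom, int(center + off), float(beta), label, ridx))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "beta_true", "region_label", "region_id"])
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df = df.drop_duplicates(["chrom", "pos"], keep="last").reset_index(drop=True)
    n = len(df)
    causal = df["region_id"].to_numpy() >= 0
    maf = rng.uniform(*config.maf_range, size=n)
    maf[causal] = rng.uniform(*config.causal_maf_range, size=causal.sum())
    df["maf_base"] = maf
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[alt_idx]
    # mark the rare-in-B causal subset
    df["rare_in_b"] = False
    if config.rare_in_b_fraction > 0 and causal.any():
        idx = np.flatnonzero(causal)
        k = int(round(config.rare_in_b_fraction * len(idx)))
        chosen = rng.choice(idx, size=k, replace=False)
        df.loc[chosen, "rare_in_b"] = True
    df["swap_in_b"] = rng.random(n) < config.allele_swap_fraction
    df["low_info"] = (rng.random(n) < config.low_info_fraction) & ~causal
    return df


def _cohort_table(
    scaffold: pd.DataFrame,
    cohort: str,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    rare_here: np.ndarray,
    swap_here: np.ndarray,
) -> pd.DataFrame:
    n = len(scaffold)
    n_total = n_cases + n_controls
    maf = scaffold["maf_base"].to_numpy() * np.clip(rng.normal(1.0, 0.03, size=n), 0.5, 1.5)
    maf = np.clip(maf, 1e-4, 0.5)
    # effectively monomorphic here: minor allele count below any QC threshold
    maf[rare_here] = 0.5 / (2 * n_total)
    neff = _n_eff(n_cases, n_controls)
    se = 1.0 / np.sqrt(2.0 * neff * maf * (1.0 - maf))
    beta = scaffold["beta_true"].to_numpy() + se * rng.standard_normal(n)
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(beta / se))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    info = rng.uniform(0.85, 1.0, size=n)
    info[scaffold["low_info"].to_numpy()] = rng.uniform(0.05, 0.29, size=int(scaffold["low_info"].sum()))
    mac = np.round(2 * n_total * maf).astype(int)
    ref = scaffold["ref"].to_numpy().copy()
    alt = scaffold["alt"].to_numpy().copy()
    out_beta = beta.copy()
    if swap_here.any():
        ref[swap_here], alt[swap_here] = alt[swap_here].copy(), ref[swap_here].copy()
        out_beta[swap_here] = -out_beta[swap_here]
    return pd.DataFrame(
        {
            "CHR": scaffold["chrom"].to_numpy(),
            "POS": scaffold["pos"].to_numpy(),
            "REF": ref,
            "ALT": alt,
            "BETA": out_beta,
            "SE": se,
            "PVAL": p,
            "MAF": maf,
            "MAC": mac,
            "INFO": info,
            "N": n_total,
            "COHORT": cohort,
        }
    )


def gen_cohort_pair_summaries(
    config: SummarySimConfig,
    active_labels: Sequence[str] = ("shared", "single", "recurrent"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate summary statistics for two cohorts plus the truth region map.

    ``active_labels`` selects which planted region groups carry their effect
    in this analysis (regions outside the set are generated as null), so one
    scaffold can feed the single-event, recurrent-event and full analyses of
    the same synthetic genome via :func:`gen_analysis_suite`.

    Returns ``(cohort_a, cohort_b, truth)`` where truth lists every planted
    region with its label, effect, causal-variant keys and rare-in-B flag.
    """
    rng = np.random.default_rng(config.seed)
    scaffold = _variant_scaffold(config, rng)
    if len(scaffold) == 0:
        empty = pd.DataFrame(
            columns=["CHR", "POS", "REF", "ALT", "BETA", "SE", "PVAL", "MAF", "MAC", "INFO", "N", "COHORT"]
        )
        return empty, empty.copy(), pd.DataFrame(
            columns=["region_id", "label", "chrom", "position", "beta", "n_causal", "rare_in_b"]
        )
    active = scaffold.copy()
    inactive = ~active["region_label"].isin(list(active_labels))
    active.loc[inactive, "beta_true"] = 0.0
    rare = active["rare_in_b"].to_numpy()
    swap = active["swap_in_b"].to_numpy()
    none = np.zeros(len(active), dtype=bool)
    a = _cohort_table(active, "A", config.n_cases_a, config.n_controls_a, rng, none, none)
    b = _cohort_table(active, "B", config.n_cases_b, config.n_controls_b, rng, rare, swap)

    truth_rows = []
    regions = (
        [(r, "shared") for r in config.shared_regions]
        + [(r, "single") for r in config.single_only_regions]
        + [(r, "recurrent") for r in config.recurrent_only_regions]
    )
    for ridx, ((chrom, center, beta, n_causal), label) in enumerate(regions):
        members = scaffold[scaffold["region_id"] == ridx]
        truth_rows.append(
            {
                "region_id": ridx,
                "label": label,
                "chrom": chrom,
                "position": center,
                "beta": beta,
                "n_causal": n_causal,
                "rare_in_b": bool(members["rare_in_b"].all()) if len(members) else False,
                "causal_keys": [
                    (int(r.chrom), int(r.pos)) for r in members.itertuples()
                ],
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["region_id", "label", "chrom", "position", "beta", "n_causal", "rare_in_b", "causal_keys"],
    )
    return a, b, truth


def gen_analysis_suite(
    config: SummarySimConfig,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Cohort pairs for the single, recurrent and full analyses of one genome.

    The three analyses share variant positions, alleles and frequencies
    (derived from ``config.seed``) but draw independent sampling noise.  The
    full analysis carries the effects of every planted region, emulating an
    all-cases-vs-controls scan.
    """
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    specs = {
        "single": ("shared", "single"),
        "recurrent": ("shared", "recurrent"),
        "full": ("shared", "single", "recurrent"),
    }
    for i, (name, labels) in enumerate(specs.items()):
        cfg = SummarySimConfig(**{**config.__dict__, "seed": config.seed * 4 + i + 1})
        # keep the scaffold identical across analyses: re-derive with base seed
        rng = np.random.default_rng(config.seed)
        scaffold = _variant_scaffold(cfg, rng)
        noise_rng = np.random.default_rng((config.seed * 4 + i + 1) % (2**31))
        active = scaffold.copy()
        active.loc[~active["region_label"].isin(labels), "beta_true"] = 0.0
        rare = active["rare_in_b"].to_numpy()
        swap = active["swap_in_b"].to_numpy()
        none = np.zeros(len(active), dtype=bool)
        a = _cohort_table(active, "A", cfg.n_cases_a, cfg.n_controls_a, noise_rng, none, none)
        b = _cohort_table(active, "B", cfg.n_cases_b, cfg.n_controls_b, noise_rng, rare, swap)
        out[name] = (a, b)
    return out


# ---------------------------------------------------------------------------
# Phenome table
# ---------------------------------------------------------------------------

_PHEWAS_CATEGORIES = [
    "circulatory system", "endocrine/metabolic", "respiratory", "digestive",
    "genitourinary", "musculoskeletal", "neurological", "mental disorders",
    "dermatologic", "hematopoietic", "infectious diseases", "neoplasms",
    "sense organs", "injuries & poisonings", "symptoms", "pregnancy", "congenital",
]


def gen_phenome_table(
    n_phenocodes: int,
    snps: Sequence[str],
    planted: Sequence[tuple[str, int, float]] = (),
    seed: int = 0,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format phenome association table (PHENOCODE, CATEGORY, SNP, BETA, PVAL).

    Unplanted cells draw p uniformly on (0, 1); each planted
    ``(snp, phenocode_index, p)`` cell carries exactly the requested p-value.
    """
    if n_phenocodes <= 0:
        raise ValueError("n_phenocodes must be positive")
    cats = list(categories) if categories is not None else _PHEWAS_CATEGORIES
    rng = np.random.default_rng(seed)
    codes = [f"PC{i:04d}" for i in range(n_phenocodes)]
    code_cat = {c: cats[i % len(cats)] for i, c in enumerate(codes)}
    n_cells = n_phenocodes * len(snps)
    p = rng.uniform(np.finfo(float).tiny, 1.0, size=n_cells)
    beta = rng.normal(0.0, 0.05, size=n_cells)
    df = pd.DataFrame(
        {
            "PHENOCODE": np.repeat(codes, len(snps)),
            "SNP": np.tile(np.asarray(snps, dtype=object), n_phenocodes),
            "BETA": beta,
            "PVAL": p,
        }
    )
    df["CATEGORY"] = df["PHENOCODE"].map(code_cat)
    df = df[["PHENOCODE", "CATEGORY", "SNP", "BETA", "PVAL"]]
    idx = df.set_index(["SNP", "PHENOCODE"]).index
    for snp, code_i, pval in planted:
        if not (0 < pval <= 1):
            raise ValueError("planted p-values must lie in (0, 1]")
        if not (0 <= code_i < n_phenocodes):
            raise ValueError(f"planted phenocode index {code_i} out of range")
        where = idx.get_indexer([(snp, codes[code_i])])
        if where[0] < 0:
            raise ValueError(f"planted SNP {snp!r} not in snps")
        df.iloc[where[0], df.columns.get_loc("PVAL")] = pval
    return df


# ---------------------------------------------------------------------------
# Expression panels
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimConfig:
    """Conditions for multi-tissue expression panels with planted modules.

    Each target gene anchors a module of ``module_size`` neighbor genes whose
    pairwise correlation with the target is ``module_cor``.  Consecutive
    target pairs share ``shared_neighbor_overlap`` of their module genes;
    shared genes correlate at the module level with *both* targets, which
    requires the pair's latent factors to correlate at ``2·module_cor − 1``
    (hence ``module_cor ≥ 0.5`` whenever overlap is requested).  Modules are
    planted identically in every tissue; samples are drawn independently per
    tissue.
    """

    n_genes: int = 300
    n_samples_per_tissue: int = 200
    n_tissues: int = 7
    target_genes: Sequence[str] = ("TG01", "TG02")
    module_size: int = 25
    module_cor: float = 0.9
    background_cor: float = 0.0
    shared_neighbor_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_cor < self.module_cor < 1.0):
            raise ValueError("need 0 <= background_cor < module_cor < 1")
        if self.module_size < 1 or self.n_tissues < 1:
            raise ValueError("module_size and n_tissues must be >= 1")
        if self.module_size * len(self.target_genes) > self.n_genes:
            raise ValueError("planted modules exceed the gene universe")
        if self.shared_neighbor_overlap > 0 and self.module_cor < 0.5:
            raise ValueError("shared neighbors require module_cor >= 0.5")
        if not (0.0 <= self.shared_neighbor_overlap <= 1.0):
            raise ValueError("shared_neighbor_overlap must lie in [0, 1]")


def gen_expression_panels(
    config: ExpressionSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-tissue gene × sample expression matrices plus truth membership.

    Returns ``(panels, truth)`` where ``panels`` maps tissue name to a
    genes-by-samples DataFrame and ``truth`` lists, per (target, tissue), the
    planted neighbor genes and whether each is shared with the paired target.
    """
    rng = np.random.default_rng(config.seed)
    targets = list(config.target_genes)
    n_targets = len(targets)
    c = config.module_cor
    b = config.background_cor
    s = max(2 * c - 1, 0.0)
    n_shared = int(round(config.shared_neighbor_overlap * config.module_size))

    # assign gene identifiers: targets, module members, background
    n_module_genes = 0
    membership: list[tuple[str, str, bool]] = []  # (gene, target, shared?)
    gene_names: list[str] = list(targets)
    pair_of: dict[int, int] = {}
    for t in range(0, n_targets - 1, 2):
        pair_of[t] = t + 1
        pair_of[t + 1] = t
    counter = 0
    shared_genes_of_pair: dict[tuple[int, int], list[str]] = {}
    for t, target in enumerate(targets):
        mate = pair_of.get(t)
        own = config.module_size
        shared_here: list[str] = []
        if mate is not None and n_shared > 0:
            key = (min(t, mate), max(t, mate))
            if key not in shared_genes_of_pair:
                shared_genes_of_pair[key] = [
                    f"SH{key[0]:02d}_{j:03d}" for j in range(n_shared)
                ]
                gene_names.extend(shared_genes_of_pair[key])
            shared_here = shared_genes_of_pair[key]
            own = config.module_size - n_shared
        own_genes = [f"MG{t:02d}_{j:03d}" for j in range(own)]
        gene_names.extend(own_genes)
        n_module_genes += own
        for g in own_genes:
            membership.append((g, target, False))
        for g in shared_here:
            membership.append((g, target, True))
    n_bg = config.n_genes - len(gene_names)
    if n_bg < 0:
        raise ValueError("planted modules exceed the gene universe")
    bg_genes = [f"BG{j:04d}" for j in range(n_bg)]
    gene_names.extend(bg_genes)

    panels: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for w in range(config.n_tissues):
        tissue = f"tissue_{w:02d}"
        m = config.n_samples_per_tissue
        g_global = rng.standard_normal(m)
        # latent pair factors h, per-target factors f_t = sqrt(s) h + sqrt(1-s) u_t
        f = {}
        h_of_pair: dict[tuple[int, int], np.ndarray] = {}
        for t in range(n_targets):
            mate = pair_of.get(t)
            if mate is not None:
                key = (min(t, mate), max(t, mate))
                if key not in h_of_pair:
                    h_of_pair[key] = rng.standard_normal(m)
                h = h_of_pair[key]
                f[t] = np.sqrt(s) * h + np.sqrt(1 - s) * rng.standard_normal(m)
            else:
                f[t] = rng.standard_normal(m)
        data = np.empty((len(gene_names), m))
        row_of = {g: i for i, g in enumerate(gene_names)}
        for t, target in enumerate(targets):
            data[row_of[target]] = np.sqrt(c) * f[t] + np.sqrt(1 - c) * rng.standard_normal(m)
        for key, genes in shared_genes_of_pair.items():
            h = h_of_pair[key]
            f1, f2 = f[key[0]], f[key[1]]
            norm = np.sqrt(2 + 2 * s)
            for g in genes:
                shared_sig = (f1 + f2) / norm
                data[row_of[g]] = np.sqrt(c) * shared_sig + np.sqrt(1 - c) * rng.standard_normal(m)
        for g, target, is_shared in membership:
            if is_shared:
                continue
            t = targets.index(target)
            data[row_of[g]] = np.sqrt(c) * f[t] + np.sqrt(1 - c) * rng.standard_normal(m)
        for g in bg_genes:
            data[row_of[g]] = (
                np.sqrt(b) * g_global + np.sqrt(1 - b) * rng.standard_normal(m)
            )
        cols = [f"{tissue}_S{j:04d}" for j in range(m)]
        panels[tissue] = pd.DataFrame(data, index=gene_names, columns=cols)
        for g, target, is_shared in membership:
            truth_rows.append((target, g, tissue, is_shared))
    truth = pd.DataFrame(truth_rows, columns=["target", "neighbor", "tissue", "shared"])
    return panels, truth


# ---------------------------------------------------------------------------
# Individual-level genotype cohorts
# ---------------------------------------------------------------------------


def gen_genotype_cohort(
    n: int,
    n_snps: int,
    planted_effects: Mapping[int, float] | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    prevalence: float = 0.3,
    covariate_effects: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Simulate genotypes, binary phenotype and covariates for one cohort.

    Genotypes are Hardy–Weinberg draws at uniform MAFs; the phenotype follows
    a logistic model with the planted per-SNP log-odds effects plus covariate
    effects on birth year, sex, batch and four principal-component stand-ins.

    Returns ``(genotypes, labels, covariates, variant_meta)``.
    """
    if n <= 0 or n_snps <= 0:
        raise ValueError("n and n_snps must be positive")
    planted_effects = dict(planted_effects or {})
    if covariate_effects is None:
        covariate_effects = {
            "birth_year_std": -0.2, "sex": 0.3, "batch": 0.1,
            "pc1": 0.1, "pc2": -0.1, "pc3": 0.05, "pc4": -0.05,
        }
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_snps)
    genotypes = rng.binomial(2, maf[None, :], size=(n, n_snps)).astype(np.int8)
    covariates = pd.DataFrame(
        {
            "birth_year_std": rng.normal(0.0, 1.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "batch": rng.integers(0, 2, size=n).astype(float),
            "pc1": rng.normal(0.0, 1.0, size=n),
            "pc2": rng.normal(0.0, 1.0, size=n),
            "pc3": rng.normal(0.0, 1.0, size=n),
            "pc4": rng.normal(0.0, 1.0, size=n),
        }
    )
    eta = np.full(n, np.log(prevalence / (1 - prevalence)))
    for j, beta in planted_effects.items():
        eta = eta + beta * (genotypes[:, j] - 2 * maf[j])
    for name, gamma in covariate_effects.items():
        col = covariates[name].to_numpy()
        eta = eta + gamma * (col - col.mean())
    labels = pd.Series(rng.random(n) < expit(eta), name="case").astype(int)
    variant_meta = pd.DataFrame(
        {
            "CHR": np.ones(n_snps, dtype=int),
            "POS": (np.arange(n_snps) + 1) * 10_000,
            "REF": _BASES[rng.integers(0, 4, size=n_snps)],
            "ALT": "",
            "MAF": maf,
        }
    )
    ref_idx = np.array([list("ACGT").index(r) for r in variant_meta["REF"]])
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    variant_meta["ALT"] = _BASES[alt_idx]
    variant_meta["beta_true"] = [planted_effects.get(j, 0.0) for j in range(n_snps)]
    return genotypes, labels, covariates, variant_meta
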