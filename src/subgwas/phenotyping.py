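"""Recurrent-event phenotyping from longitudinal diagnosis registries.

Participants are classified, per cardiovascular trait (atrial fibrillation or
myocardial infarction), into four groups from hospital diagnosis records and a
death registry:

* ``control`` — no qualifying event of *either* trait;
* ``single`` — exactly one qualifying event, surviving a trait-specific
  relapse window before death/censoring;
* ``recurrent`` — two or more qualifying events separated by more than a
  configurable gap (default strictly more than 30 days);
* ``excluded`` — a single event too close to death or the end of registry
  coverage to rule out an unobserved relapse, or death caused by the trait.

Events are counted from ICD-9/ICD-10 codes registered with a *main* (primary)
or *bi* (secondary) diagnosis role.  The first event counts regardless of
role; later records only open a new event when they are more than the gap
apart from the last counted event and are either a main diagnosis or the sole
diagnosis recorded for that participant on that day.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAIN = "main"
BI = "bi"

LABELS = ("control", "single", "recurrent", "excluded", "other")
EXCLUSION_REASONS = (
    "none",
    "died_of_phenotype",
    "died_within_window",
    "censored_within_window",
)


class DataIntegrityError(ValueError):
    """Raised when registry rows contradict each other (e.g. events after death)."""


# ---------------------------------------------------------------------------
# Trait definitions and ICD code matching
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^([A-Z]?)(\d+)(?:\.(\d+))?-\1?(\d+)$")


def expand_code_range(spec: str) -> list[str]:
    """Expand a code-range spec like ``"I21-I24"`` or ``"401-405"`` to prefixes.

    Plain codes pass through unchanged; only integer root ranges are expanded.
    """
    spec = spec.strip().upper()
    m = _RANGE_RE.match(spec)
    if not m:
        return [spec]
    letter, lo, frac, hi = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    if frac is not None or hi < lo:
        raise ValueError(f"cannot expand code range {spec!r}")
    width = len(m.group(2))
    return [f"{letter}{i:0{width}d}" for i in range(lo, hi + 1)]


def _normalize_code(code: str) -> str:
    return code.strip().upper().replace(".", "").replace(" ", "")


@dataclass(frozen=True)
class TraitDefinition:
    """A trait phenotype: its ICD code prefixes and relapse window.

    ``relapse_window_years`` is the time span within which most second events
    occur; single-event participants whose event falls inside this window
    before death or censoring are excluded as potentially misclassified.
    """

    name: str
    icd10_codes: Sequence[str]
    icd9_codes: Sequence[str]
    relapse_window_years: int

    _icd10_prefixes: tuple[str, ...] = field(init=False, repr=False, compare=False)
    _icd9_prefixes: tuple[str, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.icd10_codes or not self.icd9_codes:
            raise ValueError("code prefix lists must be non-empty")
        if self.relapse_window_years <= 0:
            raise ValueError("relapse_window_years must be positive")
        object.__setattr__(
            self,
            "_icd10_prefixes",
            tuple(_normalize_code(p) for c in self.icd10_codes for p in expand_code_range(c)),
        )
        object.__setattr__(
            self,
            "_icd9_prefixes",
            tuple(_normalize_code(p) for c in self.icd9_codes for p in expand_code_range(c)),
        )


AF = TraitDefinition("AF", icd10_codes=["I48"], icd9_codes=["427.3"], relapse_window_years=5)
MI = TraitDefinition("MI", icd10_codes=["I21-I24"], icd9_codes=["410"], relapse_window_years=7)

TRAITS: Mapping[str, TraitDefinition] = {"AF": AF, "MI": MI}


def matches_trait(icd_version: int, code: str, trait: TraitDefinition) -> bool:
    """True iff ``code`` (or any ancestor prefix of it) is a trait code.

    Matching is prefix-based after stripping dots, so ICD-9 ``427.31`` matches
    the AF root ``427.3`` and ICD-10 ``I21.4`` matches the MI range I21-I24.
    """
    if not code:
        raise ValueError("empty diagnosis code")
    if icd_version == 10:
        prefixes = trait._icd10_prefixes
    elif icd_version == 9:
        prefixes = trait._icd9_prefixes
    else:
        raise ValueError(f"unknown ICD version {icd_version!r}")
    norm = _normalize_code(code)
    return any(norm.startswith(p) for p in prefixes)


# ---------------------------------------------------------------------------
# Records and events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosisRecord:
    participant_id: str
    date: dt.date
    icd_version: int
    code: str
    role: str  # "main" or "bi"


@dataclass(frozen=True)
class VitalRecord:
    participant_id: str
    death_date: dt.date | None = None
    cause_codes: tuple[tuple[int, str], ...] = ()  # (icd_version, code) pairs

    def __post_init__(self) -> None:
        if self.death_date is None and self.cause_codes:
            raise ValueError("cause_codes present without a death date")


@dataclass(frozen=True)
class ClinicalEvent:
    date: dt.date
    role_at_count: str  # "first-any", "main" or "bi-sole"


@dataclass(frozen=True)
class PhenotypeAssignment:
    participant_id: str
    trait: str
    label: str
    exclusion_reason: str
    first_event_date: dt.date | None
    n_events: int


def add_years(date: dt.date, years: int) -> dt.date:
    """Calendar-year shift; 29 Feb clamps to 28 Feb in non-leap target years."""
    try:
        return date.replace(year=date.year + years)
    except ValueError:
        return date.replace(year=date.year + years, day=28)


def extract_events(
    records: Iterable[DiagnosisRecord],
    trait: TraitDefinition,
    gap_days: int = 30,
) -> list[ClinicalEvent]:
    """Count distinct clinical events of ``trait`` for one participant.

    ``records`` must contain *all* diagnosis records of the participant (any
    code), because the sole-diagnosis criterion for secondary-role records is
    evaluated against every record of that participant-day.
    """
    records = list(records)
    if not records:
        return []
    per_day_total: dict[dt.date, int] = {}
    trait_days: dict[dt.date, bool] = {}  # date -> any main-role trait record
    for r in records:
        per_day_total[r.date] = per_day_total.get(r.date, 0) + 1
        if matches_trait(r.icd_version, r.code, trait):
            trait_days[r.date] = trait_days.get(r.date, False) or (r.role == MAIN)
    if not trait_days:
        return []
    days = sorted(trait_days)
    events = [ClinicalEvent(days[0], "first-any")]
    last = days[0]
    for day in days[1:]:
        if (day - last).days <= gap_days:
            continue
        if trait_days[day]:
            events.append(ClinicalEvent(day, MAIN))
        elif per_day_total[day] == 1:
            events.append(ClinicalEvent(day, "bi-sole"))
        else:
            continue  # bi-diagnosis alongside other records: not a new event
        last = day
    return events


def classify_participant(
    participant_id: str,
    events: Sequence[ClinicalEvent],
    vital: VitalRecord | None,
    censor_date: dt.date,
    trait: TraitDefinition,
) -> PhenotypeAssignment:
    """Assign control-candidate / single / recurrent / excluded for one trait.

    Exclusions apply only to single-event participants: death caused by the
    trait, death within the relapse window of the first event, or a censoring
    date within that window ("less than" the window is strict, so an event
    exactly at the window boundary survives).
    """
    n = len(events)
    if n == 0:
        return PhenotypeAssignment(participant_id, trait.name, "control", "none", None, 0)
    first = events[0].date
    if vital is not None and vital.death_date is not None and vital.death_date < first:
        raise DataIntegrityError(
            f"participant {participant_id}: death {vital.death_date} precedes first event {first}"
        )
    if n >= 2:
        return PhenotypeAssignment(participant_id, trait.name, "recurrent", "none", first, n)
    boundary = add_years(first, trait.relapse_window_years)
    if vital is not None and vital.death_date is not None:
        if any(matches_trait(v, c, trait) for v, c in vital.cause_codes):
            return PhenotypeAssignment(
                participant_id, trait.name, "excluded", "died_of_phenotype", first, 1
            )
        if vital.death_date < boundary:
            return PhenotypeAssignment(
                participant_id, trait.name, "excluded", "died_within_window", first, 1
            )
    if censor_date < boundary:
        return PhenotypeAssignment(
            participant_id, trait.name, "excluded", "censored_within_window", first, 1
        )
    return PhenotypeAssignment(participant_id, trait.name, "single", "none", first, 1)


def _records_from_frame(diagnoses: pd.DataFrame) -> dict[str, list[DiagnosisRecord]]:
    by_pid: dict[str, list[DiagnosisRecord]] = {}
    dates = pd.to_datetime(diagnoses["date"]).dt.date
    for pid, date, ver, code, role in zip(
        diagnoses["participant_id"], dates, diagnoses["icd_version"],
        diagnoses["code"], diagnoses["role"],
    ):
        by_pid.setdefault(str(pid), []).append(
            DiagnosisRecord(str(pid), date, int(ver), str(code), str(role))
        )
    return by_pid


def _vitals_from_frame(vitals: pd.DataFrame) -> dict[str, VitalRecord]:
    if vitals["participant_id"].duplicated().any():
        dup = vitals.loc[vitals["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise DataIntegrityError(f"duplicate participant {dup!r} in vital registry")
    out: dict[str, VitalRecord] = {}
    for _, row in vitals.iterrows():
        pid = str(row["participant_id"])
        death = row.get("death_date")
        if pd.isna(death) or death in ("", None):
            out[pid] = VitalRecord(pid)
            continue
        death_date = pd.Timestamp(death).date()
        causes: list[tuple[int, str]] = []
        raw = row.get("cause_codes", "")
        if isinstance(raw, str) and raw:
            for tok in raw.split(";"):
                ver, code = tok.split(":", 1)
                causes.append((int(ver), code))
        out[pid] = VitalRecord(pid, death_date, tuple(causes))
    return out


def assign_cohort(
    diagnoses: pd.DataFrame,
    vitals: pd.DataFrame,
    censor_date: dt.date,
    traits: Sequence[TraitDefinition] = (AF, MI),
    gap_days: int = 30,
    participants: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Classify every participant for every trait.

    The ``control`` label is granted only to participants with zero events of
    *all* traits; a participant with events of another trait is neither a case
    nor a control for this one and is labelled ``other`` (dropped from that
    trait's analyses).

    Returns a frame with one row per participant per trait: ``participant_id,
    trait, label, exclusion_reason, first_event_date, n_events``.
    """
    records = _records_from_frame(diagnoses)
    vital_map = _vitals_from_frame(vitals)
    if participants is None:
        pids = sorted(set(records) | set(vital_map))
    else:
        pids = sorted(str(p) for p in participants)
    rows = []
    event_counts: dict[str, dict[str, int]] = {}
    for pid in pids:
        recs = records.get(pid, [])
        vital = vital_map.get(pid)
        event_counts[pid] = {}
        for trait in traits:
            events = extract_events(recs, trait, gap_days=gap_days)
            event_counts[pid][trait.name] = len(events)
            rows.append(classify_participant(pid, events, vital, censor_date, trait))
    out = pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in rows],
            "trait": [a.trait for a in rows],
            "label": [a.label for a in rows],
            "exclusion_reason": [a.exclusion_reason for a in rows],
            "first_event_date": [a.first_event_date for a in rows],
            "n_events": [a.n_events for a in rows],
        }
    )
    # controls must be event-free for every trait
    any_events = {pid: sum(c.values()) > 0 for pid, c in event_counts.items()}
    mask = (out["label"] == "control") & out["participant_id"].map(any_events)
    out.loc[mask, "label"] = "other"
    for trait in traits:
        sub = out[out["trait"] == trait.name]
        logger.info(
            "%s: %s", trait.name,
            ", ".join(f"{lab}={n}" for lab, n in sub["label"].value_counts().items()),
        )
    return out


# ---------------------------------------------------------------------------
# Baseline characteristics
# ---------------------------------------------------------------------------


def compare_baseline(
    assignments: pd.DataFrame,
    characteristics: pd.DataFrame,
    trait: str,
    continuous: Sequence[str],
    binary: Sequence[str],
    alpha: float = 0.05,
    n_tests: int | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Compare baseline characteristics of single- vs recurrent-event groups.

    Continuous variables use a two-sided two-sample Student's t-test (pooled
    variance by default, Welch behind ``welch=True``); binary variables use
    Fisher's exact test.  Significance is flagged at the Bonferroni-adjusted
    level ``alpha / n_tests`` (default: the number of characteristics tested).
    Missing values are dropped per characteristic; a continuous test with
    fewer than two non-missing values in a group is reported as
    not-computable (NaN) rather than raising.
    """
    n_tests = n_tests if n_tests is not None else len(continuous) + len(binary)
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    adj_alpha = alpha / n_tests
    sub = assignments[(assignments["trait"] == trait)]
    single_ids = set(sub.loc[sub["label"] == "single", "participant_id"])
    recur_ids = set(sub.loc[sub["label"] == "recurrent", "participant_id"])
    chars = characteristics.set_index(characteristics["participant_id"].astype(str))
    g1 = chars.loc[chars.index.isin(single_ids)]
    g2 = chars.loc[chars.index.isin(recur_ids)]

    rows = []
    for col in continuous:
        a = pd.to_numeric(g1[col], errors="coerce").dropna()
        b = pd.to_numeric(g2[col], errors="coerce").dropna()
        if len(a) < 2 or len(b) < 2:
            stat, p = np.nan, np.nan
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "characteristic": col, "kind": "continuous",
                "single_mean": a.mean() if len(a) else np.nan,
                "single_sd": a.std(ddof=1) if len(a) > 1 else np.nan,
                "recurrent_mean": b.mean() if len(b) else np.nan,
                "recurrent_sd": b.std(ddof=1) if len(b) > 1 else np.nan,
                "statistic": stat, "p": p,
            }
        )
    for col in binary:
        a = pd.to_numeric(g1[col], errors="coerce").dropna().astype(int)
        b = pd.to_numeric(g2[col], errors="coerce").dropna().astype(int)
        table = np.array(
            [[(a == 1).sum(), (a == 0).sum()], [(b == 1).sum(), (b == 0).sum()]]
        )
        if table.sum() == 0:
            odds, p = np.nan, np.nan
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "characteristic": col, "kind": "binary",
                "single_mean": a.mean() if len(a) else np.nan,
                "single_sd": np.nan,
                "recurrent_mean": b.mean() if len(b) else np.nan,
                "recurrent_sd": np.nan,
                "statistic": odds, "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_alpha"] = adj_alpha
    out["significant"] = out["p"] < adj_alpha
    return out


def bonferroni_alpha(alpha: float = 0.05, n_tests: int = 8) -> float:
    """Per-test significance level for the baseline comparison (0.05/8 by default)."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests
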