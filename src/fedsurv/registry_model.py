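"""Registry records, cohort selection, and covariate derivation.

A registry extract is one row per tumour: ICD-O-3 topography and morphology
codes, diagnosis and end-of-follow-up dates, vital status and the clinical
attributes used as prognostic factors. This module turns raw records into
the analysis cohort: it applies the oral-cavity-cancer inclusion filters,
derives the (time, event) survival outcome with follow-up expressed in years
to one decimal, bins the clinical attributes into the categorical levels
used by the regression models, computes annual hospital surgical volume, and
encodes cohort rows into a dummy-coded design matrix from a model
specification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "CovariateBlock",
    "ModelSpec",
    "DEFAULT_CUTOFF",
    "COHORT_COLUMNS",
    "select_cohort",
    "derive_survival",
    "categorize",
    "compute_hospital_volume",
    "build_cohort",
    "build_design_matrix",
    "multivariable_spec",
    "read_patient_table",
    "write_cohort_table",
]

# Information horizon for vital status: follow-up collected up to this date.
DEFAULT_CUTOFF = date(2019, 1, 31)

DAYS_PER_YEAR = 365.25

# Oral cavity squamous cell carcinoma site codes. Lip mucosa and hard palate
# are enumerated at 4 characters; tongue, floor of mouth/gum and buccal
# mucosa include every subsite, so they match on the 3-character stem.
TOPOGRAPHY_EXACT = {"C00.3", "C00.4", "C00.5", "C05.0", "C05.8", "C05.9"}
TOPOGRAPHY_PREFIX = {"C02", "C03", "C04", "C06"}

MORPHOLOGY_RANGE = (8050, 8089)  # squamous cell carcinoma histologies
DIAGNOSIS_YEARS = (2004, 2016)

VITAL_STATUSES = {"alive", "dead"}
SEXES = {"male", "female"}
STAGES = {"I", "II", "III", "IVA", "IVB", "IVC", "unknown"}
GRADES = {"well", "moderate", "poor_undiff", "unknown"}
TREATMENTS = {"surgery_only", "surgery_adjuvant"}

EARLY_STAGES = {"I", "II"}
ADVANCED_STAGES = {"III", "IVA", "IVB", "IVC"}

COHORT_COLUMNS = [
    "patient_id",
    "time",
    "event",
    "country",
    "age_cat",
    "sex",
    "period",
    "stage_group",
    "location",
    "grade_cat",
    "treatment",
    "volume_cat",
]


@dataclass(frozen=True)
class PatientRecord:
    """One raw registry row (one tumour)."""

    patient_id: str
    tumour_sequence: int
    topography: str
    morphology: int
    diagnosis_date: date
    vital_status: str
    end_date: date
    sex: str
    age_at_diagnosis: int
    stage: str
    grade: str
    treatment: str
    hospital_id: str
    surgery: bool

    def __post_init__(self) -> None:
        if self.end_date < self.diagnosis_date:
            raise ValueError(
                f"record {self.patient_id}: end_date {self.end_date} precedes "
                f"diagnosis_date {self.diagnosis_date}"
            )
        if not 8000 <= self.morphology <= 9999:
            raise ValueError(
                f"record {self.patient_id}: morphology {self.morphology} "
                "outside the 8000-9999 histology range"
            )
        if self.vital_status not in VITAL_STATUSES:
            raise ValueError(f"record {self.patient_id}: bad vital_status {self.vital_status!r}")
        if self.sex not in SEXES:
            raise ValueError(f"record {self.patient_id}: bad sex {self.sex!r}")
        if self.stage not in STAGES:
            raise ValueError(f"record {self.patient_id}: bad stage {self.stage!r}")
        if self.grade not in GRADES:
            raise ValueError(f"record {self.patient_id}: bad grade {self.grade!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"record {self.patient_id}: bad treatment {self.treatment!r}")


@dataclass(frozen=True)
class CovariateBlock:
    """One categorical variable: ordered levels with a reference level."""

    variable: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError(
                f"reference {self.reference!r} not among levels of {self.variable!r}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"duplicate levels in block {self.variable!r}")

    @property
    def dummy_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class ModelSpec:
    """Covariate blocks (dummy coding vs a reference level) plus optional
    country-by-factor interaction blocks."""

    covariate_blocks: tuple[CovariateBlock, ...]
    interaction_blocks: tuple[tuple[str, str], ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        names = [b.variable for b in self.covariate_blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variables in covariate_blocks")
        for left, right in self.interaction_blocks:
            if left not in names or right not in names:
                raise ValueError(
                    f"interaction ({left}, {right}) references a variable "
                    "absent from covariate_blocks"
                )

    def block(self, variable: str) -> CovariateBlock:
        for b in self.covariate_blocks:
            if b.variable == variable:
                return b
        raise KeyError(variable)

    def column_labels(self) -> list[str]:
        labels = []
        for b in self.covariate_blocks:
            labels.extend(f"{b.variable}={l}" for l in b.dummy_levels)
        for left, right in self.interaction_blocks:
            lb, rb = self.block(left), self.block(right)
            for ll in lb.dummy_levels:
                for rl in rb.dummy_levels:
                    labels.append(f"{left}={ll}:{right}={rl}")
        return labels

    @property
    def n_columns(self) -> int:
        return len(self.column_labels())

    def with_interaction(self, factor: str, country_var: str = "country") -> "ModelSpec":
        return ModelSpec(
            covariate_blocks=self.covariate_blocks,
            interaction_blocks=self.interaction_blocks + ((country_var, factor),),
            label=f"{self.label}+{country_var}x{factor}" if self.label else f"{country_var}x{factor}",
        )


def multivariable_spec() -> ModelSpec:
    """The full multivariable model: country plus eight prognostic factors,
    18 dummy-coded columns in total."""
    return ModelSpec(
        covariate_blocks=(
            CovariateBlock("country", ("TW", "NL"), "TW"),
            CovariateBlock("age_cat", ("lt60", "60_69", "ge70"), "lt60"),
            CovariateBlock("sex", ("female", "male"), "female"),
            CovariateBlock("period", ("2004_2007", "2008_2011", "2012_2016"), "2004_2007"),
            CovariateBlock("stage_group", ("early", "advanced", "unknown"), "early"),
            CovariateBlock(
                "location",
                ("tongue", "lip", "floor_gum", "hard_palate", "buccal_other"),
                "tongue",
            ),
            CovariateBlock("grade_cat", ("well", "moderate", "poor_undiff", "unknown"), "well"),
            CovariateBlock("treatment", ("surgery_only", "surgery_adjuvant"), "surgery_only"),
            CovariateBlock("volume_cat", ("ge100", "v50_99", "lt50"), "ge100"),
        ),
        label="multivariable",
    )


# ---------------------------------------------------------------------------
# Cohort selection
# ---------------------------------------------------------------------------

def _topography_included(code: str) -> bool:
    code = code.strip().upper()
    if not code.startswith("C"):
        raise ValueError(f"unparseable topography code {code!r}")
    stem = code.split(".")[0]
    if len(stem) != 3 or not stem[1:].isdigit():
        raise ValueError(f"unparseable topography code {code!r}")
    return code in TOPOGRAPHY_EXACT or stem in TOPOGRAPHY_PREFIX


def _first_failed_rule(rec: PatientRecord) -> str | None:
    try:
        topo_ok = _topography_included(rec.topography)
    except ValueError:
        return "unparseable_topography"
    if not topo_ok:
        return "topography_not_oral_cavity"
    if not MORPHOLOGY_RANGE[0] <= rec.morphology <= MORPHOLOGY_RANGE[1]:
        return "morphology_not_scc"
    if not DIAGNOSIS_YEARS[0] <= rec.diagnosis_date.year <= DIAGNOSIS_YEARS[1]:
        return "diagnosis_year_out_of_window"
    if not rec.surgery:
        return "no_surgery"
    if rec.tumour_sequence != 1:
        return "not_first_primary"
    return None


def select_cohort(
    records: list[PatientRecord],
    exclusion_log: dict[str, str] | None = None,
) -> list[PatientRecord]:
    """Apply the inclusion filters and keep at most one tumour per patient.

    Keeps records with an included oral-cavity topography code, squamous-cell
    morphology (8050-8089), diagnosis year 2004-2016, surgical treatment and
    tumour sequence 1 (first primary). If several of a patient's records
    survive the filters, the earliest diagnosis is kept (ties broken by the
    smaller record order). Rejected records are written to *exclusion_log*
    as patient_id -> first failed rule, never raised.
    """
    kept: dict[str, PatientRecord] = {}
    for rec in records:
        reason = _first_failed_rule(rec)
        if reason is not None:
            if exclusion_log is not None and rec.patient_id not in kept:
                exclusion_log.setdefault(rec.patient_id, reason)
            continue
        prev = kept.get(rec.patient_id)
        if prev is None or rec.diagnosis_date < prev.diagnosis_date:
            kept[rec.patient_id] = rec
        elif exclusion_log is not None:
            exclusion_log.setdefault(rec.patient_id + "#dup", "duplicate_first_primary")
    if exclusion_log is not None:
        for pid in list(exclusion_log):
            if pid in kept:
                del exclusion_log[pid]
    return list(kept.values())


# ---------------------------------------------------------------------------
# Outcome derivation
# ---------------------------------------------------------------------------

def round_years(days: float) -> float:
    """Days -> years on a 365.25-day year, rounded half-up to one decimal."""
    years = days / DAYS_PER_YEAR
    return math.floor(years * 10.0 + 0.5) / 10.0


def derive_survival(record: PatientRecord, cutoff: date = DEFAULT_CUTOFF) -> tuple[float, int]:
    """Follow-up time (years, one decimal) and event indicator.

    Survival runs from diagnosis to death or last follow-up; the cutoff date
    is the information horizon — anything after it is administratively
    censored, so event = 1 only for deaths on or before the cutoff.
    """
    if cutoff < record.diagnosis_date:
        raise ValueError(
            f"record {record.patient_id}: cutoff {cutoff} precedes diagnosis"
        )
    end = min(record.end_date, cutoff)
    event = int(record.vital_status == "dead" and record.end_date <= cutoff)
    return round_years((end - record.diagnosis_date).days), event


# ---------------------------------------------------------------------------
# Covariate derivation
# ---------------------------------------------------------------------------

def _age_cat(age: int) -> str:
    if age < 60:
        return "lt60"
    if age < 70:
        return "60_69"
    return "ge70"


def _period(year: int) -> str:
    if year <= 2007:
        return "2004_2007"
    if year <= 2011:
        return "2008_2011"
    return "2012_2016"


def _stage_group(stage: str) -> str:
    if stage in EARLY_STAGES:
        return "early"
    if stage in ADVANCED_STAGES:
        return "advanced"
    return "unknown"


def _location(topography: str) -> str:
    code = topography.strip().upper()
    stem = code.split(".")[0]
    if code in {"C00.3", "C00.4", "C00.5"}:
        return "lip"
    if stem == "C02":
        return "tongue"
    if stem in {"C03", "C04"}:
        return "floor_gum"
    if code in {"C05.0", "C05.8", "C05.9"}:
        return "hard_palate"
    if stem == "C06":
        return "buccal_other"
    raise ValueError(f"topography {topography!r} not in the included site groups")


def categorize(record: PatientRecord) -> dict[str, str]:
    """Bin a selected record's attributes into the model's categorical levels."""
    return {
        "age_cat": _age_cat(record.age_at_diagnosis),
        "sex": record.sex,
        "period": _period(record.diagnosis_date.year),
        "stage_group": _stage_group(record.stage),
        "location": _location(record.topography),
        "grade_cat": record.grade,
        "treatment": record.treatment,
    }


def compute_hospital_volume(records: list[PatientRecord]) -> dict[tuple[str, int], str]:
    """Annual surgical volume category per (hospital, diagnosis year).

    Volume is the number of oral-cavity surgeries the treating centre
    performed in the patient's diagnosis year, computed within one registry
    from its retained records, categorized <50 / 50-99 / >=100.
    """
    counts: dict[tuple[str, int], int] = {}
    for rec in records:
        key = (rec.hospital_id, rec.diagnosis_date.year)
        counts[key] = counts.get(key, 0) + 1
    return {key: volume_category(n) for key, n in counts.items()}


def volume_category(n: int) -> str:
    if n < 50:
        return "lt50"
    if n <= 99:
        return "v50_99"
    return "ge100"


def build_cohort(
    records: list[PatientRecord],
    country: str,
    cutoff: date = DEFAULT_CUTOFF,
    exclusion_log: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Raw records of one registry -> analysis cohort table.

    Runs selection, outcome derivation, categorization and hospital-volume
    assignment; returns a DataFrame with the cohort columns. Volume is
    computed within this registry only — sites never see each other's
    records.
    """
    selected = select_cohort(records, exclusion_log=exclusion_log)
    volume = compute_hospital_volume(selected)
    rows = []
    for rec in selected:
        time, event = derive_survival(rec, cutoff)
        row = {"patient_id": rec.patient_id, "time": time, "event": event, "country": country}
        row.update(categorize(rec))
        row["volume_cat"] = volume[(rec.hospital_id, rec.diagnosis_date.year)]
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Dummy-code a cohort table per the model spec.

    One 0/1 column per non-reference level per block, in spec order;
    interaction blocks append products of the first variable's dummies with
    the second variable's dummies. Raises on a category outside a block's
    level list, naming the variable and offending rows.
    """
    n = len(cohort)
    block_dummies: dict[str, dict[str, np.ndarray]] = {}
    columns: list[np.ndarray] = []
    labels: list[str] = []
    for b in spec.covariate_blocks:
        values = cohort[b.variable].to_numpy()
        bad = ~np.isin(values, list(b.levels))
        if bad.any():
            idx = np.flatnonzero(bad)[:5]
            raise ValueError(
                f"variable {b.variable!r}: unseen level(s) "
                f"{sorted(set(values[bad]))} at rows {idx.tolist()}"
            )
        dummies = {l: (values == l).astype(float) for l in b.dummy_levels}
        block_dummies[b.variable] = dummies
        for l in b.dummy_levels:
            columns.append(dummies[l])
            labels.append(f"{b.variable}={l}")
    for left, right in spec.interaction_blocks:
        for ll, lcol in block_dummies[left].items():
            for rl, rcol in block_dummies[right].items():
                columns.append(lcol * rcol)
                labels.append(f"{left}={ll}:{right}={rl}")
    X = np.column_stack(columns) if columns else np.empty((n, 0))
    return X, labels


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "patient_id",
    "tumour_sequence",
    "topography",
    "morphology",
    "diagnosis_date",
    "vital_status",
    "end_date",
    "sex",
    "age_at_diagnosis",
    "stage",
    "grade",
    "treatment",
    "hospital_id",
    "surgery",
]


def read_patient_table(path, sep: str | None = None) -> list[PatientRecord]:
    """Read a delimited registry extract (ISO-8601 dates, header row)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                tumour_sequence=int(row.tumour_sequence),
                topography=str(row.topography),
                morphology=int(row.morphology),
                diagnosis_date=date.fromisoformat(str(row.diagnosis_date)),
                vital_status=str(row.vital_status),
                end_date=date.fromisoformat(str(row.end_date)),
                sex=str(row.sex),
                age_at_diagnosis=int(row.age_at_diagnosis),
                stage=str(row.stage),
                grade=str(row.grade),
                treatment=str(row.treatment),
                hospital_id=str(row.hospital_id),
                surgery=bool(row.surgery),
            )
        )
    return records


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
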