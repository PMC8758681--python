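"""Cohort table parsing and stratified summaries.

The cohort table records one row per tissue block (a "sample"): patient
identity, age at index diagnosis, lesion size, laterality, nuclear grade
(Low / Inter. / High), dominant histological architecture, ER and HER2
status, the number of microdissected regions profiled, and where the block
falls in the diagnostic timeline (index lesion, recurrence with a month
offset, or synchronous lesion).

Samples — not patients — are the counting unit for every stratified
summary; a patient may contribute several blocks (e.g. an index lesion and
a later recurrence).  HER2 status uses the four-level dialect of the
source table: ``+``, ``-``, ``equ`` (equivocal, called from ERBB2 copy
number/expression) and ``NA``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import IO

import pandas as pd

__all__ = [
    "CohortSample",
    "CohortTable",
    "CohortParseError",
    "parse_cohort_table",
    "serialize_cohort_table",
    "summarize_cohort",
    "count_samples_by_size",
    "count_unique_patients",
]

GRADES = ("Low", "Inter.", "High")
ARCHITECTURES = ("Cribriform", "Solid", "Micropapillary", "Mixed", "ADH")
LATERALITIES = ("Left", "Right")
ER_TOKENS = {"+": "positive", "-": "negative", "NA": "missing"}
HER2_TOKENS = {"+": "positive", "-": "negative", "equ": "equivocal", "NA": "missing"}
DIAGNOSIS_ORDERS = ("Index", "Recurrence", "Synchronous")

#: Column headers of the tab-delimited cohort table, in file order.
COLUMNS = [
    "Patient ID",
    "Block ID",
    "Age at Index",
    "Size (cm)",
    "Laterality",
    "Grade",
    "Architecture",
    "ER",
    "HER2",
    "N. of Regions",
    "Diagnosis Order",
]

STRATIFIERS = ("grade_group", "architecture", "er", "her2")


class CohortParseError(ValueError):
    """Raised when a cohort table row cannot be interpreted."""


@dataclass(frozen=True)
class CohortSample:
    """One tissue block with its clinical and pathological annotations."""

    patient_id: str
    block_id: str
    age_years: int | None
    size_cm: float | None
    laterality: str
    grade: str
    architecture: str
    er_status: str  # positive / negative / missing
    her2_status: str  # positive / negative / equivocal / missing
    n_regions: int
    diagnosis_order: str  # Index / Recurrence / Synchronous
    months_offset: int | None = None

    def __post_init__(self) -> None:
        if self.size_cm is not None and self.size_cm < 0:
            raise ValueError(f"negative size_cm for block {self.block_id}")
        if self.n_regions < 1:
            raise ValueError(f"n_regions < 1 for block {self.block_id}")

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}_{self.block_id}"

    @property
    def grade_group(self) -> str:
        """Collapse grade into the HG-DCIS / LG-DCIS / ADH grouping.

        Intermediate and high grades are pooled as HG-DCIS; low-grade
        lesions are LG-DCIS unless their architecture is ADH.
        """
        if self.grade in ("Inter.", "High"):
            return "HG-DCIS"
        return "ADH" if self.architecture == "ADH" else "LG-DCIS"


@dataclass(frozen=True)
class CohortTable:
    samples: tuple[CohortSample, ...]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": s.patient_id,
                    "block_id": s.block_id,
                    "age_years": s.age_years,
                    "size_cm": s.size_cm,
                    "laterality": s.laterality,
                    "grade": s.grade,
                    "grade_group": s.grade_group,
                    "architecture": s.architecture,
                    "er_status": s.er_status,
                    "her2_status": s.her2_status,
                    "n_regions": s.n_regions,
                    "diagnosis_order": s.diagnosis_order,
                    "months_offset": s.months_offset,
                }
                for s in self.samples
            ]
        )


_RECUR_RE = re.compile(r"^Recur\.\s*\(\+(\d+)\s*mos\.\)$")


def _parse_diagnosis(token: str, row: int) -> tuple[str, int | None]:
    token = token.strip()
    if token == "Index":
        return "Index", None
    if token == "Synchronous":
        return "Synchronous", None
    m = _RECUR_RE.match(token)
    if m:
        return "Recurrence", int(m.group(1))
    raise CohortParseError(f"row {row}: unknown diagnosis order token {token!r}")


def parse_cohort_table(source: str | IO[str]) -> CohortTable:
    """Parse a tab-delimited cohort table into a :class:`CohortTable`.

    ``source`` may be a path, a string of file content, or a text stream.
    ``NA`` maps to missing; HER2 ``equ`` maps to equivocal.  Unknown
    grade/architecture tokens and duplicate (patient, block) pairs raise
    :class:`CohortParseError` naming the offending row.
    """
    if isinstance(source, str) and ("\t" in source or "\n" in source):
        df = pd.read_csv(io.StringIO(source), sep="\t", dtype=str, keep_default_na=False)
    else:  # path or open text stream
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)

    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortParseError(f"missing columns: {missing_cols}")

    samples: list[CohortSample] = []
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        patient = rec["Patient ID"].strip()
        block = rec["Block ID"].strip()
        key = (patient, block)
        if key in seen:
            raise CohortParseError(f"row {i}: duplicate block {block!r} for patient {patient!r}")
        seen.add(key)

        grade = rec["Grade"].strip()
        if grade not in GRADES:
            raise CohortParseError(f"row {i}: unknown grade token {grade!r}")
        arch = rec["Architecture"].strip()
        if arch not in ARCHITECTURES:
            raise CohortParseError(f"row {i}: unknown architecture token {arch!r}")
        lat = rec["Laterality"].strip()
        if lat not in LATERALITIES:
            raise CohortParseError(f"row {i}: unknown laterality token {lat!r}")
        er = rec["ER"].strip()
        if er not in ER_TOKENS:
            raise CohortParseError(f"row {i}: unknown ER token {er!r}")
        her2 = rec["HER2"].strip()
        if her2 not in HER2_TOKENS:
            raise CohortParseError(f"row {i}: unknown HER2 token {her2!r}")

        age_tok = rec["Age at Index"].strip()
        size_tok = rec["Size (cm)"].strip()
        order, months = _parse_diagnosis(rec["Diagnosis Order"], i)
        samples.append(
            CohortSample(
                patient_id=patient,
                block_id=block,
                age_years=None if age_tok == "NA" else int(age_tok),
                size_cm=None if size_tok == "NA" else float(size_tok),
                laterality=lat,
                grade=grade,
                architecture=arch,
                er_status=ER_TOKENS[er],
                her2_status=HER2_TOKENS[her2],
                n_regions=int(rec["N. of Regions"]),
                diagnosis_order=order,
                months_offset=months,
            )
        )
    return CohortTable(tuple(samples))


def serialize_cohort_table(table: CohortTable) -> str:
    """Serialize back to the tab-delimited dialect accepted by the parser."""
    er_rev = {v: k for k, v in ER_TOKENS.items()}
    her2_rev = {v: k for k, v in HER2_TOKENS.items()}
    lines = ["\t".join(COLUMNS)]
    for s in table:
        if s.diagnosis_order == "Recurrence":
            order = f"Recur. (+{s.months_offset} mos.)"
        else:
            order = s.diagnosis_order
        size = "NA" if s.size_cm is None else f"{s.size_cm:g}"
        age = "NA" if s.age_years is None else str(s.age_years)
        lines.append(
            "\t".join(
                [
                    s.patient_id,
                    s.block_id,
                    age,
                    size,
                    s.laterality,
                    s.grade,
                    s.architecture,
                    er_rev[s.er_status],
                    her2_rev[s.her2_status],
                    str(s.n_regions),
                    order,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def summarize_cohort(table: CohortTable, stratifier: str) -> dict[str, int]:
    """Count samples per category of ``stratifier``.

    ``stratifier`` is one of ``grade_group``, ``architecture``, ``er`` or
    ``her2``.  Samples with a missing status for the chosen stratifier are
    reported under ``unevaluable``; the returned counts always partition
    the table.  For HER2, equivocal samples are evaluable (they count in
    the denominator) but are not positive.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}; expected one of {STRATIFIERS}")
    if len(table) == 0:
        raise ValueError("empty cohort table")

    counts: dict[str, int] = {}

    def bump(key: str) -> None:
        counts[key] = counts.get(key, 0) + 1

    for s in table:
        if stratifier == "grade_group":
            bump(s.grade_group)
        elif stratifier == "architecture":
            bump(s.architecture)
        elif stratifier == "er":
            bump("unevaluable" if s.er_status == "missing" else s.er_status)
        else:  # her2
            bump("unevaluable" if s.her2_status == "missing" else s.her2_status)
    return counts


def count_samples_by_size(table: CohortTable, min_size_cm: float) -> int:
    """Number of samples with a recorded size of at least ``min_size_cm``.

    The threshold is inclusive (>=); blocks with no recorded size are
    excluded from the count.
    """
    if min_size_cm < 0:
        raise ValueError("min_size_cm must be non-negative")
    return sum(1 for s in table if s.size_cm is not None and s.size_cm >= min_size_cm)


def count_unique_patients(table: CohortTable) -> int:
    """Number of distinct patients contributing at least one block."""
    return len({s.patient_id for s in table})
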