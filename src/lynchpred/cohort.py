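"""Cohort data model and CSV input/output.

The unit of analysis is the *index patient* (proband): the family member in
whom tumour screening for Lynch syndrome was performed. Family history is
stored at the granularity the risk models consume — per-relative-degree
counts of colorectal cancer (CRC), endometrial cancer (EC) and other
LS-associated tumours, with the youngest age at diagnosis per category —
rather than as a full pedigree.

Files are UTF-8, comma-delimited CSV with a fixed header. Missing optional
values are empty cells. Count columns must be explicit integers: an empty
count cell is a row error, so unknown family history is never silently
treated as negative history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Optional

import pandas as pd

from .errors import RowError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
MUTATION_STATUSES = ("none",) + GENES + ("unknown",)
SEXES = ("male", "female")
NUM_CRC_LEVELS = ("0", "1", "2+")

#: Column order of the cohort CSV schema.
COLUMNS = (
    "id",
    "sex",
    "num_crc",
    "age_first_crc",
    "any_proximal_crc",
    "ec",
    "age_ec",
    "other_ls_cancer",
    "fdr_crc_n",
    "fdr_crc_youngest_age",
    "fdr_ec_n",
    "fdr_ec_youngest_age",
    "fdr_other_ls_n",
    "sdr_crc_n",
    "sdr_crc_youngest_age",
    "sdr_ec_n",
    "sdr_ec_youngest_age",
    "sdr_other_ls_n",
    "mutation_status",
)

#: Extra columns of the scored-cohort CSV schema.
SCORE_COLUMNS = (
    "p_mlh1",
    "p_msh2",
    "p_msh6",
    "p_pms2",
    "p_overall",
    "mmrpredict_p",
    "bethesda_flag",
)


@dataclass
class IndexPatient:
    """One screened proband with personal and family cancer history."""

    id: str
    sex: str
    num_crc: str
    age_first_crc: Optional[float] = None
    any_proximal_crc: Optional[bool] = None
    ec: bool = False
    age_ec: Optional[float] = None
    other_ls_cancer: bool = False
    fdr_crc_n: int = 0
    fdr_crc_youngest_age: Optional[float] = None
    fdr_ec_n: int = 0
    fdr_ec_youngest_age: Optional[float] = None
    fdr_other_ls_n: int = 0
    sdr_crc_n: int = 0
    sdr_crc_youngest_age: Optional[float] = None
    sdr_ec_n: int = 0
    sdr_ec_youngest_age: Optional[float] = None
    sdr_other_ls_n: int = 0
    mutation_status: str = "unknown"

    @property
    def has_crc(self) -> bool:
        return self.num_crc != "0"

    @property
    def is_carrier(self) -> bool:
        return self.mutation_status in GENES

    def violations(self) -> list[str]:
        """Return every invariant violation as a machine-readable string."""
        v: list[str] = []
        if self.sex not in SEXES:
            v.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.num_crc not in NUM_CRC_LEVELS:
            v.append(f"num_crc must be one of {NUM_CRC_LEVELS}, got {self.num_crc!r}")
        if self.mutation_status not in MUTATION_STATUSES:
            v.append(f"mutation_status must be one of {MUTATION_STATUSES}")

        for name in ("age_first_crc", "age_ec", "fdr_crc_youngest_age",
                     "fdr_ec_youngest_age", "sdr_crc_youngest_age",
                     "sdr_ec_youngest_age"):
            a = getattr(self, name)
            if a is not None and not (0 <= a <= 120):
                v.append(f"{name} must be in [0, 120], got {a}")

        if self.num_crc in NUM_CRC_LEVELS:
            if self.has_crc:
                if self.age_first_crc is None:
                    v.append("age_first_crc required when num_crc >= 1")
                if self.any_proximal_crc is None:
                    v.append("any_proximal_crc required when num_crc >= 1")
            else:
                if self.age_first_crc is not None:
                    v.append("age_first_crc present but num_crc = 0")
                if self.any_proximal_crc is not None:
                    v.append("any_proximal_crc defined only when num_crc >= 1")

        if self.ec and self.sex == "male":
            v.append("ec = true requires sex = female")
        if self.ec and self.age_ec is None:
            v.append("age_ec required when ec = true")
        if not self.ec and self.age_ec is not None:
            v.append("age_ec present but ec = false")

        for count, age in (("fdr_crc_n", "fdr_crc_youngest_age"),
                           ("fdr_ec_n", "fdr_ec_youngest_age"),
                           ("sdr_crc_n", "sdr_crc_youngest_age"),
                           ("sdr_ec_n", "sdr_ec_youngest_age")):
            n = getattr(self, count)
            a = getattr(self, age)
            if n < 0:
                v.append(f"{count} must be >= 0")
            if n >= 1 and a is None:
                v.append(f"{age} required when {count} >= 1")
            if n == 0 and a is not None:
                v.append(f"{age} present but {count} = 0")
        for count in ("fdr_other_ls_n", "sdr_other_ls_n"):
            if getattr(self, count) < 0:
                v.append(f"{count} must be >= 0")
        return v

    def validate(self) -> "IndexPatient":
        v = self.violations()
        if v:
            raise ValidationError(f"patient {self.id!r}: " + "; ".join(v))
        return self


@dataclass
class Cohort:
    """An ordered collection of validated index patients."""

    patients: list[IndexPatient] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[IndexPatient]:
        return iter(self.patients)

    def validate(self) -> "Cohort":
        seen: set[str] = set()
        for p in self.patients:
            if p.id in seen:
                raise ValidationError(f"duplicate patient id {p.id!r}")
            seen.add(p.id)
            p.validate()
        return self

    def subset(self, keep: Iterable[bool], provenance: str = "") -> "Cohort":
        kept = [p for p, k in zip(self.patients, keep) if k]
        return Cohort(kept, provenance or self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append({f.name: getattr(p, f.name) for f in fields(IndexPatient)})
        return pd.DataFrame(rows, columns=list(COLUMNS))


# --- cell-level (de)serialisation -----------------------------------------

_BOOL = {"true": True, "false": False}


def _parse_bool(cell: str, col: str) -> bool:
    try:
        return _BOOL[cell.strip().lower()]
    except KeyError:
        raise ValueError(f"column {col}: expected true/false, got {cell!r}")


def _parse_opt_bool(cell: str, col: str) -> Optional[bool]:
    return None if cell.strip() == "" else _parse_bool(cell, col)


def _parse_opt_float(cell: str, col: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"column {col}: expected a number, got {cell!r}")


def _parse_count(cell: str, col: str) -> int:
    cell = cell.strip()
    if cell == "":
        # unknown history must stay an error, never an implicit zero
        raise ValueError(f"column {col}: count is missing (explicit 0 required)")
    try:
        return int(cell)
    except ValueError:
        raise ValueError(f"column {col}: expected an integer count, got {cell!r}")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _parse_row(row: "pd.Series") -> IndexPatient:
    return IndexPatient(
        id=str(row["id"]).strip(),
        sex=str(row["sex"]).strip(),
        num_crc=str(row["num_crc"]).strip(),
        age_first_crc=_parse_opt_float(row["age_first_crc"], "age_first_crc"),
        any_proximal_crc=_parse_opt_bool(row["any_proximal_crc"], "any_proximal_crc"),
        ec=_parse_bool(row["ec"], "ec"),
        age_ec=_parse_opt_float(row["age_ec"], "age_ec"),
        other_ls_cancer=_parse_bool(row["other_ls_cancer"], "other_ls_cancer"),
        fdr_crc_n=_parse_count(row["fdr_crc_n"], "fdr_crc_n"),
        fdr_crc_youngest_age=_parse_opt_float(row["fdr_crc_youngest_age"], "fdr_crc_youngest_age"),
        fdr_ec_n=_parse_count(row["fdr_ec_n"], "fdr_ec_n"),
        fdr_ec_youngest_age=_parse_opt_float(row["fdr_ec_youngest_age"], "fdr_ec_youngest_age"),
        fdr_other_ls_n=_parse_count(row["fdr_other_ls_n"], "fdr_other_ls_n"),
        sdr_crc_n=_parse_count(row["sdr_crc_n"], "sdr_crc_n"),
        sdr_crc_youngest_age=_parse_opt_float(row["sdr_crc_youngest_age"], "sdr_crc_youngest_age"),
        sdr_ec_n=_parse_count(row["sdr_ec_n"], "sdr_ec_n"),
        sdr_ec_youngest_age=_parse_opt_float(row["sdr_ec_youngest_age"], "sdr_ec_youngest_age"),
        sdr_other_ls_n=_parse_count(row["sdr_other_ls_n"], "sdr_other_ls_n"),
        mutation_status=str(row["mutation_status"]).strip(),
    )


def read_cohort(path, strict: bool = True) -> Cohort:
    """Read and validate a cohort CSV.

    In strict mode any parsing failure or invariant violation raises
    :class:`RowError` (or :class:`SchemaError` for header problems).
    In non-strict mode offending rows are dropped; the number dropped and
    each reason is written to the module logger.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    patients: list[IndexPatient] = []
    dropped = 0
    for i, row in df.iterrows():
        row_id = str(row["id"]) or f"<row {i}>"
        try:
            p = _parse_row(row)
            bad = p.violations()
            if bad:
                raise RowError(row_id, "; ".join(bad))
        except RowError:
            if strict:
                raise
            dropped += 1
            logger.warning("dropping row %s: invariant violation", row_id)
            continue
        except ValueError as exc:
            if strict:
                raise RowError(row_id, str(exc)) from exc
            dropped += 1
            logger.warning("dropping row %s: %s", row_id, exc)
            continue
        patients.append(p)
    if dropped:
        logger.info("read_cohort: dropped %d invalid row(s)", dropped)
    cohort = Cohort(patients, provenance=str(path))
    # id uniqueness is a cohort-level invariant, always enforced
    seen: set[str] = set()
    for p in cohort.patients:
        if p.id in seen:
            raise SchemaError(f"duplicate patient id {p.id!r}")
        seen.add(p.id)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a validated cohort to CSV; read_cohort(write_cohort(c)) == c."""
    cohort.validate()
    rows = []
    for p in cohort.patients:
        rows.append({f.name: _fmt(getattr(p, f.name)) for f in fields(IndexPatient)})
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
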