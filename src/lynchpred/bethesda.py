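"""Revised Bethesda guideline classifier.

The revised Bethesda guidelines select CRC patients for tumour-based Lynch
syndrome screening. Against the one-row-per-proband schema we evaluate:

* C1 — CRC diagnosed before age 50;
* C2 — synchronous or metachronous CRC, or another LS-associated tumour in
  the proband, at any age;
* C3 — MSI-high histology before age 60: *not evaluable* here, because the
  schema carries no tumour histology; C3 is reported as such and excluded
  from the fulfilment disjunction rather than silently counted false;
* C4 — CRC with at least one first-degree relative with an LS-related
  tumour diagnosed before age 50 (ages are recorded for relatives' CRC and
  EC; the "other LS tumour" counts carry no ages, so they cannot satisfy
  the under-50 clause);
* C5 — CRC with two or more first- or second-degree relatives with
  LS-related tumours at any age.

Age comparisons are strict (< 50, < 60), following the guideline text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import IndexPatient
from .errors import NotApplicableError

LS_RELATED = ("CRC", "EC", "other")


@dataclass(frozen=True)
class BethesdaResult:
    fulfilled: bool
    criteria_met: tuple[str, ...] = ()
    #: C3 needs tumour histology, which the cohort schema does not carry.
    c3_evaluable: bool = False

    def __post_init__(self):
        assert self.fulfilled == bool(self.criteria_met)


def meets_revised_bethesda(patient: IndexPatient) -> BethesdaResult:
    """Classify one CRC proband against the revised Bethesda guidelines."""
    if not patient.has_crc:
        raise NotApplicableError(
            f"patient {patient.id!r} has no CRC; the revised Bethesda "
            "guidelines apply to CRC patients")

    met: list[str] = []
    if patient.age_first_crc is not None and patient.age_first_crc < 50:
        met.append("C1")
    if patient.num_crc == "2+" or patient.ec or patient.other_ls_cancer:
        met.append("C2")
    # C3 intentionally absent: not evaluable without histology.
    c4 = (
        (patient.fdr_crc_n >= 1 and patient.fdr_crc_youngest_age is not None
         and patient.fdr_crc_youngest_age < 50)
        or (patient.fdr_ec_n >= 1 and patient.fdr_ec_youngest_age is not None
            and patient.fdr_ec_youngest_age < 50)
    )
    if c4:
        met.append("C4")
    total_relatives = (patient.fdr_crc_n + patient.fdr_ec_n + patient.fdr_other_ls_n
                       + patient.sdr_crc_n + patient.sdr_ec_n + patient.sdr_other_ls_n)
    if total_relatives >= 2:
        met.append("C5")

    return BethesdaResult(fulfilled=bool(met), criteria_met=tuple(met))
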