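"""Descriptive cohort comparisons: frequencies and continuous summaries.

Reproduces the layout of clinical "Table 1" comparisons between mutation
carriers and non-carriers: percentages with chi-square or Fisher exact
tests for frequencies, medians with interquartile ranges and Mann-Whitney
U tests for ages. Test dispatch is conventional: Fisher when any expected
cell count is below 5, otherwise Pearson chi-square without continuity
correction; the test actually used is recorded per row.

Endometrial-cancer rows use female denominators only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.stats as st

from .bethesda import meets_revised_bethesda
from .cohort import Cohort, IndexPatient
from .errors import ValidationError

__all__ = [
    "ContingencyTable",
    "chi_square_test",
    "fisher_exact",
    "mann_whitney_u",
    "dispatch_frequency_test",
    "summarize_cohort",
]


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table of non-negative integer counts."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("group A", "group B")
    col_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValidationError("a contingency table is 2x2")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    def expected(self) -> np.ndarray:
        arr = self.array
        return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def chi_square_test(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square, df 1, without continuity correction."""
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined for a zero margin")
    stat, p, _, _ = st.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (hypergeometric tail sum)."""
    _, p = st.fisher_exact(table.array, alternative="two-sided")
    return float(p)


def dispatch_frequency_test(table: ContingencyTable) -> tuple[str, float]:
    """Fisher when any expected cell < 5, else chi-square; returns (name, p)."""
    if (table.expected() < 5).any():
        return "fisher", fisher_exact(table)
    return "chi-square", chi_square_test(table)[1]


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small samples (min group size < 8, no ties),
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    small = min(a.size, b.size) < 8
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method,
                          use_continuity=False)
    return float(res.statistic), float(res.pvalue)


# --- Table-1-style cohort summary -----------------------------------------

def _pct_cell(k: int, n: int) -> str:
    if n == 0:
        return "-"
    pct = 100.0 * k / n
    if 0 < pct < 1:
        return f"{pct:.1f}% ({k})"
    return f"{int(np.floor(pct + 0.5))}% ({k})"


def _median_iqr_cell(values: np.ndarray) -> str:
    if values.size == 0:
        return "-"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.0f} [{q1:.0f}-{q3:.0f}]"


@dataclass(frozen=True)
class _FlagRow:
    label: str
    flag: Callable[[IndexPatient], Optional[bool]]   # None = excluded from denominator


@dataclass(frozen=True)
class _AgeRow:
    label: str
    age: Callable[[IndexPatient], Optional[float]]


_ROWS: list = [
    _FlagRow("Revised Bethesda guidelines",
             lambda p: meets_revised_bethesda(p).fulfilled if p.has_crc else None),
    _FlagRow("Male gender", lambda p: p.sex == "male"),
    _AgeRow("Age CRC (median, IQR)", lambda p: p.age_first_crc),
    _FlagRow("Proximal CRC", lambda p: p.any_proximal_crc if p.has_crc else None),
    _FlagRow(">= 2 CRCs", lambda p: p.num_crc == "2+"),
    _FlagRow("Endometrial cancer",
             lambda p: p.ec if p.sex == "female" else None),
    _AgeRow("Age EC (median, IQR)", lambda p: p.age_ec),
    _FlagRow("Multiple LS cancers",
             lambda p: p.num_crc == "2+" or (p.has_crc and (p.ec or p.other_ls_cancer))),
    _FlagRow("FDR CRC", lambda p: p.fdr_crc_n >= 1),
    _FlagRow(">= 2 FDRs with CRC", lambda p: p.fdr_crc_n >= 2),
    _AgeRow("FDR age CRC (median, IQR)", lambda p: p.fdr_crc_youngest_age),
    _FlagRow("FDR endometrial cancer", lambda p: p.fdr_ec_n >= 1),
    _FlagRow(">= 2 FDRs with EC", lambda p: p.fdr_ec_n >= 2),
    _AgeRow("FDR age EC (median, IQR)", lambda p: p.fdr_ec_youngest_age),
    _FlagRow("FDR other LS cancers", lambda p: p.fdr_other_ls_n >= 1),
    _FlagRow("SDR CRC", lambda p: p.sdr_crc_n >= 1),
    _FlagRow(">= 2 SDRs with CRC", lambda p: p.sdr_crc_n >= 2),
    _AgeRow("SDR age CRC (median, IQR)", lambda p: p.sdr_crc_youngest_age),
    _FlagRow("SDR endometrial cancer", lambda p: p.sdr_ec_n >= 1),
    _FlagRow(">= 2 SDRs with EC", lambda p: p.sdr_ec_n >= 2),
    _AgeRow("SDR age EC (median, IQR)", lambda p: p.sdr_ec_youngest_age),
    _FlagRow("SDR other LS cancers", lambda p: p.sdr_other_ls_n >= 1),
]


def summarize_cohort(cohort: Cohort, contrast: str = "all_carriers") -> pd.DataFrame:
    """Table-1-style comparison of carriers vs non-mutation carriers.

    ``contrast`` is ``all_carriers`` (any gene vs none) or ``pms2_only``
    (PMS2 carriers vs none). Patients with unknown status are excluded.
    Returns a DataFrame with columns: variable, negative, positive, test, p.
    """
    if contrast not in ("all_carriers", "pms2_only"):
        raise ValidationError("contrast must be all_carriers or pms2_only")
    neg = [p for p in cohort if p.mutation_status == "none"]
    if contrast == "all_carriers":
        pos = [p for p in cohort if p.is_carrier]
        pos_label = "Mutation positive"
    else:
        pos = [p for p in cohort if p.mutation_status == "PMS2"]
        pos_label = "PMS2 mutation positive"
    if not neg or not pos:
        raise ValidationError("both comparison groups must be non-empty")

    records = [{"variable": "n", "negative": str(len(neg)),
                "positive": str(len(pos)), "test": "", "p": np.nan}]
    for row in _ROWS:
        if isinstance(row, _FlagRow):
            nvals = [row.flag(p) for p in neg]
            pvals = [row.flag(p) for p in pos]
            nvals = [v for v in nvals if v is not None]
            pvals = [v for v in pvals if v is not None]
            k_n, k_p = sum(nvals), sum(pvals)
            table = ContingencyTable(((int(k_n), int(len(nvals) - k_n)),
                                      (int(k_p), int(len(pvals) - k_p))))
            try:
                test, p = dispatch_frequency_test(table)
            except ValidationError:
                test, p = "-", np.nan
            records.append({"variable": row.label,
                            "negative": _pct_cell(k_n, len(nvals)),
                            "positive": _pct_cell(k_p, len(pvals)),
                            "test": test, "p": p})
        else:
            a = np.array([v for v in (row.age(p) for p in neg) if v is not None])
            b = np.array([v for v in (row.age(p) for p in pos) if v is not None])
            if a.size and b.size:
                _, p = mann_whitney_u(a, b)
                test = "mann-whitney"
            else:
                p, test = np.nan, "-"
            records.append({"variable": row.label,
                            "negative": _median_iqr_cell(a),
                            "positive": _median_iqr_cell(b),
                            "test": test, "p": p})
    df = pd.DataFrame.from_records(records)
    df.attrs["positive_label"] = pos_label
    df.attrs["significance_note"] = "p < 0.01 considered statistically significant"
    return df
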