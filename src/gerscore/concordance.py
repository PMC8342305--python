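"""Paired diagnostic comparison of accelerometric and pH-metry calls.

Each study contributes one binary accelerometric call (mean amplitude
>= 1 µV) and one binary pH call (Boix-Ochoa composite > 16.6).  The 2x2
contingency table and the derived rates (PPV, sensitivity, specificity,
NPV, and the fraction of accelerometry-positive studies with a negative
pH score — the non-acid-reflux signature) are exact rational arithmetic
on the cell counts.

Because neither method is a gold standard here, ``diagnostics`` takes a
``reference`` parameter naming which method plays the role of the test;
with ``reference="ph"`` the PPV answers: of the pH-positive studies, what
fraction were also accelerometry-positive.

``build_fixture`` reproduces the published cohort margins as synthetic
per-study tables: the full 85-study cohort (cells 18/42/2/23), the
11-infant surgical subgroup and the 20-infant anti-reflux-medication
subgroup.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Set, Union

import pandas as pd

from .errors import EmptyInputError, ValidationError

__all__ = [
    "StudyRecord",
    "ContingencyTable",
    "Rate",
    "tabulate",
    "diagnostics",
    "build_fixture",
    "FIXTURES",
    "read_studies_csv",
    "write_studies_csv",
]


@dataclass
class StudyRecord:
    study_id: str
    accel_positive: bool
    ph_positive: bool
    subgroup_flags: Set[str] = field(default_factory=set)
    accel_score: Optional[float] = None   # µV
    boix_ochoa: Optional[float] = None


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cell counts for paired accelerometric / pH calls."""

    both_pos: int
    accel_pos_ph_neg: int
    accel_neg_ph_pos: int
    both_neg: int

    def __post_init__(self) -> None:
        for name in ("both_pos", "accel_pos_ph_neg", "accel_neg_ph_pos", "both_neg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.both_pos + self.accel_pos_ph_neg + self.accel_neg_ph_pos + self.both_neg

    def transposed(self) -> "ContingencyTable":
        """Swap the roles of the two methods (off-diagonal swap)."""
        return ContingencyTable(
            both_pos=self.both_pos,
            accel_pos_ph_neg=self.accel_neg_ph_pos,
            accel_neg_ph_pos=self.accel_pos_ph_neg,
            both_neg=self.both_neg,
        )


def tabulate(
    records: List[StudyRecord], subgroup: Optional[str] = None
) -> ContingencyTable:
    """Exact cell counts, optionally restricted to a subgroup flag."""
    if subgroup is not None:
        records = [r for r in records if subgroup in r.subgroup_flags]
    if not records:
        raise EmptyInputError(
            "no study records" + (f" with subgroup flag {subgroup!r}" if subgroup else "")
        )
    bp = sum(1 for r in records if r.accel_positive and r.ph_positive)
    apn = sum(1 for r in records if r.accel_positive and not r.ph_positive)
    anp = sum(1 for r in records if not r.accel_positive and r.ph_positive)
    bn = sum(1 for r in records if not r.accel_positive and not r.ph_positive)
    return ContingencyTable(bp, apn, anp, bn)


@dataclass(frozen=True)
class Rate:
    """A diagnostic rate kept as an exact fraction; percent to 1 decimal."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def fraction(self) -> Optional[Fraction]:
        return Fraction(self.numerator, self.denominator) if self.defined else None

    @property
    def pct(self) -> Optional[float]:
        if not self.defined:
            return None
        return round(100.0 * self.numerator / self.denominator, 1)

    def __repr__(self) -> str:
        if not self.defined:
            return "Rate(undefined)"
        return f"Rate({self.numerator}/{self.denominator} = {self.pct}%)"


def diagnostics(t: ContingencyTable, reference: str = "ph") -> Dict[str, Rate]:
    """Named diagnostic rates on a 2x2 table.

    With ``reference="ph"`` the pH score is the test and the accelerometric
    call the condition it is checked against (and vice versa for
    ``reference="accel"``).  Undefined rates (zero denominator) are reported
    as undefined, never as 0.
    """
    if reference not in ("ph", "accel"):
        raise ValidationError(f"reference must be 'ph' or 'accel', got {reference!r}")
    bp, apn, anp, bn = t.both_pos, t.accel_pos_ph_neg, t.accel_neg_ph_pos, t.both_neg
    if reference == "accel":
        apn, anp = anp, apn  # swap which method is the test
    # test = reference method; condition = the other method's call
    rates = {
        "ppv": Rate(bp, bp + anp),          # test-positive that are condition-positive
        "sensitivity": Rate(bp, bp + apn),  # condition-positive detected by the test
        "specificity": Rate(bn, bn + anp),
        "npv": Rate(bn, bn + apn),
        "test_neg_condition_pos_fraction": Rate(apn, bp + apn),
    }
    if reference == "ph":
        # the paper's headline fraction: accel-positive studies with negative pH
        rates["accel_pos_ph_neg_fraction"] = Rate(t.accel_pos_ph_neg, bp + t.accel_pos_ph_neg)
    return rates


def _records(name: str, rows: List[tuple], flags: Set[str]) -> List[StudyRecord]:
    return [
        StudyRecord(
            study_id=f"{name}-{i + 1:03d}",
            accel_positive=a,
            ph_positive=p,
            subgroup_flags=set(flags),
        )
        for i, (a, p) in enumerate(rows)
    ]


FIXTURES = ("full_cohort", "surgical", "medicated")


def build_fixture(name: str) -> List[StudyRecord]:
    """Synthetic study tables encoding the published cohort margins exactly.

    - ``full_cohort``: 85 studies — 18 concurrent-positive, 42
      accelerometry-positive/pH-negative, 2 accelerometry-negative/
      pH-positive, 23 concurrent-negative.
    - ``surgical``: 11 infants requiring anti-aspiration surgery — 2 positive
      by both methods, 8 accelerometry-positive with a pH false negative,
      1 negative by both (10/11 accelerometry-positive).
    - ``medicated``: 20 infants on anti-reflux medication — 19 pH-negative
      (13 accelerometry-positive, 7 negative overall), and the single
      pH-positive study was also accelerometry-positive.
    """
    if name == "full_cohort":
        rows = [(True, True)] * 18 + [(True, False)] * 42 + [(False, True)] * 2 + [(False, False)] * 23
        return _records("cohort", rows, set())
    if name == "surgical":
        rows = [(True, True)] * 2 + [(True, False)] * 8 + [(False, False)] * 1
        return _records("surgical", rows, {"surgical"})
    if name == "medicated":
        rows = [(True, True)] * 1 + [(True, False)] * 12 + [(False, False)] * 7
        return _records("medicated", rows, {"on_ger_meds"})
    raise ValidationError(f"unknown fixture {name!r}; expected one of {FIXTURES}")


_CSV_COLUMNS = [
    "study_id",
    "accel_positive",
    "ph_positive",
    "surgical",
    "on_ger_meds",
    "accel_score_uV",
    "boix_ochoa",
]


def read_studies_csv(path: Union[str, Path]) -> List[StudyRecord]:
    """Read a study table CSV (columns as in :data:`_CSV_COLUMNS`)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty study table") from None
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no study rows")
    for col in ("study_id", "accel_positive", "ph_positive"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        flags = set()
        if "surgical" in df.columns and bool(row.get("surgical", False)):
            flags.add("surgical")
        if "on_ger_meds" in df.columns and bool(row.get("on_ger_meds", False)):
            flags.add("on_ger_meds")
        records.append(
            StudyRecord(
                study_id=str(row["study_id"]),
                accel_positive=bool(row["accel_positive"]),
                ph_positive=bool(row["ph_positive"]),
                subgroup_flags=flags,
                accel_score=float(row["accel_score_uV"])
                if "accel_score_uV" in df.columns and pd.notna(row.get("accel_score_uV"))
                else None,
                boix_ochoa=float(row["boix_ochoa"])
                if "boix_ochoa" in df.columns and pd.notna(row.get("boix_ochoa"))
                else None,
            )
        )
    return records


def write_studies_csv(records: List[StudyRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "study_id": r.study_id,
            "accel_positive": r.accel_positive,
            "ph_positive": r.ph_positive,
            "surgical": "surgical" in r.subgroup_flags,
            "on_ger_meds": "on_ger_meds" in r.subgroup_flags,
            "accel_score_uV": r.accel_score,
            "boix_ochoa": r.boix_ochoa,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
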