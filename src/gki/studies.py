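"""Published brain-tumor diet studies: bundled group means and verification.

Five previously published human and mouse brain-tumor studies reported group
mean blood glucose and β-OHB under ketogenic-diet (KD), standard-diet (SD),
restricted (-R) and unrestricted (-UR) arms, some with radiation (+Rad).
The GKI printed for each arm should be recoverable from its glucose/ketone
pair by plain division and one-decimal rounding; :func:`verify_table1`
recomputes every row and reports mismatches (there are none).

The transcription ships as a frozen CSV inside the package — 20 records:
the two pediatric-astrocytoma patients contribute a baseline and a day-56
row each (4), the glioblastoma patient a baseline and day-21 row (2), the
four-arm CT-2A mouse study 4 rows, the two-tumor three-arm mouse study 6,
and the GL261 radiation study 4.

A second published table gives ad-libitum (AL) vs calorie-restricted (CR)
group means for the VM-M3 glioblastoma model.  Its printed GKIs are means
of per-animal ratios, which cannot be reproduced from the printed group
means alone (a ratio of means is not a mean of ratios); both conventions
are therefore exposed via :class:`GroupSummary`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from statistics import fmean
from typing import Literal, Optional, Sequence

from .units import Analyte, Concentration, Unit, ValidationError, compute_gki, display_gki

__all__ = [
    "StudyRecord",
    "VerificationRow",
    "GroupSummary",
    "DIET_CODES",
    "load_table1_fixtures",
    "verify_table1",
    "load_table2_groups",
    "group_summary",
]

DIET_CODES = ("KD-UR", "KD-R", "SD-UR", "SD-R", "SD-UR+Rad", "KD-UR+Rad")


@dataclass(frozen=True)
class StudyRecord:
    """One published diet arm (or patient timepoint): group means and outcome.

    ``n_subjects`` is kept as text because the source reports ranges such as
    "12-14".  ``outcome`` is opaque prose (tumor weight, survival, imaging);
    no outcome statistics are computed here.
    """

    study_id: int
    species: Literal["human", "mouse"]
    tumor: str
    diet_code: str
    n_subjects: str
    days_on_diet: int
    glucose_mM: float
    ketone_mM: float
    ketone_source: Literal["blood", "urine"]
    printed_gki: float
    outcome: str

    def __post_init__(self) -> None:
        if not 1 <= self.study_id <= 5:
            raise ValidationError(f"study_id out of range: {self.study_id}")
        if self.diet_code not in DIET_CODES:
            raise ValidationError(f"unknown diet code: {self.diet_code!r}")
        for name in ("glucose_mM", "ketone_mM", "printed_gki"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def recomputed_gki(self) -> float:
        g = Concentration(Analyte.GLUCOSE, self.glucose_mM, Unit.MM)
        k = Concentration(Analyte.BETA_HYDROXYBUTYRATE, self.ketone_mM, Unit.MM)
        return compute_gki(g, k).value


@dataclass(frozen=True)
class VerificationRow:
    record: StudyRecord
    recomputed_display: str
    printed_display: str
    match: bool
    non_comparable: bool


@dataclass(frozen=True)
class GroupSummary:
    """Group-level GKI under both averaging conventions.

    ``gki_of_means`` divides the group mean glucose by the group mean ketone
    (always computable from published summaries); ``mean_of_gkis`` averages
    per-subject ratios and needs individual data.  By a Jensen-type
    inequality the two generally differ; only ``mean_of_gkis`` is guaranteed
    to lie between the per-subject extremes.
    """

    label: str
    mean_glucose_mM: float
    mean_ketone_mM: float
    gki_of_means: float
    mean_of_gkis: Optional[float]
    n: int


def _data_path(name: str):
    return resources.files("gki.data").joinpath(name)


def load_table1_fixtures() -> list[StudyRecord]:
    """Load the frozen 20-record transcription of the five-study table."""
    with _data_path("table1.csv").open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    records = [
        StudyRecord(
            study_id=int(r["study_id"]),
            species=r["species"],  # type: ignore[arg-type]
            tumor=r["tumor"],
            diet_code=r["diet_code"],
            n_subjects=r["n_subjects"],
            days_on_diet=int(r["days_on_diet"]),
            glucose_mM=float(r["glucose_mM"]),
            ketone_mM=float(r["ketone_mM"]),
            ketone_source=r["ketone_source"],  # type: ignore[arg-type]
            printed_gki=float(r["printed_gki"]),
            outcome=r["outcome"],
        )
        for r in rows
    ]
    if len(records) != 20:
        raise ValidationError(f"expected 20 study records, found {len(records)}")
    return records


def verify_table1(records: Optional[Sequence[StudyRecord]] = None) -> list[VerificationRow]:
    """Recompute every record's GKI and compare to the printed value.

    Mismatches are reported, not raised — this is a verification report.
    Urinary-ketone rows verify arithmetically like all others but are
    flagged non-comparable (urine acetoacetate is not blood β-OHB).
    """
    if records is None:
        records = load_table1_fixtures()
    out = []
    for rec in records:
        recomputed = display_gki(rec.recomputed_gki)
        printed = display_gki(rec.printed_gki)
        out.append(
            VerificationRow(
                record=rec,
                recomputed_display=recomputed,
                printed_display=printed,
                match=recomputed == printed,
                non_comparable=rec.ketone_source == "urine",
            )
        )
    return out


def load_table2_groups() -> list[GroupSummary]:
    """AL vs CR group summaries for the VM-M3 model, from printed means.

    ``mean_of_gkis`` is ``None`` for both groups: the printed GKIs (15.3,
    6.5) are per-animal ratio means whose underlying individual data are
    unpublished, so only the ratio-of-means convention can be recomputed
    here (16.0 for AL, ~6.3 for CR — deliberately not equal to the printed
    values).
    """
    with _data_path("table2.csv").open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for r in rows:
        g, k = float(r["glucose_mM"]), float(r["ketone_mM"])
        out.append(
            GroupSummary(
                label=r["label"],
                mean_glucose_mM=g,
                mean_ketone_mM=k,
                gki_of_means=g / k,
                mean_of_gkis=None,
                n=0,
            )
        )
    return out


def group_summary(
    per_subject: Sequence[tuple[float, float]], label: str = ""
) -> GroupSummary:
    """Summarise a group of per-subject (glucose mM, ketone mM) pairs.

    Computes both averaging conventions so their divergence is visible.
    """
    if not per_subject:
        raise ValidationError("group must contain at least one subject")
    for g, k in per_subject:
        if k <= 0:
            raise ValidationError("all ketone values must be positive")
        if g < 0:
            raise ValidationError("glucose values must be non-negative")
    mean_g = fmean(g for g, _ in per_subject)
    mean_k = fmean(k for _, k in per_subject)
    return GroupSummary(
        label=label,
        mean_glucose_mM=mean_g,
        mean_ketone_mM=mean_k,
        gki_of_means=mean_g / mean_k,
        mean_of_gkis=fmean(g / k for g, k in per_subject),
        n=len(per_subject),
    )
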