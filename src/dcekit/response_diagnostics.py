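"""Tumor response classification and cutoff-based diagnostic evaluation.

mRECIST categories measure only the arterially enhancing (viable)
portion of target lesions: complete response (CR) is disappearance of
any intratumoral arterial enhancement; partial response (PR) is at
least a 30% decrease in the sum of viable diameters against baseline;
progressive disease (PD) is at least a 20% increase against the
smallest sum recorded since treatment start; stable disease (SD) is
anything else.  CR/PR lesions form the responder group, SD/PD the
non-responder group.

For early-response prediction, a lesion is predicted to respond when
its distribution volume DV falls at or below a cutoff; predictive
performance is summarized as sensitivity, specificity, PPV, NPV and the
clinical utility indexes CUI+ = sensitivity x PPV and
CUI- = specificity x NPV.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .data_model_io import StudyDataset, std
from .exceptions import ValidationError

CATEGORIES = ("CR", "PR", "SD", "PD")
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})

#: Default DV cutoffs (ml/100 ml) per visit for predicting response,
#: applied as "responder if DV <= cutoff".
DEFAULT_DV_CUTOFFS = {"pre_tace": 40.0, "day3": 30.0, "day10": 17.0}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (the convention used for reported percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(fraction: float | None) -> float | None:
    """Fraction -> whole percent, round-half-up; passes None through."""
    return None if fraction is None else round_half_up(100.0 * fraction)


# ---------------------------------------------------------------------------
# mRECIST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MrecistAssessment:
    """Viable-diameter sums needed to categorize one assessment."""

    baseline_sum_mm: float
    current_sum_mm: float
    nadir_sum_mm: float
    any_enhancement: bool

    def __post_init__(self):
        if min(self.baseline_sum_mm, self.current_sum_mm, self.nadir_sum_mm) < 0:
            raise ValidationError("diameter sums must be non-negative")
        if self.nadir_sum_mm > self.baseline_sum_mm:
            raise ValidationError("nadir cannot exceed the baseline sum")


def group_of(category: str) -> str:
    if category not in CATEGORIES:
        raise ValidationError(f"unknown mRECIST category {category!r}")
    return "responder" if category in RESPONDER_CATEGORIES else "non_responder"


def mrecist_classify(a: MrecistAssessment) -> str:
    """Apply the four mRECIST rules to one assessment.

    Boundary cases qualify: exactly 30% decrease is PR, exactly 20%
    increase is PD.  Thresholds carry a relative tolerance of 1e-9 so
    boundary classifications survive floating-point rescaling of the
    diameters.
    """
    if not a.any_enhancement:
        return "CR"
    if a.current_sum_mm >= 1.2 * a.nadir_sum_mm * (1.0 - 1e-9):
        return "PD"
    if a.current_sum_mm <= 0.7 * a.baseline_sum_mm * (1.0 + 1e-9):
        return "PR"
    return "SD"


def group_responders(categories) -> dict:
    """Counts per mRECIST category and per response group."""
    cats = list(categories)
    if not cats:
        raise ValidationError("no categories to group")
    by_cat = {c: 0 for c in CATEGORIES}
    for c in cats:
        if c not in CATEGORIES:
            raise ValidationError(f"unknown mRECIST category {c!r}")
        by_cat[c] += 1
    return {
        "by_category": by_cat,
        "responders": by_cat["CR"] + by_cat["PR"],
        "non_responders": by_cat["SD"] + by_cat["PD"],
    }


def mixed_outcome_patients(dataset: StudyDataset) -> tuple[int, list[str]]:
    """Patients whose lesions split across responder and non-responder groups."""
    df = dataset.lesions
    if "outcome_final" not in df.columns or df["outcome_final"].isna().any():
        raise ValidationError("final outcomes are required")
    mixed = []
    for pid, grp in df.groupby("patient_id", sort=True):
        groups = {group_of(c) for c in grp["outcome_final"]}
        if len(groups) > 1:
            mixed.append(pid)
    return len(mixed), mixed


# ---------------------------------------------------------------------------
# Cutoff construction and prediction
# ---------------------------------------------------------------------------

def cutoff_mean_plus_2sd(responder_values, sd_convention: str = "population") -> float:
    """Cutoff = mean + 2 SD of the responder lesions' values."""
    values = np.asarray(list(responder_values), dtype=float)
    if len(values) < 2:
        raise ValidationError("need at least two responder values for a cutoff")
    return float(np.mean(values) + 2.0 * std(values, sd_convention))


def predict_by_cutoff(dv: float, cutoff: float) -> str:
    """Predicted group: responder iff DV <= cutoff (boundary inclusive)."""
    if dv < 0:
        raise ValidationError("dv must be non-negative")
    return "responder" if dv <= cutoff else "non_responder"


# ---------------------------------------------------------------------------
# Diagnostic metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; 'positive' means true/predicted responder."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticReport:
    """Diagnostic test summary; fields with a zero denominator are None."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    cui_positive: float | None
    cui_negative: float | None
    cutoff: float | None = None
    counts: ConfusionCounts | None = None

    def as_row(self) -> dict:
        """Flat dict with percentages (round-half-up) and 3-decimal CUIs."""
        r3 = lambda v: None if v is None else round_half_up(v, 3)
        return {
            "cutoff": self.cutoff,
            "sensitivity_pct": as_percent(self.sensitivity),
            "specificity_pct": as_percent(self.specificity),
            "ppv_pct": as_percent(self.ppv),
            "npv_pct": as_percent(self.npv),
            "cui_positive": r3(self.cui_positive),
            "cui_negative": r3(self.cui_negative),
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def diagnostic_metrics(counts: ConfusionCounts, cutoff: float | None = None) -> DiagnosticReport:
    """Sensitivity, specificity, PPV, NPV and clinical utility indexes.

    Requires at least one true positive-class and one true
    negative-class case; PPV/NPV (and the CUI that depends on them) are
    None when their denominator is empty.
    """
    if counts.positives == 0 and counts.negatives == 0:
        raise ValidationError("empty confusion table")
    sens = _ratio(counts.tp, counts.positives)
    spec = _ratio(counts.tn, counts.negatives)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    cui_pos = None if (sens is None or ppv is None) else sens * ppv
    cui_neg = None if (spec is None or npv is None) else spec * npv
    return DiagnosticReport(sens, spec, ppv, npv, cui_pos, cui_neg, cutoff, counts)


def confusion_from_values(dv_values, true_groups, cutoff: float) -> ConfusionCounts:
    """Tabulate predictions of ``predict_by_cutoff`` against true groups."""
    tp = fp = fn = tn = 0
    for dv, g in zip(dv_values, true_groups):
        pred = predict_by_cutoff(float(dv), cutoff)
        if g == "responder":
            tp, fn = (tp + 1, fn) if pred == "responder" else (tp, fn + 1)
        elif g == "non_responder":
            fp, tn = (fp + 1, tn) if pred == "responder" else (fp, tn + 1)
        else:
            raise ValidationError(f"unknown group {g!r}")
    return ConfusionCounts(tp, fp, fn, tn)


def cutoff_report_table(dv_by_timepoint: dict, groups, cutoffs: dict | None = None) -> pd.DataFrame:
    """Per-visit diagnostic report for DV cutoffs.

    Parameters
    ----------
    dv_by_timepoint : dict
        Mapping timepoint -> per-lesion DV values (aligned with ``groups``).
    groups : sequence of str
        True response group per lesion.
    cutoffs : dict, optional
        Timepoint -> cutoff; defaults to :data:`DEFAULT_DV_CUTOFFS`.
    """
    cutoffs = dict(DEFAULT_DV_CUTOFFS if cutoffs is None else cutoffs)
    rows = []
    for tp, dvs in dv_by_timepoint.items():
        counts = confusion_from_values(dvs, groups, cutoffs[tp])
        report = diagnostic_metrics(counts, cutoff=cutoffs[tp])
        rows.append({"timepoint": tp, **report.as_row()})
    return pd.DataFrame(rows)
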