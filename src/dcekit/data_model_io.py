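"""Shared data model and file I/O.

The study design this package targets is a liver DCE-MRI protocol with
burst sampling: short phases of rapid imaging (five frames over 30 s)
placed at pre-contrast, the hepatic arterial-dominant window, and a tail
of late phases out to 10 minutes after contrast injection.  Time zero is
the moment of contrast injection; pre-contrast frames carry negative
times so that baseline frames are identifiable by sign alone.

Curves travel as per-ROI mean signal versus time.  Study tables carry
one row per lesion with patient-level metadata repeated, mirroring the
demographic table of a small prospective cohort (11 patients, 21
hepatocellular carcinoma lesions, at most two lesions per patient).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: Canonical visit labels, in chronological order.
TIMEPOINTS = ("pre_tace", "day3", "day10")

CURVE_COLUMNS = ("roi_id", "time_s", "signal", "is_baseline")

STUDY_COLUMNS = (
    "patient_id",
    "lesion_id",
    "gender",
    "age",
    "segment",
    "size_mm",
    "outcome_day3",
    "outcome_day10",
    "outcome_final",
    "interval_pre_mri_to_tace_days",
    "interval_tace_to_followup_days",
    "followup_modality",
)


def std(values, convention: str = "population") -> float:
    """Standard deviation under the configured convention.

    ``population`` divides by n (the convention that reproduces the
    descriptive statistics this package's fixtures are checked against);
    ``sample`` divides by n - 1.
    """
    values = np.asarray(values, dtype=float)
    if convention == "population":
        return float(np.std(values, ddof=0))
    if convention == "sample":
        return float(np.std(values, ddof=1))
    raise ValueError(f"unknown SD convention: {convention!r}")


# ---------------------------------------------------------------------------
# Acquisition schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSchedule:
    """Burst-phase frame timing.

    Parameters
    ----------
    phase_starts : sequence of float
        Start of each 30-s imaging phase, in seconds from injection.
        The pre-contrast phase starts at a negative time so that all of
        its frames precede injection.
    frames_per_phase : int
        Frames acquired within each phase (default 5).
    phase_duration : float
        Length of each phase in seconds (default 30).
    """

    phase_starts: tuple = (-30.0, 20.0, 60.0, 120.0, 180.0, 240.0, 330.0, 420.0, 510.0, 600.0)
    frames_per_phase: int = 5
    phase_duration: float = 30.0

    def __post_init__(self):
        starts = np.asarray(self.phase_starts, dtype=float)
        if starts.size < 1:
            raise ValidationError("schedule needs at least one phase")
        if np.any(np.diff(starts) <= 0):
            raise ValidationError("phase starts must be strictly increasing")
        if self.frames_per_phase < 1 or self.phase_duration <= 0:
            raise ValidationError("frames_per_phase >= 1 and phase_duration > 0 required")
        object.__setattr__(self, "phase_starts", tuple(float(s) for s in starts))
        t = self.frame_times
        if np.any(np.diff(t) <= 0):
            raise ValidationError("derived frame times are not strictly increasing")
        pre = t[t < 0]
        if pre.size and pre.max() >= 0:
            raise ValidationError("pre-contrast frames must precede injection")

    @property
    def n_phases(self) -> int:
        return len(self.phase_starts)

    @property
    def frame_times(self) -> np.ndarray:
        """Flat array of frame midpoint times (seconds from injection)."""
        dt = self.phase_duration / self.frames_per_phase
        offsets = (np.arange(self.frames_per_phase) + 0.5) * dt
        return (np.asarray(self.phase_starts)[:, None] + offsets[None, :]).ravel()

    @property
    def n_frames(self) -> int:
        return self.n_phases * self.frames_per_phase

    @property
    def n_baseline(self) -> int:
        """Number of frames acquired entirely before injection."""
        return int(np.sum(self.frame_times < 0))

    @property
    def phase_index(self) -> np.ndarray:
        """Phase membership of each frame."""
        return np.repeat(np.arange(self.n_phases), self.frames_per_phase)


def default_schedule() -> AcquisitionSchedule:
    """The packaged acquisition schedule.

    Pre-contrast phase at -30 s, an arterial-dominant phase starting
    20 s post-injection (frame midpoints 23-47 s), and late phases
    starting at 60, 120, 180, 240, 330, 420, 510 and 600 s.  Five frames
    over 30 s in each phase: 50 frames in total.
    """
    return AcquisitionSchedule()


# ---------------------------------------------------------------------------
# Signal curves
# ---------------------------------------------------------------------------

@dataclass
class SignalCurve:
    """Mean scanner signal over one ROI versus time.

    ``n_baseline`` is the number of leading pre-contrast frames used to
    estimate the baseline signal S0.
    """

    roi_id: str
    times: np.ndarray
    values: np.ndarray
    n_baseline: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValidationError(f"{self.roi_id}: times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.roi_id}: times must be strictly increasing")
        if not (1 <= self.n_baseline <= len(self.times)):
            raise ValidationError(f"{self.roi_id}: n_baseline must be in [1, n_frames]")

    def __len__(self) -> int:
        return len(self.times)


def phase_average(curve: SignalCurve, schedule: AcquisitionSchedule) -> SignalCurve:
    """Collapse each burst phase to a single frame at its mean time.

    Optional preprocessing for kinetic fitting; the default pipeline
    fits all frames jointly.
    """
    if len(curve) != schedule.n_frames:
        raise ValidationError("curve length does not match schedule")
    idx = schedule.phase_index
    t = np.array([curve.times[idx == p].mean() for p in range(schedule.n_phases)])
    v = np.array([curve.values[idx == p].mean() for p in range(schedule.n_phases)])
    n_base = int(np.sum(t < 0))
    return SignalCurve(curve.roi_id, t, v, max(n_base, 1))


def read_curve_table(path) -> list[SignalCurve]:
    """Read per-ROI signal curves from a CSV table.

    The table must have columns ``roi_id, time_s, signal, is_baseline``.
    Rows may appear in any order; within an ROI the (sorted) times must
    be strictly increasing and the baseline flags must mark at least one
    leading frame.
    """
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"curve table missing columns: {sorted(missing)}")
    curves = []
    for roi_id, grp in df.groupby("roi_id", sort=True):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"{roi_id}: duplicate or non-monotone times")
        base = grp["is_baseline"].astype(bool).to_numpy()
        n_base = int(base.sum())
        if n_base == 0:
            raise ValidationError(f"{roi_id}: no baseline frames flagged (cannot form S0)")
        if not base[:n_base].all():
            raise ValidationError(f"{roi_id}: baseline frames must be the earliest frames")
        curves.append(SignalCurve(str(roi_id), times, grp["signal"].to_numpy(dtype=float), n_base))
    return curves


def write_curve_table(curves: Iterable[SignalCurve], path) -> None:
    """Write curves to CSV in the format accepted by :func:`read_curve_table`."""
    rows = []
    for c in curves:
        for i, (t, v) in enumerate(zip(c.times, c.values)):
            rows.append((c.roi_id, t, v, i < c.n_baseline))
    pd.DataFrame(rows, columns=CURVE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROI extraction from image volumes
# ---------------------------------------------------------------------------

def extract_roi_curves(image_4d, masks, schedule: AcquisitionSchedule) -> list[SignalCurve]:
    """Spatial-mean signal curves for each labelled ROI of a 4-D volume.

    Parameters
    ----------
    image_4d : array, shape (x, y, z, t)
        Dynamic image series; the last axis must match the schedule's
        frame count.
    masks : int array, shape (x, y, z)
        Labelled ROI mask; labels >= 1 name ROIs, 0 is background.
    """
    img = np.asarray(image_4d, dtype=float)
    lab = np.asarray(masks)
    if img.ndim != 4:
        raise ValidationError("image must be 4-D (x, y, z, t)")
    if lab.shape != img.shape[:3]:
        raise ValidationError(f"mask shape {lab.shape} does not match image spatial shape {img.shape[:3]}")
    if img.shape[3] != schedule.n_frames:
        raise ValidationError(f"image has {img.shape[3]} frames, schedule expects {schedule.n_frames}")
    curves = []
    for label in np.unique(lab):
        if label < 1:
            continue
        sel = lab == label
        if not sel.any():  # pragma: no cover - unique() only returns present labels
            raise ValidationError(f"label {label} selects no voxels")
        mean_signal = img[sel].mean(axis=0)
        curves.append(SignalCurve(f"roi{int(label)}", schedule.frame_times.copy(), mean_signal, schedule.n_baseline))
    if not curves:
        raise ValidationError("mask contains no labels >= 1")
    return curves


def load_nifti_series(image_path, mask_path, schedule: AcquisitionSchedule) -> list[SignalCurve]:
    """Load a 4-D NIfTI volume plus labelled ROI mask and extract curves."""
    import nibabel as nib

    img = np.asanyarray(nib.load(str(image_path)).dataobj)
    lab = np.asanyarray(nib.load(str(mask_path)).dataobj).astype(int)
    return extract_roi_curves(img, lab, schedule)


# ---------------------------------------------------------------------------
# Study tables
# ---------------------------------------------------------------------------

@dataclass
class LesionRecord:
    """One lesion at one visit, with its kinetic parameters if fitted."""

    patient_id: str
    lesion_id: str
    segment: str
    size_mm: float
    timepoint: str
    ktrans: float | None = None  # ml/100 ml/min
    dv: float | None = None      # ml/100 ml
    mrecist_final: str | None = None

    def __post_init__(self):
        if self.size_mm <= 0:
            raise ValidationError("size_mm must be positive")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.dv is not None and not (0 <= self.dv <= 100):
            raise ValidationError("dv must lie in [0, 100] ml/100 ml")
        if self.ktrans is not None and self.ktrans < 0:
            raise ValidationError("ktrans must be non-negative")


@dataclass
class StudyDataset:
    """A study table: lesions, patient metadata, optional covariates.

    ``lesions`` has one row per lesion with the study-table columns;
    ``kinetics`` (optional) is long-format with one row per lesion per
    visit carrying ktrans/dv; ``angiogenesis`` (optional) is per patient
    per visit with Ang2 (pg/ml), VEGF (pg/ml) and c-KIT (ng/ml), shared
    by all lesions of a patient.
    """

    lesions: pd.DataFrame
    patients: pd.DataFrame = field(default=None)
    kinetics: pd.DataFrame | None = None
    angiogenesis: pd.DataFrame | None = None

    def __post_init__(self):
        df = self.lesions
        counts = df.groupby("patient_id")["lesion_id"].nunique()
        if (counts > 2).any():
            bad = counts[counts > 2].index.tolist()
            raise ValidationError(f"more than two lesions for patient(s) {bad}")
        if (df["size_mm"] <= 0).any():
            raise ValidationError("lesion sizes must be positive")
        if self.patients is None:
            keep = [c for c in ("gender", "age", "interval_pre_mri_to_tace_days",
                                "interval_tace_to_followup_days", "followup_modality")
                    if c in df.columns]
            self.patients = df.groupby("patient_id", sort=True)[keep].first().reset_index()

    @property
    def n_patients(self) -> int:
        return self.lesions["patient_id"].nunique()

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def to_records(self) -> list[LesionRecord]:
        """Flatten to per-lesion, per-visit records (kinetics required)."""
        if self.kinetics is None:
            raise ValidationError("dataset has no kinetic parameters")
        merged = self.kinetics.merge(
            self.lesions[["patient_id", "lesion_id", "segment", "size_mm", "outcome_final"]],
            on=["patient_id", "lesion_id"], how="left",
        )
        return [
            LesionRecord(
                patient_id=str(r.patient_id), lesion_id=str(r.lesion_id),
                segment=str(r.segment), size_mm=float(r.size_mm),
                timepoint=str(r.timepoint), ktrans=float(r.ktrans), dv=float(r.dv),
                mrecist_final=str(r.outcome_final),
            )
            for r in merged.itertuples()
        ]


def load_study_table(path=None) -> StudyDataset:
    """Load a study table CSV; with no path, the packaged cohort table.

    The packaged table lists the 21 lesions of the 11-patient cohort
    with per-visit mRECIST outcomes and the imaging intervals.
    """
    if path is None:
        path = resources.files("dcekit").joinpath("data/table1_study.csv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"study table missing columns: {sorted(missing)}")
    return StudyDataset(lesions=df)


def write_study_table(dataset: StudyDataset, path) -> None:
    dataset.lesions.to_csv(path, index=False)


def describe_cohort(dataset: StudyDataset, sd_convention: str = "population") -> dict:
    """Descriptive statistics of a study table.

    Returns patient/lesion counts, the mean +/- SD largest lesion
    dimension (mm) and the mean +/- SD interval between the pre-therapy
    MRI and embolization (days).
    """
    sizes = dataset.lesions["size_mm"].to_numpy(dtype=float)
    intervals = dataset.patients["interval_pre_mri_to_tace_days"].to_numpy(dtype=float)
    return {
        "n_patients": dataset.n_patients,
        "n_lesions": dataset.n_lesions,
        "size_mm_mean": float(np.mean(sizes)),
        "size_mm_sd": std(sizes, sd_convention),
        "interval_pre_mri_to_tace_mean_days": float(np.mean(intervals)),
        "interval_pre_mri_to_tace_sd_days": std(intervals, sd_convention),
    }
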