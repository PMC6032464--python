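"""Synthetic study generation.

Builds complete synthetic DCE-MRI studies — arterial input, per-lesion
signal curves on the burst sampling schedule, a study table with
response outcomes, and angiogenesis covariates — with the statistical
structure the downstream analysis assumes, so that the whole pipeline
is testable without patient data.

The per-group, per-visit kinetic parameter distributions default to the
published cohort statistics for responder and non-responder lesions
(DV falling from ~28 to ~9 ml/100 ml in responders across pre-therapy,
day-3 and day-10 visits, roughly stable near 30 in non-responders, and
the analogous Ktrans trajectories).  Draws use moment-matched
distributions: a truncated normal matched to the requested mean/SD for
cells with moderate spread, and a moment-matched lognormal for
high-variability cells (several Ktrans cells have SD exceeding the
mean, which no normal truncated to positive values can reproduce).
Either way the sampled marginal carries exactly the configured mean and
SD, so empirical group summaries converge to the configured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model_io import AcquisitionSchedule, SignalCurve, StudyDataset, default_schedule
from .exceptions import ValidationError
from .signal_conversion import ConcentrationCurve, Hematocrit, blood_to_plasma
from .tracer_kinetics import DV_BOUNDS, KTRANS_BOUNDS, KineticParams, tofts_forward

GROUPS = ("responder", "non_responder")

#: Published per-group, per-visit (mean, SD) for DV [ml/100 ml] and
#: Ktrans [ml/100 ml/min].
DEFAULT_PARAM_STATS = {
    "responder": {
        "dv": {"pre_tace": (28.4, 12.4), "day3": (14.2, 7.0), "day10": (8.6, 4.7)},
        "ktrans": {"pre_tace": (145.2, 151.3), "day3": (15.9, 15.3), "day10": (8.7, 9.5)},
    },
    "non_responder": {
        "dv": {"pre_tace": (32.3, 11.6), "day3": (24.5, 12.1), "day10": (27.0, 9.5)},
        "ktrans": {"pre_tace": (67.5, 66.5), "day3": (105.4, 197.3), "day10": (97.0, 166.0)},
    },
}

_PARAM_BOUNDS = {"dv": (DV_BOUNDS[0], DV_BOUNDS[1]), "ktrans": (1e-3, KTRANS_BOUNDS[1])}

#: Final-outcome composition within each response group (observed cohort mix).
_CATEGORY_MIX = {"responder": (("CR", 5 / 8), ("PR", 3 / 8)),
                 "non_responder": (("SD", 11 / 13), ("PD", 2 / 13))}


@dataclass
class CohortSpec:
    """Configuration of a synthetic study.

    Defaults emulate the published cohort: 11 patients, 21 lesions (at
    most two per patient), a responder fraction of 8/21, the burst
    acquisition schedule, bolus arrival 20 s after injection, fixed
    hematocrit 0.45, and baseline signal-to-noise ratio 20.
    """

    n_patients: int = 11
    n_lesions: int = 21
    max_lesions_per_patient: int = 2
    responder_prob: float = 8 / 21
    param_stats: dict = field(default_factory=lambda: DEFAULT_PARAM_STATS)
    noise_snr: float = 20.0
    schedule: AcquisitionSchedule = field(default_factory=default_schedule)
    bolus_arrival_s: float = 20.0
    hematocrit: float = 0.45
    s0_tissue: float = 200.0
    s0_blood: float = 150.0
    n_aorta_slices: int = 5
    patient_corr: float = 0.3       # latent correlation of a patient's two lesions
    ang2_spearman: float = 0.6      # target rank correlation of Ang2 with lesion DV
    seed: int = 0

    def __post_init__(self):
        if self.max_lesions_per_patient > 2:
            raise ValidationError("at most two lesions per patient are supported")
        if self.n_lesions > self.n_patients * self.max_lesions_per_patient:
            raise ValidationError("n_lesions exceeds patient capacity")
        if not (0 <= self.responder_prob <= 1):
            raise ValidationError("responder_prob must be a probability")
        if not (0 <= self.patient_corr < 1):
            raise ValidationError("patient_corr must lie in [0, 1)")
        for group in GROUPS:
            for param in ("dv", "ktrans"):
                for tp, (m, s) in self.param_stats[group][param].items():
                    if s < 0 or m <= 0:
                        raise ValidationError(f"bad (mean, sd) for {group}/{param}/{tp}")


@dataclass
class GroundTruth:
    """Truth ledger of a synthetic study, for recovery tests."""

    params: pd.DataFrame        # patient_id, lesion_id, timepoint, group, ktrans, dv
    angiogenesis: pd.DataFrame  # patient_id, timepoint, ang2, vegf, ckit

    def group_of(self, patient_id: str, lesion_id: str) -> str:
        sel = self.params[(self.params.patient_id == patient_id)
                          & (self.params.lesion_id == lesion_id)]
        groups = sel["group"].unique()
        assert len(groups) == 1
        return groups[0]


# ---------------------------------------------------------------------------
# Moment-matched marginals
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _matched_distribution(mean: float, sd: float, lo: float, hi: float):
    """A frozen scipy distribution on [lo, hi] with the requested moments.

    Truncated normal when the coefficient of variation permits it
    (CV < 0.8 stays comfortably inside the truncated-normal feasible
    region); moment-matched lognormal otherwise.
    """
    if sd == 0:
        return stats.uniform(loc=mean, scale=0.0)
    if sd / mean < 0.8:
        def moment_gap(theta):
            mu, log_sigma = theta
            sigma = math.exp(log_sigma)
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
            return [m - mean, math.sqrt(v) - sd]

        sol = optimize.root(moment_gap, x0=[mean, math.log(sd)], method="hybr")
        if sol.success:
            mu, sigma = sol.x[0], math.exp(sol.x[1])
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            return stats.truncnorm(a, b, loc=mu, scale=sigma)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))


def _draw_from_latent(z, mean, sd, lo, hi):
    """Transform standard-normal latents to the matched marginal (Gaussian copula)."""
    dist = _matched_distribution(float(mean), float(sd), float(lo), float(hi))
    u = stats.norm.cdf(np.clip(z, -8.0, 8.0))
    return np.clip(dist.ppf(u), lo, hi)


# ---------------------------------------------------------------------------
# Arterial input
# ---------------------------------------------------------------------------

def generate_aif(schedule: AcquisitionSchedule, bolus_arrival_s: float = 20.0,
                 seed: int | None = None) -> ConcentrationCurve:
    """Deterministic population arterial-blood input at the frame times.

    Gamma-variate first pass (peak relative enhancement ~3 about 10 s
    after bolus arrival) riding on a slow bi-exponential washout; zero
    before arrival.  ``seed`` is accepted for interface symmetry with
    the stochastic generators; the curve is deterministic.
    """
    t = schedule.frame_times
    if bolus_arrival_s >= t[-1]:
        raise ValidationError("bolus arrival lies after the last frame")
    ts = t - bolus_arrival_s
    peak, t_peak, alpha = 3.0, 10.0, 2.5
    first_pass = np.where(
        ts > 0, (np.maximum(ts, 0) / t_peak) ** alpha * np.exp(alpha * (1 - ts / t_peak)), 0.0)
    washout = np.where(
        ts > 0,
        0.45 * (1 - np.exp(-np.maximum(ts, 0) / 25.0))
        * (0.65 * np.exp(-np.maximum(ts, 0) / 350.0) + 0.35 * np.exp(-np.maximum(ts, 0) / 3000.0)),
        0.0)
    values = peak * (0.85 * first_pass + washout)
    return ConcentrationCurve("aif_true", t.copy(), values, "arterial_blood")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _assign_lesions(spec: CohortSpec) -> list[tuple[str, str]]:
    """Deterministic lesion->patient layout: fill patients up to capacity."""
    pairs = []
    per_patient = np.full(spec.n_patients, spec.n_lesions // spec.n_patients)
    per_patient[: spec.n_lesions - per_patient.sum()] += 1
    for p, k in enumerate(per_patient):
        for l in range(int(k)):
            pairs.append((f"p{p + 1:03d}", f"l{l + 1}"))
    return pairs


def generate_cohort(spec: CohortSpec):
    """Generate a full synthetic study.

    Returns
    -------
    dataset : StudyDataset
        Study table (per-lesion outcomes, demographics) with the
        angiogenesis covariate table attached.
    truth : GroundTruth
        True kinetic parameters and group labels per lesion and visit.
    curves : list of SignalCurve
        Noisy tissue signal curves for every lesion and visit plus
        aortic candidate curves per visit (roi ids
        ``{patient}_{lesion}_{timepoint}`` and
        ``aorta_s{slice}_{timepoint}``).
    """
    from .data_model_io import TIMEPOINTS

    rng = np.random.default_rng(spec.seed)
    pairs = _assign_lesions(spec)
    sched = spec.schedule
    frame_times = sched.frame_times

    aif_blood = generate_aif(sched, spec.bolus_arrival_s)
    cp_true = blood_to_plasma(aif_blood, Hematocrit(spec.hematocrit))

    groups = np.where(rng.random(len(pairs)) < spec.responder_prob,
                      "responder", "non_responder")

    # latent normals: shared patient factor + lesion-specific factor,
    # independently per visit and per parameter
    patient_ids = sorted({p for p, _ in pairs})
    p_index = {p: i for i, p in enumerate(patient_ids)}
    c = spec.patient_corr
    z_pat = rng.standard_normal((len(patient_ids), len(TIMEPOINTS), 2))
    z_les = rng.standard_normal((len(pairs), len(TIMEPOINTS), 2))
    z = math.sqrt(c) * z_pat[[p_index[p] for p, _ in pairs]] + math.sqrt(1 - c) * z_les

    truth_rows = []
    curves: list[SignalCurve] = []
    noise_sd_tissue = 0.0 if np.isinf(spec.noise_snr) else spec.s0_tissue / spec.noise_snr
    noise_sd_blood = 0.0 if np.isinf(spec.noise_snr) else spec.s0_blood / spec.noise_snr

    for i, ((pid, lid), group) in enumerate(zip(pairs, groups)):
        for j, tp in enumerate(TIMEPOINTS):
            dv = float(_draw_from_latent(z[i, j, 0], *spec.param_stats[group]["dv"][tp],
                                         *_PARAM_BOUNDS["dv"]))
            kt = float(_draw_from_latent(z[i, j, 1], *spec.param_stats[group]["ktrans"][tp],
                                         *_PARAM_BOUNDS["ktrans"]))
            truth_rows.append((pid, lid, tp, group, kt, dv))
            ct = tofts_forward(KineticParams(kt, dv), cp_true, frame_times)
            signal = spec.s0_tissue * (1.0 + ct.values)
            if noise_sd_tissue:
                signal = signal + rng.normal(0.0, noise_sd_tissue, size=signal.shape)
            curves.append(SignalCurve(f"{pid}_{lid}_{tp}", frame_times.copy(),
                                      signal, sched.n_baseline))

    for tp in TIMEPOINTS:
        for s in range(spec.n_aorta_slices):
            signal = spec.s0_blood * (1.0 + aif_blood.values)
            if noise_sd_blood:
                signal = signal + rng.normal(0.0, noise_sd_blood, size=signal.shape)
            curves.append(SignalCurve(f"aorta_s{s + 1}_{tp}", frame_times.copy(),
                                      signal, sched.n_baseline))

    truth_params = pd.DataFrame(
        truth_rows, columns=["patient_id", "lesion_id", "timepoint", "group", "ktrans", "dv"])

    # --- study table -------------------------------------------------------
    lesion_rows = []
    for i, ((pid, lid), group) in enumerate(zip(pairs, groups)):
        cats, probs = zip(*_CATEGORY_MIX[group])
        final = rng.choice(cats, p=probs)
        if group == "responder":
            early = final
        else:
            early = rng.choice(["CR", "PR", "SD"], p=[0.45, 0.2, 0.35])
        size = float(_draw_from_latent(rng.standard_normal(), 22.6, 17.9, 3.0, 120.0))
        lesion_rows.append((pid, lid, group, early, early, final, round(size, 1),
                            str(int(rng.integers(1, 9)))))
    lesions = pd.DataFrame(lesion_rows, columns=[
        "patient_id", "lesion_id", "group_true", "outcome_day3", "outcome_day10",
        "outcome_final", "size_mm", "segment"])

    pat_rows = []
    for pid in patient_ids:
        pat_rows.append((
            pid,
            "m" if rng.random() < 8 / 11 else "f",
            int(np.clip(round(rng.normal(65, 10)), 30, 90)),
            max(1, int(round(float(_draw_from_latent(rng.standard_normal(), 2.7, 2.0, 0.5, 15.0))))),
            max(30, int(round(rng.normal(71, 19)))),
            rng.choice(["CT", "CTHA", "MRI"], p=[0.8, 0.15, 0.05]),
        ))
    patients = pd.DataFrame(pat_rows, columns=[
        "patient_id", "gender", "age", "interval_pre_mri_to_tace_days",
        "interval_tace_to_followup_days", "followup_modality"])
    lesions = lesions.merge(patients, on="patient_id")

    # --- angiogenesis covariates ------------------------------------------
    # Ang2 is coupled to the patient-mean DV latent via a Gaussian copula so
    # that the lesion-level Spearman correlation approximates the target.
    rho = 2 * math.sin(math.pi * spec.ang2_spearman / 6)  # Pearson on latents
    ang_rows = []
    for pid in patient_ids:
        idx = [i for i, (p, _) in enumerate(pairs) if p == pid]
        for j, tp in enumerate(TIMEPOINTS):
            zbar = z[idx, j, 0].mean()
            fac = math.sqrt((1 + (len(idx) - 1) * c) / len(idx))
            zbar_std = zbar / fac
            rho_eff = min(rho / fac, 0.999)
            z_ang = rho_eff * zbar_std + math.sqrt(max(1 - rho_eff ** 2, 0.0)) * rng.standard_normal()
            ang2 = 3500.0 + 900.0 * z_ang
            vegf = max(1.0, rng.normal((80.0, 95.0, 220.0)[j], 50.0))
            ckit = max(0.5, rng.normal(8.5, 2.0))
            ang_rows.append((pid, tp, round(ang2, 1), round(vegf, 1), round(ckit, 2)))
    angiogenesis = pd.DataFrame(ang_rows, columns=["patient_id", "timepoint", "ang2", "vegf", "ckit"])

    dataset = StudyDataset(lesions=lesions, patients=patients,
                           kinetics=None, angiogenesis=angiogenesis)
    truth = GroundTruth(params=truth_params, angiogenesis=angiogenesis)
    return dataset, truth, curves


# ---------------------------------------------------------------------------
# Minimal image phantom (for testing ROI extraction only)
# ---------------------------------------------------------------------------

def make_block_phantom(curves, background: float = 10.0):
    """Broadcast signal curves into labelled blocks of a 4-D volume.

    Each curve fills a 2x2x2 voxel block labelled 1..n; the rest of the
    volume is constant background.  Returns ``(image_4d, mask)``.
    """
    curves = list(curves)
    n = len(curves)
    n_frames = len(curves[0])
    img = np.full((2 * n, 2, 2, n_frames), background, dtype=float)
    mask = np.zeros((2 * n, 2, 2), dtype=int)
    for i, c in enumerate(curves):
        if len(c) != n_frames:
            raise ValidationError("phantom curves must share a common length")
        img[2 * i: 2 * i + 2, :, :, :] = c.values[None, None, None, :]
        mask[2 * i: 2 * i + 2, :, :] = i + 1
    return img, mask
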