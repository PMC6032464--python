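"""End-to-end analysis pipeline: curves -> fits -> study statistics.

Glue used by both the command-line interface and the acceptance
machinery.  Curve naming convention (produced by the synthetic
generator and expected here): tissue curves are named
``{patient}_{lesion}_{timepoint}`` and aortic candidates
``aorta_s{slice}_{timepoint}``, with timepoints ``pre_tace``, ``day3``
and ``day10``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .data_model_io import TIMEPOINTS, SignalCurve, StudyDataset, describe_cohort
from .exceptions import ValidationError
from .group_statistics import (RepeatedAnovaResult, StatResult, anova_across_time,
                               friedman_test, mann_whitney_u, spearman_correlation,
                               summarize_groups)
from .response_diagnostics import cutoff_report_table, group_of, group_responders, \
    mixed_outcome_patients
from .signal_conversion import Hematocrit, blood_to_plasma, semi_auto_aif, \
    signal_to_concentration
from .tracer_kinetics import fit_tofts


def _split_roi(roi_id: str):
    """roi id -> (kind, patient, lesion, timepoint)."""
    for tp in TIMEPOINTS:
        if roi_id.endswith("_" + tp):
            stem = roi_id[: -len(tp) - 1]
            if stem.startswith("aorta"):
                return "aorta", None, None, tp
            parts = stem.split("_")
            if len(parts) != 2:
                raise ValidationError(f"cannot parse roi id {roi_id!r}")
            return "tissue", parts[0], parts[1], tp
    raise ValidationError(f"roi id {roi_id!r} carries no known timepoint suffix")


def fit_study_curves(curves: list[SignalCurve], config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Fit every tissue curve of a study against its visit's AIF.

    Per visit: aortic candidate curves are converted to enhancement,
    merged by the semi-automatic rule, hematocrit-corrected to plasma,
    and used as the input function for all of that visit's lesion fits.

    Returns a table with one row per lesion per visit:
    ``patient_id, lesion_id, timepoint, ktrans, dv, rss, converged``.
    """
    config = config or AnalysisConfig()
    aorta: dict[str, list] = {tp: [] for tp in TIMEPOINTS}
    tissue: dict[str, list] = {tp: [] for tp in TIMEPOINTS}
    for c in curves:
        kind, pid, lid, tp = _split_roi(c.roi_id)
        if kind == "aorta":
            aorta[tp].append(signal_to_concentration(c, kind="arterial_blood",
                                                     s0_floor=config.s0_floor))
        else:
            tissue[tp].append((pid, lid, signal_to_concentration(c, s0_floor=config.s0_floor)))

    rows = []
    hct = Hematocrit(config.hematocrit)
    for tp in TIMEPOINTS:
        if not tissue[tp]:
            continue
        if not aorta[tp]:
            raise ValidationError(f"no aortic curves for timepoint {tp}")
        cb = semi_auto_aif(aorta[tp], peak_fraction=config.aif_peak_fraction)
        cp = blood_to_plasma(cb, hct)
        for pid, lid, ct in tissue[tp]:
            fit = fit_tofts(ct, cp, n_starts=config.fit_n_starts, tol=config.fit_tol)
            rows.append((pid, lid, tp, fit.params.ktrans, fit.params.dv,
                         fit.rss, fit.converged))
    return pd.DataFrame(rows, columns=["patient_id", "lesion_id", "timepoint",
                                       "ktrans", "dv", "rss", "converged"])


def attach_kinetics(dataset: StudyDataset, fits: pd.DataFrame) -> StudyDataset:
    """Return a dataset with the fitted parameters attached."""
    return StudyDataset(lesions=dataset.lesions, patients=dataset.patients,
                        kinetics=fits, angiogenesis=dataset.angiogenesis)


def _sr(result: StatResult | None) -> dict | None:
    if result is None:
        return None
    return {"statistic": result.statistic, "p_value": result.p_value,
            "method": result.method, "exact": result.exact}


def _complete_matrix(kin: pd.DataFrame, parameter: str) -> tuple[np.ndarray, list]:
    """Lesions x timepoints matrix keeping complete cases only."""
    wide = kin.pivot_table(index=["patient_id", "lesion_id"], columns="timepoint",
                           values=parameter)
    wide = wide.reindex(columns=list(TIMEPOINTS)).dropna()
    return wide.to_numpy(dtype=float), list(wide.index)


def analyze_study(dataset: StudyDataset, config: AnalysisConfig | None = None) -> dict:
    """The study's statistical layer on a fitted dataset.

    Computes per-group summary tables, within-group Friedman tests
    across the three visits, between-group Mann-Whitney tests per
    visit, the DV cutoff diagnostic table, and — when angiogenesis
    covariates are present — the DV-Ang2 rank correlation and
    repeated-measures ANOVAs of each covariate.
    """
    config = config or AnalysisConfig()
    if dataset.kinetics is None:
        raise ValidationError("dataset carries no kinetic parameters; fit first")
    kin = dataset.kinetics.merge(
        dataset.lesions[["patient_id", "lesion_id", "outcome_final"]],
        on=["patient_id", "lesion_id"], how="inner")
    kin["group"] = kin["outcome_final"].map(group_of)

    out: dict = {"grouping": group_responders(dataset.lesions["outcome_final"]),
                 "mixed_outcome_patients": mixed_outcome_patients(dataset)[0]}
    if "interval_pre_mri_to_tace_days" in dataset.patients.columns:
        out["descriptives"] = describe_cohort(dataset, config.sd_convention)

    out["summary"] = {}
    out["friedman"] = {}
    out["mann_whitney"] = {}
    for parameter in ("dv", "ktrans"):
        table = summarize_groups(dataset, parameter, config.sd_convention)
        out["summary"][parameter] = table.to_dict(orient="records")
        out["friedman"][parameter] = {}
        for group in ("responder", "non_responder"):
            sub = kin[kin["group"] == group]
            matrix, _ = _complete_matrix(sub, parameter)
            if matrix.shape[0] >= 2:
                out["friedman"][parameter][group] = _sr(
                    friedman_test(matrix, config.friedman_exact_threshold))
        out["mann_whitney"][parameter] = {}
        for tp in TIMEPOINTS:
            sub = kin[kin["timepoint"] == tp]
            xs = sub.loc[sub["group"] == "responder", parameter].to_numpy(dtype=float)
            ys = sub.loc[sub["group"] == "non_responder", parameter].to_numpy(dtype=float)
            if xs.size and ys.size:
                out["mann_whitney"][parameter][tp] = _sr(
                    mann_whitney_u(xs, ys, config.mannwhitney_exact_limit))

    # diagnostic cutoff table on DV
    wide, index = _complete_matrix(kin, "dv")
    group_by_lesion = {key: g for key, g in
                       kin.groupby(["patient_id", "lesion_id"])["group"].first().items()}
    groups = [group_by_lesion[key] for key in index]
    dv_by_tp = {tp: wide[:, j] for j, tp in enumerate(TIMEPOINTS)}
    diag = cutoff_report_table(dv_by_tp, groups, config.dv_cutoffs)
    out["diagnostics"] = diag.to_dict(orient="records")

    # angiogenesis covariates (per patient, duplicated across lesions)
    if dataset.angiogenesis is not None:
        ang = dataset.angiogenesis
        merged = kin.merge(ang, on=["patient_id", "timepoint"], how="inner")
        out["spearman_dv_ang2"] = _sr(spearman_correlation(
            merged["dv"], merged["ang2"], config.spearman_exact_limit))
        out["anova"] = {}
        for cov in ("ang2", "vegf", "ckit"):
            wide_cov = ang.pivot_table(index="patient_id", columns="timepoint",
                                       values=cov).reindex(columns=list(TIMEPOINTS)).dropna()
            pat_group = (kin.groupby("patient_id")["group"]
                         .agg(lambda s: "responder" if (s == "responder").any() else "non_responder"))
            common = wide_cov.index.intersection(pat_group.index)
            wide_cov = wide_cov.loc[common]
            labels = pat_group.loc[common].to_numpy()
            if len(np.unique(labels)) >= 2 and len(common) > len(np.unique(labels)):
                res: RepeatedAnovaResult = anova_across_time(wide_cov.to_numpy(dtype=float), labels)
                out["anova"][cov] = {"time": _sr(res.time),
                                     "interaction": _sr(res.interaction),
                                     "group": _sr(res.group)}
    return out
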