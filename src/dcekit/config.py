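"""YAML-backed configuration objects."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .data_model_io import AcquisitionSchedule
from .exceptions import FormatError
from .response_diagnostics import DEFAULT_DV_CUTOFFS
from .synthetic_cohort import CohortSpec


@dataclass
class AnalysisConfig:
    """Tunables of the analysis pipeline, with the packaged defaults.

    ``dv_cutoffs`` are the per-visit DV thresholds (ml/100 ml) used for
    response prediction; the defaults are the study's operating
    cutoffs.  ``sd_convention`` selects population (divide-by-n) or
    sample SD for all descriptive statistics and the mean+2SD cutoff
    rule.
    """

    hematocrit: float = 0.45
    aif_peak_fraction: float = 0.5
    sd_convention: str = "population"
    s0_floor: float = 1e-9
    tsvd_reg: float = 0.15
    dv_cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_DV_CUTOFFS))
    friedman_exact_threshold: int = 8
    mannwhitney_exact_limit: int = 25
    spearman_exact_limit: int = 9
    fit_n_starts: int = 3
    fit_tol: float = 1e-8

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def cohort_spec_from_yaml(path, seed: int | None = None) -> CohortSpec:
    """Build a :class:`CohortSpec` from a YAML mapping.

    Recognized keys mirror the dataclass fields; ``schedule`` may be a
    mapping with ``phase_starts``, ``frames_per_phase`` and
    ``phase_duration``.  ``seed`` (if given) overrides the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "schedule" in raw and isinstance(raw["schedule"], dict):
        raw["schedule"] = AcquisitionSchedule(**{
            k: tuple(v) if k == "phase_starts" else v for k, v in raw["schedule"].items()})
    if "param_stats" in raw:
        raw["param_stats"] = {
            g: {p: {tp: tuple(ms) for tp, ms in tps.items()} for p, tps in params.items()}
            for g, params in raw["param_stats"].items()}
    known = {f.name for f in fields(CohortSpec)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown cohort spec keys: {sorted(unknown)}")
    if seed is not None:
        raw["seed"] = seed
    return CohortSpec(**raw)
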