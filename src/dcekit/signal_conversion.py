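"""Signal-to-concentration conversion and arterial input handling.

Tracer concentration is approximated by the relative signal
enhancement S(t)/S0 - 1, with S0 the mean pre-contrast signal.  For a
spoiled gradient-echo acquisition at low contrast dose the enhancement
is approximately proportional to gadolinium concentration, so relative
enhancement serves directly as the concentration proxy; no relaxivity
calibration to mM is attempted.  Arterial blood enhancement is
converted to plasma concentration by dividing by (1 - Hct), with a
fixed hematocrit of 0.45 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model_io import SignalCurve
from .exceptions import ConversionError, ValidationError

CURVE_KINDS = ("tissue", "arterial_blood", "arterial_plasma")


@dataclass
class ConcentrationCurve:
    """Time-resolved tracer concentration (relative-enhancement units)."""

    roi_id: str
    times: np.ndarray
    values: np.ndarray
    kind: str = "tissue"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError(f"{self.roi_id}: times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.roi_id}: times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.roi_id}: concentration values must be finite")
        if self.kind not in CURVE_KINDS:
            raise ValidationError(f"unknown curve kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Hematocrit:
    """Volume fraction of red cells in whole blood."""

    value: float = 0.45

    def __post_init__(self):
        if not (0 < self.value < 1):
            raise ValidationError("hematocrit must lie strictly between 0 and 1")


def signal_to_concentration(curve: SignalCurve, kind: str = "tissue",
                            s0_floor: float = 1e-9) -> ConcentrationCurve:
    """Convert a signal curve to relative enhancement C(t) = S(t)/S0 - 1.

    S0 is the arithmetic mean of the curve's ``n_baseline`` pre-contrast
    frames.  Baseline frames therefore map to values scattered around 0.

    Raises
    ------
    ConversionError
        If S0 is non-positive or below ``s0_floor``.
    """
    s0 = float(np.mean(curve.values[: curve.n_baseline]))
    if s0 <= 0 or s0 < s0_floor:
        raise ConversionError(f"{curve.roi_id}: baseline signal S0={s0:.3g} is not usable")
    return ConcentrationCurve(curve.roi_id, curve.times.copy(), curve.values / s0 - 1.0, kind)


def blood_to_plasma(curve: ConcentrationCurve, hct: Hematocrit | float = Hematocrit()) -> ConcentrationCurve:
    """Scale arterial blood concentration to plasma: Cp = Cb / (1 - Hct)."""
    if curve.kind != "arterial_blood":
        raise TypeError(f"expected an arterial_blood curve, got kind {curve.kind!r}")
    h = hct.value if isinstance(hct, Hematocrit) else float(hct)
    if not (0 <= h < 1):
        raise ValidationError("hematocrit fraction must lie in [0, 1)")
    return ConcentrationCurve(curve.roi_id, curve.times.copy(), curve.values / (1.0 - h), "arterial_plasma")


def semi_auto_aif(candidate_curves, seed_roi: str | None = None,
                  peak_fraction: float = 0.5) -> ConcentrationCurve:
    """Average candidate aortic curves into one arterial input function.

    Emulates semi-automatic AIF definition over several aortic slices:
    candidates whose peak enhancement falls below ``peak_fraction`` of
    the best candidate's peak (flow voids, partial-volume slices) are
    excluded, and the surviving curves are averaged.

    Parameters
    ----------
    candidate_curves : iterable of ConcentrationCurve
        Arterial-blood curves sampled on a common time grid.
    seed_roi : str, optional
        If given, only candidates whose roi_id starts with this prefix
        are considered.
    """
    curves = list(candidate_curves)
    if seed_roi is not None:
        curves = [c for c in curves if c.roi_id.startswith(seed_roi)]
    if not curves:
        raise ValidationError("no candidate curves for AIF definition")
    times = curves[0].times
    for c in curves[1:]:
        if not np.allclose(c.times, times):
            raise ValidationError("AIF candidates must share a common time grid")
    peaks = np.array([c.values.max() for c in curves])
    best = peaks.max()
    if best <= 0:
        raise ValidationError("no candidate shows positive enhancement")
    kept = [c for c, p in zip(curves, peaks) if p >= peak_fraction * best]
    if not kept:  # pragma: no cover - the best candidate always survives
        raise ValidationError("all AIF candidates excluded")
    mean_values = np.mean([c.values for c in kept], axis=0)
    return ConcentrationCurve("aif", times.copy(), mean_values, "arterial_blood")
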