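"""One-compartment tracer-kinetic model: forward model, fitting, deconvolution.

The tissue is modelled as a single well-mixed compartment fed by the
arterial plasma concentration Cp(t):

    dCt/dt = Ktrans' * Cp(t) - kep * Ct(t),      kep = Ktrans' / v

so that

    Ct(t) = Ktrans' * integral_0^t Cp(tau) exp(-kep (t - tau)) dtau.

Externally Ktrans is expressed in ml/100 ml/min and the distribution
volume DV in ml/100 ml (the units in which liver DCE-MRI results are
reported); internally both are converted to per-second rate and
fractional volume.  With a hepatocyte-specific contrast agent DV
aggregates plasma, interstitial and intracellular space, which is why a
pure one-compartment description (no separate plasma-volume term) is
used.

Cp is treated as piecewise linear between its samples and the
convolution integral is evaluated in closed form on each interval, so
the forward model is exact for piecewise-linear inputs and costs O(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, linalg, optimize

from .exceptions import DomainError, FitError, ValidationError
from .signal_conversion import ConcentrationCurve

KTRANS_BOUNDS = (0.0, 1000.0)   # ml/100 ml/min
DV_BOUNDS = (1e-2, 100.0)       # ml/100 ml

#: (ml/100 ml/min) -> (fraction/s): divide by 100, divide by 60.
_PER_MIN_PER_100ML = 6000.0


@dataclass(frozen=True)
class KineticParams:
    """Transfer constant and distribution volume of the one-compartment model."""

    ktrans: float  # ml/100 ml/min
    dv: float      # ml/100 ml

    def __post_init__(self):
        if not (self.ktrans >= 0):
            raise DomainError("ktrans must be non-negative")
        if not (0 < self.dv <= 100):
            raise DomainError("dv must lie in (0, 100] ml/100 ml")

    @property
    def kep_per_s(self) -> float:
        """Efflux rate constant kep = Ktrans / DV, in 1/s."""
        return self.ktrans / (60.0 * self.dv)


@dataclass
class KineticFit:
    """Result of fitting the one-compartment model to one tissue curve."""

    params: KineticParams
    rss: float
    converged: bool
    n_points: int
    fitted_curve: ConcentrationCurve


@dataclass
class PlasmaFlowResult:
    """Model-free deconvolution output for ROI-guidance plasma-flow maps."""

    pf: float                    # ml/100 ml/min
    impulse_response: np.ndarray  # f * R(t), ml/100 ml/min
    times: np.ndarray


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

class _ForwardGeometry:
    """Precomputed time geometry shared by all forward evaluations.

    Knots are the union of the Cp sample times and the requested output
    times, restricted to t >= 0 (tracer cannot be present before
    injection); Cp is linearly interpolated onto them once.
    """

    def __init__(self, cp_times, cp_values, eval_times):
        cp_times = np.asarray(cp_times, dtype=float)
        eval_times = np.asarray(eval_times, dtype=float)
        if eval_times.min() < cp_times[0] - 1e-9 or eval_times.max() > cp_times[-1] + 1e-9:
            raise ValidationError("eval_times must lie within the Cp time span")
        knots = np.union1d(np.union1d(cp_times, eval_times), [0.0])
        knots = knots[(knots >= 0.0) & (knots <= cp_times[-1] + 1e-12)]
        self.knots = knots
        self.cp_at_knots = np.interp(knots, cp_times, cp_values)
        self.h = np.diff(knots)
        self.c0 = self.cp_at_knots[:-1]
        self.slope = np.diff(self.cp_at_knots) / self.h
        self.eval_times = eval_times
        self.negative = eval_times < 0
        # index of each non-negative eval time within the knot array
        self.eval_idx = np.searchsorted(knots, eval_times[~self.negative])

    def evaluate(self, ktrans: float, dv: float) -> np.ndarray:
        """Ct at the requested eval times for the given external-unit params."""
        out = np.zeros_like(self.eval_times)
        if ktrans == 0.0:
            return out
        kt_s = ktrans / _PER_MIN_PER_100ML
        kep = ktrans / (60.0 * dv)
        x = kep * self.h
        small = x < 1e-6
        with np.errstate(over="ignore"):
            decay = np.exp(-x)
        # per-interval integral of (c0 + slope*u) * exp(-kep*(h-u)) du
        a = np.where(small, self.h * (1.0 - x / 2.0 + x * x / 6.0), -np.expm1(-x) / kep)
        b = np.where(small, self.h ** 2 * (0.5 - x / 6.0 + x * x / 24.0),
                     (self.h - a) / max(kep, 1e-300))
        q = kt_s * (self.c0 * a + self.slope * b)
        y = np.empty(len(self.knots))
        y[0] = 0.0
        acc = 0.0
        for j in range(len(self.h)):
            acc = acc * decay[j] + q[j]
            y[j + 1] = acc
        out[~self.negative] = y[self.eval_idx]
        return out


def tofts_forward(params: KineticParams, cp: ConcentrationCurve,
                  eval_times, roi_id: str = "tissue") -> ConcentrationCurve:
    """Simulate the tissue concentration curve for given kinetic parameters.

    Parameters
    ----------
    params : KineticParams
        Ktrans (ml/100 ml/min) and DV (ml/100 ml).
    cp : ConcentrationCurve
        Arterial plasma input, piecewise linear between samples.
    eval_times : array of float
        Output times (seconds); must lie within the span of ``cp.times``.
        Times before injection (t < 0) map to zero concentration.
    """
    if cp.kind != "arterial_plasma":
        raise TypeError(f"cp must be an arterial_plasma curve, got {cp.kind!r}")
    geom = _ForwardGeometry(cp.times, cp.values, eval_times)
    return ConcentrationCurve(roi_id, np.asarray(eval_times, dtype=float),
                              geom.evaluate(params.ktrans, params.dv), "tissue")


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

def _linearized_start(ct: ConcentrationCurve, cp: ConcentrationCurve) -> tuple[float, float]:
    """Initial (ktrans, dv) from the integral form of the compartment ODE.

    Integrating the ODE gives Ct(t) = Ktrans' I[Cp](t) - kep I[Ct](t),
    linear in (Ktrans', kep); a least-squares solve on cumulative
    trapezoidal integrals yields a starting point (Murase-style
    linearization).
    """
    mask = ct.times >= 0
    t = ct.times[mask]
    y = ct.values[mask]
    cpv = np.interp(t, cp.times, cp.values)
    x1 = integrate.cumulative_trapezoid(cpv, t, initial=0.0)
    x2 = integrate.cumulative_trapezoid(y, t, initial=0.0)
    design = np.column_stack([x1, -x2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    kt = float(np.clip(coef[0] * _PER_MIN_PER_100ML, 1e-3, KTRANS_BOUNDS[1]))
    kep_per_min = coef[1] * 60.0
    if kep_per_min > 1e-9:
        dv = float(np.clip(kt / kep_per_min, *DV_BOUNDS))
    else:
        dv = 50.0
    return kt, dv


def fit_tofts(ct: ConcentrationCurve, cp: ConcentrationCurve,
              n_starts: int = 3, tol: float = 1e-8) -> KineticFit:
    """Estimate Ktrans and DV by bounded nonlinear least squares.

    Multi-start strategy: the linearized-solve initial point plus the
    same point with Ktrans scaled by 0.3 and 3, to guard against local
    minima under sparse burst sampling.  Bounds: Ktrans in [0, 1000]
    ml/100 ml/min, DV in (0, 100] ml/100 ml.

    A degenerate, identically-zero tissue curve returns Ktrans = 0 with
    ``converged=True`` (DV is unidentifiable there and is reported as
    the mid-range placeholder 50).
    """
    if ct.kind != "tissue":
        raise TypeError(f"ct must be a tissue curve, got {ct.kind!r}")
    if cp.kind != "arterial_plasma":
        raise TypeError(f"cp must be an arterial_plasma curve, got {cp.kind!r}")
    n_post = int(np.sum(ct.times > 0))
    if n_post < 4:
        raise FitError(f"{ct.roi_id}: need at least 4 post-injection samples, have {n_post}")

    geom = _ForwardGeometry(cp.times, cp.values, ct.times)
    y = ct.values

    if np.max(np.abs(y)) < 1e-12:
        params = KineticParams(0.0, 50.0)
        fitted = ConcentrationCurve(ct.roi_id, ct.times.copy(), np.zeros_like(y), "tissue")
        return KineticFit(params, 0.0, True, len(y), fitted)

    def residuals(theta):
        return geom.evaluate(theta[0], theta[1]) - y

    kt0, dv0 = _linearized_start(ct, cp)
    starts = [(kt0, dv0)]
    for s in (0.3, 3.0):
        starts.append((float(np.clip(kt0 * s, 1e-3, KTRANS_BOUNDS[1])), dv0))
    starts = starts[:max(1, n_starts)]

    lower = np.array([KTRANS_BOUNDS[0], DV_BOUNDS[0]])
    upper = np.array([KTRANS_BOUNDS[1], DV_BOUNDS[1]])
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower + 1e-12, upper)
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lower, upper),
                                         method="trf", xtol=tol, ftol=tol, gtol=tol)
        except Exception:  # optimizer breakdown from one start is not fatal
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        params = KineticParams(kt0, dv0)
        fitted = tofts_forward(params, cp, ct.times, ct.roi_id)
        return KineticFit(params, float(np.sum(residuals((kt0, dv0)) ** 2)),
                          False, len(y), fitted)

    params = KineticParams(float(best.x[0]), float(best.x[1]))
    fitted_values = geom.evaluate(*best.x)
    fitted = ConcentrationCurve(ct.roi_id, ct.times.copy(), fitted_values, "tissue")
    return KineticFit(params, float(2.0 * best.cost), bool(best.success), len(y), fitted)


# ---------------------------------------------------------------------------
# Model-free deconvolution (plasma-flow maps)
# ---------------------------------------------------------------------------

def plasma_flow_deconvolution(ct: ConcentrationCurve, cp: ConcentrationCurve,
                              reg: float = 0.15, dt: float | None = None) -> PlasmaFlowResult:
    """Recover f * R(t) from Ct = f (Cp * R) by truncated-SVD deconvolution.

    Both curves are resampled onto a uniform grid from injection to the
    end of the shorter curve; the discretized convolution matrix is
    inverted with singular values below ``reg`` times the largest one
    set aside.  The plasma flow estimate is the peak of the recovered
    impulse response (R(0) = 1 for a causal residue function).
    """
    if not (0 <= reg < 1):
        raise ValidationError("reg must lie in [0, 1)")
    t_end = min(ct.times[-1], cp.times[-1])
    if dt is None:
        post = ct.times[ct.times >= 0]
        dt = float(np.median(np.diff(post))) if len(post) > 1 else 1.0
    grid = np.arange(0.0, t_end + dt / 2, dt)
    if len(grid) < 3:
        raise ValidationError("time span too short for deconvolution")
    ctg = np.interp(grid, ct.times, ct.values)
    cpg = np.interp(grid, cp.times, cp.values)

    conv = linalg.toeplitz(cpg, np.zeros_like(cpg)) * dt
    u, s, vt = np.linalg.svd(conv, full_matrices=False)
    keep = s >= reg * s[0] if s[0] > 0 else np.zeros_like(s, dtype=bool)
    if not keep.any():
        raise ValidationError("all singular values truncated; input Cp may be zero")
    inv_s = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    h = vt.T @ (inv_s * (u.T @ ctg))  # fraction/s
    h = h * _PER_MIN_PER_100ML        # ml/100 ml/min
    h[0] = max(h[0], 0.0)
    pf = float(max(h.max(), 0.0))
    return PlasmaFlowResult(pf=pf, impulse_response=h, times=grid)
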