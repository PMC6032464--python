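"""Nonparametric and repeated-measures statistics for small cohorts.

The study design compares perfusion parameters within lesions across
three visits (Friedman test), between responder and non-responder
groups (Mann-Whitney U), against angiogenesis covariates (Spearman rank
correlation), and evaluates covariate changes over time with a mixed
two-way repeated-measures ANOVA (between-subject group factor, within-
subject time factor).

With 8 and 13 lesions per group, asymptotic p-values are shaky, so the
rank tests compute exact permutation p-values below configurable sample
-size thresholds (full enumeration of rank assignments) and fall back
to the usual tie-corrected asymptotics above them.  ``StatResult.exact``
records which route was taken.  No multiple-testing correction is
applied by default; :func:`holm_adjust` is available for callers that
want one.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import TIMEPOINTS, StudyDataset, std
from .exceptions import ValidationError
from .response_diagnostics import group_of


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its p-value and provenance."""

    statistic: float | None
    p_value: float | None
    method: str
    exact: bool = False

    def __post_init__(self):
        if self.p_value is not None and not (0 <= self.p_value <= 1):
            raise ValidationError("p-value outside [0, 1]")


@dataclass(frozen=True)
class RepeatedAnovaResult:
    """F tests of a mixed two-way repeated-measures ANOVA."""

    time: StatResult
    interaction: StatResult
    group: StatResult


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from within-row mid-ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    a = float((ranks ** 2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    denom = a - c
    if denom <= 1e-12:  # all rows constant
        return 0.0
    return (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / denom


def friedman_test(values, exact_threshold: int = 8) -> StatResult:
    """Friedman test across k >= 3 repeated conditions.

    For n <= ``exact_threshold`` rows the p-value is exact: the null
    distribution is built by enumerating all (k!)^n independent
    permutations of each row's rank vector (a dynamic program over
    column rank sums keeps this cheap).  Larger n uses the chi-square
    approximation with k - 1 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 3:
        raise ValidationError("need a 2-D matrix with >= 2 rows and >= 3 columns")
    if not np.all(np.isfinite(x)):
        raise ValidationError("missing cells are not allowed")
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    statistic = _friedman_statistic(ranks)

    if n <= exact_threshold and math.factorial(k) <= 720:
        # DP over column sums of doubled ranks (mid-ranks are halves)
        perms = list(itertools.permutations(range(k)))
        states: dict[tuple, int] = {tuple([0] * k): 1}
        for i in range(n):
            row2 = np.rint(2 * ranks[i]).astype(int)
            contribs = [tuple(row2[list(p)]) for p in perms]
            new: dict[tuple, int] = {}
            for key, cnt in states.items():
                for contrib in contribs:
                    nk = tuple(key[j] + contrib[j] for j in range(k))
                    new[nk] = new.get(nk, 0) + cnt
            states = new
        a = float((ranks ** 2).sum())
        c = n * k * (k + 1) ** 2 / 4.0
        denom = a - c
        total = len(perms) ** n
        if denom <= 1e-12:
            return StatResult(0.0, 1.0, "friedman (exact)", True)
        hits = 0
        center = n * (k + 1) / 2.0
        for key, cnt in states.items():
            t = (k - 1) * sum((v / 2.0 - center) ** 2 for v in key) / denom
            if t >= statistic - 1e-9:
                hits += cnt
        return StatResult(statistic, hits / total, "friedman (exact)", True)

    p = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    return StatResult(statistic, min(p, 1.0), "friedman (chi-square approx.)", False)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y, exact_limit: int = 25) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of group assignments when the pooled sample is at
    most ``exact_limit`` and tie-free; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = tie_free and pooled.size <= exact_limit
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if use_exact else "asymptotic")
    return StatResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "mann-whitney (exact)" if use_exact else "mann-whitney (normal approx.)",
                      use_exact)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman_correlation(x, y, exact_limit: int = 9) -> StatResult:
    """Spearman rank correlation with mid-ranks for ties.

    For n <= ``exact_limit`` the two-sided p-value is exact, by
    enumerating all n! pairings of the observed rank vectors; larger n
    uses the t approximation.  Zero variance in either variable leaves
    the correlation undefined (statistic and p None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    sx = xr.std()
    sy = yr.std()
    if sx == 0 or sy == 0:
        return StatResult(None, None, "spearman (undefined: zero variance)", False)
    n = x.size
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    rho = float((xc @ yc) / (n * sx * sy))

    if n <= exact_limit:
        perms = np.array(list(itertools.permutations(yr)))
        rho_perm = ((perms - yr.mean()) @ xc) / (n * sx * sy)
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return StatResult(rho, p, "spearman (exact permutation)", True)

    if abs(rho) >= 1.0:
        return StatResult(rho, 0.0, "spearman (t approx.)", False)
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return StatResult(rho, min(p, 1.0), "spearman (t approx.)", False)


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

def anova_across_time(values, groups) -> RepeatedAnovaResult:
    """Mixed two-way ANOVA: within-subject time, between-subject group.

    Parameters
    ----------
    values : array, shape (n_subjects, k_times)
        Complete measurements; no missing cells.
    groups : sequence of hashable, length n_subjects
        Group label per subject.

    A perfectly noise-free effect (zero error mean square with non-zero
    effect mean square) is reported as an infinite F with p = 0; a
    fully degenerate design (no error degrees of freedom or a single
    group) raises.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 2 or y.shape[0] != groups.shape[0]:
        raise ValidationError("values must be (n_subjects, k) aligned with groups")
    if not np.all(np.isfinite(y)):
        raise ValidationError("missing cells are not allowed")
    n, k = y.shape
    labels = np.unique(groups)
    g = labels.size
    if g < 2 or k < 2 or n <= g:
        raise ValidationError("singular design: need >= 2 groups, >= 2 times, n > n_groups")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    ss_between_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_group = 0.0
    ss_inter = 0.0
    for lab in labels:
        sel = groups == lab
        ng = int(sel.sum())
        gm = y[sel].mean()
        ss_group += k * ng * (gm - grand) ** 2
        cell = y[sel].mean(axis=0)
        ss_inter += ng * float(((cell - gm - time_means + grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_within_subj = float(((y - subj_means[:, None]) ** 2).sum())
    ss_time = n * float(((time_means - grand) ** 2).sum())
    ss_error = ss_within_subj - ss_time - ss_inter

    df_time = k - 1
    df_inter = (g - 1) * (k - 1)
    df_group = g - 1
    df_subj = n - g
    df_error = (n - g) * (k - 1)
    ms_error = max(ss_error, 0.0) / df_error
    ms_subj = max(ss_subj_within, 0.0) / df_subj

    def f_result(ss_effect, df_effect, ms_denom, df_denom, label) -> StatResult:
        ms_effect = ss_effect / df_effect
        if ms_denom <= 1e-300:
            if ms_effect <= 1e-12:
                return StatResult(0.0, 1.0, label)
            return StatResult(float("inf"), 0.0, label)
        f = ms_effect / ms_denom
        return StatResult(float(f), float(stats.f.sf(f, df_effect, df_denom)), label)

    return RepeatedAnovaResult(
        time=f_result(ss_time, df_time, ms_error, df_error, "rm-anova time"),
        interaction=f_result(ss_inter, df_inter, ms_error, df_error, "rm-anova group x time"),
        group=f_result(ss_group, df_group, ms_subj, df_subj, "rm-anova group (between)"),
    )


# ---------------------------------------------------------------------------
# Group summaries and multiplicity
# ---------------------------------------------------------------------------

def summarize_groups(dataset: StudyDataset, parameter: str,
                     sd_convention: str = "population") -> pd.DataFrame:
    """Per-group, per-visit mean +/- SD table of a kinetic parameter.

    Requires ``dataset.kinetics``; group membership derives from the
    final mRECIST outcome in the lesion table.  Empty groups are
    omitted with a warning.
    """
    if parameter not in ("dv", "ktrans"):
        raise ValidationError("parameter must be 'dv' or 'ktrans'")
    if dataset.kinetics is None:
        raise ValidationError("dataset carries no kinetic parameters")
    kin = dataset.kinetics.merge(
        dataset.lesions[["patient_id", "lesion_id", "outcome_final"]],
        on=["patient_id", "lesion_id"], how="inner")
    kin["group"] = kin["outcome_final"].map(group_of)
    rows = []
    for group in ("responder", "non_responder"):
        sub = kin[kin["group"] == group]
        if sub.empty:
            warnings.warn(f"group {group!r} is empty; omitted from summary")
            continue
        for tp in TIMEPOINTS:
            vals = sub.loc[sub["timepoint"] == tp, parameter].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append({"group": group, "timepoint": tp, "n": vals.size,
                         "mean": float(np.mean(vals)), "sd": std(vals, sd_convention)})
    return pd.DataFrame(rows)


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjustment (off by default in all pipelines)."""
    p = np.asarray(list(p_values), dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
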