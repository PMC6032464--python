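import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dcekit as dk
from dcekit.exceptions import ValidationError


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------

def friedman_oracle(x):
    """Exact permutation p by enumerating every per-row rank permutation."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)

    def statistic(r):
        col = r.sum(axis=0)
        a = (r ** 2).sum()
        c = n * k * (k + 1) ** 2 / 4.0
        if a - c <= 1e-12:
            return 0.0
        return (k - 1) * ((col - n * (k + 1) / 2.0) ** 2).sum() / (a - c)

    obs = statistic(ranks)
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for combo in itertools.product(range(len(perms)), repeat=n):
        r = np.array([ranks[i][list(perms[c])] for i, c in enumerate(combo)])
        total += 1
        if statistic(r) >= obs - 1e-9:
            hits += 1
    return obs, hits / total


def mann_whitney_oracle(x, y):
    """Exact two-sided p over all group assignments (tie-free inputs)."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for sel in itertools.combinations(range(len(pooled)), nx):
        us.append(ranks[list(sel)].sum() - nx * (nx + 1) / 2)
    us = np.asarray(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(1.0, p)


def spearman_oracle(x, y):
    """Exact two-sided p over all pairings of the rank vectors."""
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho_obs = np.corrcoef(xr, yr)[0, 1]
    rhos = [np.corrcoef(xr, perm)[0, 1] for perm in itertools.permutations(yr)]
    p = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
    return rho_obs, p


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

class TestFriedman:
    def test_monotone_rows_strong_rejection(self):
        x = np.tile([3.0, 2.0, 1.0], (8, 1))
        res = dk.friedman_test(x)
        assert res.exact
        assert res.statistic == pytest.approx(16.0)
        assert res.p_value == pytest.approx(6 / 6 ** 8)
        assert res.p_value < 0.001

    def test_constant_matrix(self):
        res = dk.friedman_test(np.ones((5, 3)))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 3))
        p0 = dk.friedman_test(x).p_value
        for perm in itertools.permutations(range(3)):
            assert dk.friedman_test(x[:, list(perm)]).p_value == pytest.approx(p0)

    @pytest.mark.parametrize("seed,n,ties", [(1, 3, False), (2, 5, False),
                                             (3, 6, False), (4, 4, True)])
    def test_exact_p_matches_enumeration(self, seed, n, ties):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=(n, 3)).astype(float) if ties \
            else rng.normal(size=(n, 3))
        obs, p = friedman_oracle(x)
        res = dk.friedman_test(x)
        assert res.exact
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(p)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 3))
        res = dk.friedman_test(x, exact_threshold=8)
        ref = stats.friedmanchisquare(*x.T)
        assert not res.exact
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValidationError):
            dk.friedman_test(x)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation(self):
        res = dk.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups(self):
        res = dk.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=4), rng.normal(size=5)
        assert dk.mann_whitney_u(x, y).p_value == pytest.approx(
            dk.mann_whitney_u(y, x).p_value)

    @pytest.mark.parametrize("seed,nx,ny", [(0, 3, 3), (1, 2, 4), (2, 3, 2), (3, 4, 2)])
    def test_exact_p_matches_enumeration(self, seed, nx, ny):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=nx), rng.normal(size=ny)
        u, p = mann_whitney_oracle(x, y)
        res = dk.mann_whitney_u(x, y)
        assert res.exact
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            x = rng.normal(size=8)
            y = rng.normal(size=13)
            if dk.mann_whitney_u(x, y).p_value < 0.05:
                rejections += 1
        assert 0.02 < rejections / n_sim < 0.08


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        up = dk.spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        down = dk.spearman_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert up.statistic == pytest.approx(1.0)
        assert down.statistic == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        res = dk.spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6)
        assert res.exact

    def test_zero_variance_flagged(self):
        res = dk.spearman_correlation([1, 2, 3], [5, 5, 5])
        assert res.statistic is None and res.p_value is None
        assert "undefined" in res.method

    @pytest.mark.parametrize("seed,n,ties", [(0, 4, False), (1, 5, False), (2, 5, True)])
    def test_exact_p_matches_enumeration(self, seed, n, ties):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.integers(0, 3, size=n).astype(float) if ties else rng.normal(size=n)
        if np.unique(y).size == 1:
            y[0] += 1.0
        rho, p = spearman_oracle(x, y)
        res = dk.spearman_correlation(x, y)
        assert res.exact
        assert res.statistic == pytest.approx(rho)
        assert res.p_value == pytest.approx(p)

    def test_large_n_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = dk.spearman_correlation(x, y)
        ref = stats.spearmanr(x, y)
        assert not res.exact
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

class TestAnovaAcrossTime:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        n, k = 12, 3
        y = rng.normal(size=(n, k)) + np.array([0, 0.5, 1.0]) + rng.normal(size=(n, 1))
        groups = np.array(["a"] * 5 + ["b"] * 7)
        y[groups == "b"] += np.array([0, 0.8, 0.2])
        res = dk.anova_across_time(y, groups)
        df = pd.DataFrame({"y": y.ravel(),
                           "time": np.tile(["t1", "t2", "t3"], n),
                           "subj": np.repeat(np.arange(n), k),
                           "grp": np.repeat(groups, k)})
        ref = pg.mixed_anova(df, dv="y", within="time", subject="subj", between="grp")
        ref = ref.set_index("Source")
        assert res.time.statistic == pytest.approx(ref.loc["time", "F"])
        assert res.interaction.statistic == pytest.approx(ref.loc["Interaction", "F"])
        assert res.group.statistic == pytest.approx(ref.loc["grp", "F"])
        assert res.time.p_value == pytest.approx(ref.loc["time", "p_unc"])

    def test_constant_data(self):
        res = dk.anova_across_time(np.ones((6, 3)), ["a"] * 3 + ["b"] * 3)
        assert res.time.statistic == 0.0 and res.time.p_value == 1.0

    def test_within_group_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(8, 3))
        groups = ["a"] * 4 + ["b"] * 4
        res1 = dk.anova_across_time(y, groups)
        perm = np.array([1, 0, 3, 2, 5, 4, 7, 6])  # permute subjects within groups
        res2 = dk.anova_across_time(y[perm], np.asarray(groups)[perm])
        assert res1.time.statistic == pytest.approx(res2.time.statistic)
        assert res1.interaction.statistic == pytest.approx(res2.interaction.statistic)

    def test_pure_additive_time_effect(self):
        y = np.tile([1.0, 2.0, 3.0], (6, 1))
        res = dk.anova_across_time(y, ["a"] * 3 + ["b"] * 3)
        assert res.interaction.statistic == 0.0 and res.interaction.p_value == 1.0
        assert np.isinf(res.time.statistic) and res.time.p_value == 0.0

    def test_singular_design_rejected(self):
        with pytest.raises(ValidationError):
            dk.anova_across_time(np.ones((4, 3)), ["a"] * 4)


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

class TestSummarizeGroups:
    def _dataset(self):
        ds, truth, _ = dk.generate_cohort(dk.CohortSpec(seed=21))
        kin = truth.params.rename(columns={})[
            ["patient_id", "lesion_id", "timepoint", "ktrans", "dv"]]
        return dk.attach_kinetics(ds, kin)

    def test_layout_and_duplication_invariance(self):
        ds = self._dataset()
        table = dk.summarize_groups(ds, "dv")
        assert set(table["group"]) <= {"responder", "non_responder"}
        assert list(table.columns) == ["group", "timepoint", "n", "mean", "sd"]
        doubled = dk.StudyDataset(
            lesions=ds.lesions,
            patients=ds.patients,
            kinetics=pd.concat([ds.kinetics, ds.kinetics], ignore_index=True))
        t2 = dk.summarize_groups(doubled, "dv")
        np.testing.assert_allclose(table["mean"], t2["mean"])

    def test_single_lesion_group_sd_zero(self):
        lesions = pd.DataFrame({"patient_id": ["p1", "p2"], "lesion_id": ["l1", "l1"],
                                "size_mm": [10.0, 20.0],
                                "outcome_final": ["PR", "SD"]})
        kin = pd.DataFrame({"patient_id": ["p1", "p2"], "lesion_id": ["l1", "l1"],
                            "timepoint": ["day10", "day10"], "dv": [8.0, 30.0],
                            "ktrans": [5.0, 50.0]})
        ds = dk.StudyDataset(lesions=lesions, kinetics=kin)
        table = dk.summarize_groups(ds, "dv")
        assert (table["sd"] == 0).all()


def test_holm_adjustment():
    adj = dk.holm_adjust([0.01, 0.04, 0.03])
    assert adj == pytest.approx([0.03, 0.06, 0.06])
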