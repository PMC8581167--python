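"""Statistical layer against brute-force oracles and simulated panels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import micropattern as mp
from micropattern.simulate import sample_positive_distances
from micropattern.stats import dunn_posthoc


# ---------------------------------------------------------------- oracles

def brute_force_ks_statistic(a, b):
    """Max |ECDF difference| evaluated at every pooled sample point."""
    pooled = np.concatenate([a, b])
    fa = np.array([np.mean(a <= x) for x in pooled])
    fb = np.array([np.mean(b <= x) for x in pooled])
    return np.max(np.abs(fa - fb))


def brute_force_kruskal_h(groups):
    """Rank formula H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1), tie-corrected."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1 - np.sum(t**3 - t) / (n_total**3 - n_total)
    return h / correction


def brute_force_spearman(x, y):
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def brute_force_student_t(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))


# ---------------------------------------------------------------- KS

class TestKSRadial:
    def test_self_comparison(self):
        d = np.linspace(10, 400, 50)
        res = mp.ks_radial_compare(d, d)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_statistic_matches_brute_force(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(300, 50, 80), rng.normal(320, 60, 120)
        res = mp.ks_radial_compare(a, b)
        assert res.statistic == pytest.approx(brute_force_ks_statistic(a, b), abs=1e-10)

    def test_insufficient_nuclei_names_group(self):
        with pytest.raises(ValueError, match="B"):
            mp.ks_radial_compare(np.arange(20), np.arange(5), labels=("A", "B"))

    def test_power_for_ring_shift(self):
        """Rings at 325 vs 425 um, n=200: rejected at p<0.01 in most draws."""
        rng = np.random.default_rng(5)
        m1 = mp.RadialExpressionModel(kind="ring", center_um=325, width_um=40)
        m2 = mp.RadialExpressionModel(kind="ring", center_um=425, width_um=40)
        hits = 0
        for _ in range(50):
            a = sample_positive_distances(m1, 200, rng)
            b = sample_positive_distances(m2, 200, rng)
            hits += mp.ks_radial_compare(a, b, alpha=0.01).significant
        assert hits >= 45


# ---------------------------------------------------------------- Kruskal + Dunn

class TestKruskalDunn:
    def test_h_matches_hand_computed_toy(self):
        """{1,2,3},{4,5,6},{7,8,9}: rank sums 6/15/24 give H = 7.2."""
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        omnibus, pairwise = mp.kruskal_dunn({k: np.array(v, float) for k, v in groups.items()})
        assert omnibus.statistic == pytest.approx(7.2, abs=1e-10)
        assert omnibus.statistic == pytest.approx(
            brute_force_kruskal_h([np.array(v, float) for v in groups.values()]), abs=1e-10)

    def test_shifted_group_has_smallest_dunn_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        groups = {"a": a, "b": rng.normal(0, 1, 20), "c": rng.normal(10, 1, 20)}
        _, pairwise = mp.kruskal_dunn(groups)
        involving_c = pairwise[(pairwise["group1"] == "c") | (pairwise["group2"] == "c")]
        other = pairwise[(pairwise["group1"] != "c") & (pairwise["group2"] != "c")]
        assert involving_c["p_adj"].max() < other["p_adj"].min()

    def test_dunn_z_matches_hand_computation(self):
        """No ties: z = (Rbar_i - Rbar_j) / sqrt(N(N+1)/12 * (1/n_i + 1/n_j))."""
        groups = {"a": np.array([1.0, 2.0, 5.0]), "b": np.array([3.0, 8.0, 9.0]),
                  "c": np.array([4.0, 6.0, 7.0])}
        table = dunn_posthoc(groups)
        # pooled ranks: a -> 1,2,5 (mean 8/3); b -> 3,8,9 (mean 20/3); c -> 4,6,7 (mean 17/3)
        se = np.sqrt(9 * 10 / 12 * (1 / 3 + 1 / 3))
        z_ab = (8 / 3 - 20 / 3) / se
        row = table[(table["group1"] == "a") & (table["group2"] == "b")].iloc[0]
        assert row["z"] == pytest.approx(z_ab, abs=1e-10)
        assert row["p_adj"] == pytest.approx(min(1.0, 3 * 2 * sps.norm.sf(abs(z_ab))), abs=1e-10)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="3 lines"):
            mp.kruskal_dunn({"a": np.ones(5), "b": np.ones(5)})
        with pytest.raises(ValueError, match="fewer than 3"):
            mp.kruskal_dunn({"a": np.ones(2), "b": np.ones(5), "c": np.ones(5)})

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 15) for i, k in enumerate("abcd")}
        bonf = dunn_posthoc(groups, adjust="bonferroni")
        holm = dunn_posthoc(groups, adjust="holm")
        assert (holm["p_adj"] <= bonf["p_adj"] + 1e-12).all()


# ---------------------------------------------------------------- pooled t

class TestOutlierMeanExpression:
    def test_identical_not_flagged(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(30, 5, 12)
        res = mp.outlier_mean_expression(vals, vals + rng.normal(0, 0.1, 12))
        assert not res.significant

    def test_t_statistic_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = mp.outlier_mean_expression(a, b, min_pool=6)
        assert res.statistic == pytest.approx(brute_force_student_t(a, b), abs=1e-10)

    def test_five_sd_shift_detected(self):
        rng = np.random.default_rng(4)
        pool = rng.normal(30, 4, 60)
        target = rng.normal(30 + 5 * 4, 4, 8)
        res = mp.outlier_mean_expression(target, pool)
        assert res.significant and res.pvalue < 0.001

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            mp.outlier_mean_expression(np.ones(5), np.ones(20))


# ---------------------------------------------------------------- radial outlier

class TestOutlierRadial:
    def test_control_vs_itself_not_flagged(self):
        rng = np.random.default_rng(6)
        model = mp.RadialExpressionModel(kind="ring", center_um=425, width_um=40)
        a = sample_positive_distances(model, 300, rng)
        res = mp.outlier_radial(a, a, line="x", control_line="ctrl")
        assert not res.significant

    def test_center_extension_flagged(self):
        """Endoderm domain extended to the colony centre vs an outer-ring control."""
        rng = np.random.default_rng(7)
        ctrl = mp.RadialExpressionModel(kind="ring", center_um=425, width_um=40)
        ext = mp.RadialExpressionModel(kind="ring", center_um=200, width_um=150)
        hits = 0
        for _ in range(20):
            a = sample_positive_distances(ext, 200, rng)
            b = sample_positive_distances(ctrl, 200, rng)
            hits += mp.outlier_radial(a, b).significant
        assert hits >= 18


# ---------------------------------------------------------------- correlations / PCA

class TestMarkerCorrelations:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"A": x, "B": x**2, "C": -x})
        r = mp.marker_correlations(df)
        assert r.loc["A", "B"] == pytest.approx(1.0)
        assert r.loc["A", "C"] == pytest.approx(-1.0)

    def test_toy_table_matches_hand_ranked_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5])
        df = pd.DataFrame({"A": x, "B": y})
        r = mp.marker_correlations(df)
        assert r.loc["A", "B"] == pytest.approx(brute_force_spearman(x, y), abs=1e-10)

    def test_constant_marker_is_missing(self):
        df = pd.DataFrame({"A": np.arange(6.0), "B": np.full(6, 2.0)})
        r = mp.marker_correlations(df)
        assert np.isnan(r.loc["A", "B"])

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            mp.marker_correlations(pd.DataFrame({"A": [1.0], "B": [2.0]}))


class TestPCALines:
    def test_dominant_direction(self):
        rng = np.random.default_rng(8)
        t = rng.normal(0, 10, 30)
        df = pd.DataFrame({"SOX2": t + rng.normal(0, 0.5, 30),
                           "BRA": -t + rng.normal(0, 0.5, 30),
                           "SOX17": 0.5 * t + rng.normal(0, 0.5, 30)})
        res = mp.pca_lines(df)
        assert res.variance_explained[0] > 0.9

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(8, 3)), columns=["SOX2", "BRA", "SOX17"])
        res = mp.pca_lines(df)
        assert res.variance_explained.sum() == pytest.approx(1.0)

    def test_clonal_lines_cluster_by_donor(self):
        """Lines sharing a donor effect land closer than lines from other donors."""
        rng = np.random.default_rng(10)
        donors = {"aaaa": [20, 40, 10], "bbbb": [50, 10, 30], "cccc": [30, 30, 60]}
        rows, names = [], []
        for donor, mu in donors.items():
            for clone in (1, 2):
                rows.append(np.array(mu, float) + rng.normal(0, 1.0, 3))
                names.append(f"{donor}_{clone}")
        df = pd.DataFrame(rows, index=names, columns=["SOX2", "BRA", "SOX17"])
        scores = mp.pca_lines(df).scores.to_numpy()
        within, between = [], []
        for i, j in itertools.combinations(range(len(names)), 2):
            dist = np.linalg.norm(scores[i] - scores[j])
            (within if names[i][:4] == names[j][:4] else between).append(dist)
        assert max(within) < min(between)

    def test_too_few_lines_errors(self):
        with pytest.raises(ValueError):
            mp.pca_lines(pd.DataFrame({"A": [1.0], "B": [2.0]}))


def test_stats_result_validates_p():
    with pytest.raises(ValueError):
        mp.StatsResult(test="x", statistic=0.0, pvalue=1.5)
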