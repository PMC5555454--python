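import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germscan.diffscan import (
    anova_fst_by_lg,
    empirical_outliers,
    group_counts,
    jost_d,
    mean_multilocus_fst,
    nei_gst,
    scan,
    wc_fst,
    wc_fst_components,
)
from germscan.gio import GenotypeMatrix


def wc_components_reference(n, p, h):
    """Independent scalar transcription of the variance-component formulas."""
    n = [float(x) for x in n]
    p = [float(x) for x in p]
    h = [float(x) for x in h]
    r = len(n)
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWCFst:
    def test_no_between_group_variance(self):
        theta = wc_fst([10, 10], [0.4, 0.4], [0.0, 0.0])
        assert theta <= 0  # estimator noise term only; exactly the s2=0 path

    def test_fixation_limit(self):
        theta = wc_fst([1000, 1000], [1.0, 0.0], [0.0, 0.0])
        assert theta == pytest.approx(1.0, abs=1e-3)

    def test_against_reference_transcription(self):
        a, b, c = wc_fst_components([10, 10], [0.9, 0.1], [0.0, 0.0])
        ea, eb, ec = wc_components_reference([10, 10], [0.9, 0.1], [0.0, 0.0])
        np.testing.assert_allclose([a[0], b[0], c[0]], [ea, eb, ec], atol=1e-12)
        theta = wc_fst([10, 10], [0.9, 0.1], [0.0, 0.0])
        assert theta == pytest.approx(ea / (ea + eb + ec), abs=1e-12)

    def test_permutation_null_centered_near_zero(self):
        """Random halves of one population give theta scattered around 0."""
        rng = np.random.default_rng(0)
        thetas = []
        for _ in range(200):
            pool = rng.binomial(1, 0.4, 200) * 2.0
            rng.shuffle(pool)
            p1, p2 = pool[:100].mean() / 2, pool[100:].mean() / 2
            thetas.append(wc_fst([100, 100], [p1, p2], [0.0, 0.0]))
        assert abs(np.mean(thetas)) < 0.01

    def test_single_group_undefined(self):
        assert np.isnan(wc_fst([10], [0.5], [0.0]))


class TestGstAndJostD:
    def test_reciprocal_fixation(self):
        assert nei_gst([10, 10], [1.0, 0.0]) == pytest.approx(1.0)
        assert jost_d([10, 10], [1.0, 0.0]) == pytest.approx(1.0)

    def test_equal_frequencies(self):
        assert nei_gst([10, 10], [0.3, 0.3]) == pytest.approx(0.0, abs=1e-12)
        assert jost_d([10, 10], [0.3, 0.3]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # p = (0.9, 0.1): H_S = 0.18, H_T = 0.5
        assert nei_gst([10, 10], [0.9, 0.1]) == pytest.approx(0.64)
        assert jost_d([10, 10], [0.9, 0.1]) == pytest.approx((0.5 - 0.18) / 0.82 * 2, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0).map(lambda x: round(x, 6)), min_size=2, max_size=6))
    def test_allele_flip_invariance(self, ps):
        n = [20.0] * len(ps)
        h = [0.0] * len(ps)
        flipped = [1 - p for p in ps]
        for fn in (wc_fst, nei_gst, jost_d):
            a, b = fn(n, ps, h), fn(n, flipped, h)
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-10)


class TestScan:
    def test_matches_marker_by_marker_calls(self, sim_small):
        res = sim_small
        df = scan(res.genotypes, res.groups, res.marker_map)
        labels, n, p, h = group_counts(res.genotypes, res.groups)
        by_marker = {m: j for j, m in enumerate(res.genotypes.marker_ids)}
        sample = df.sample(20, random_state=1)
        for _, row in sample.iterrows():
            j = by_marker[row.marker]
            assert row.fst_wc == pytest.approx(wc_fst(n[j], p[j], h[j]), nan_ok=True, abs=1e-12)
            assert row.jost_d == pytest.approx(jost_d(n[j], p[j], h[j]), nan_ok=True, abs=1e-12)

    def test_manhattan_ordering(self, sim_small):
        df = scan(sim_small.genotypes, sim_small.groups, sim_small.marker_map)
        assert (df.groupby("linkage_group")["cM"].apply(lambda s: s.is_monotonic_increasing)).all()
        assert df["cum_pos"].is_monotonic_increasing

    def test_permuted_labels_centered_near_zero(self, sim_default):
        rng = np.random.default_rng(2)
        groups = sim_default.groups
        permuted = pd.Series(rng.permutation(groups.values), index=groups.index)
        df = scan(sim_default.genotypes, permuted, sim_default.marker_map)
        assert abs(df["fst_wc"].mean()) < 0.005

    def test_fst_and_jost_d_rank_correlated(self, sim_default):
        df = scan(sim_default.genotypes, sim_default.groups, sim_default.marker_map)
        sub = df.dropna(subset=["fst_wc", "jost_d"])
        rho = sub["fst_wc"].corr(sub["jost_d"], method="spearman")
        assert rho > 0.9

    def test_empty_group_rejected(self, sim_small):
        with pytest.raises(ValueError, match="no accessions"):
            scan(sim_small.genotypes, sim_small.groups, sim_small.marker_map,
                 group_labels=["wild", "ghost"])


class TestMultilocusFst:
    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(1, rng.uniform(0.2, 0.8, 300), size=(40, 300)) * 2.0
        g = GenotypeMatrix([f"a{i}" for i in range(40)], [f"m{j}" for j in range(300)],
                           base.astype(float))
        groups = pd.Series(["g1"] * 20 + ["g2"] * 20, index=g.accession_ids)
        est = mean_multilocus_fst(g, groups)
        assert abs(est["fst_ratio_of_sums"]) < 0.02

    def test_single_marker_equals_per_marker_theta(self, sim_small):
        g = sim_small.genotypes.subset_markers([sim_small.genotypes.marker_ids[0]])
        labels, n, p, h = group_counts(g, sim_small.groups)
        est = mean_multilocus_fst(g, sim_small.groups)
        assert est["fst_ratio_of_sums"] == pytest.approx(wc_fst(n[0], p[0], h[0]), abs=1e-12)

    def test_group_exclusion(self, sim_small):
        est = mean_multilocus_fst(sim_small.genotypes, sim_small.groups,
                                  exclude_groups=("wild",))
        assert est["n_groups"] == 2
        with pytest.raises(ValueError):
            mean_multilocus_fst(sim_small.genotypes, sim_small.groups,
                                exclude_groups=("wild", "winter"))


class TestAnova:
    def test_hand_anova_table(self):
        df = pd.DataFrame({"linkage_group": ["A", "A", "B", "B"],
                           "fst_wc": [0.1, 0.2, 0.5, 0.6]})
        f, dfree, p = anova_fst_by_lg(df)
        assert f == pytest.approx(32.0)
        assert dfree == (1, 2)

    def test_equal_values_give_zero_or_flagged(self):
        df = pd.DataFrame({"linkage_group": ["A", "A", "B", "B"], "fst_wc": [0.3] * 4})
        f, _, p = anova_fst_by_lg(df)
        assert np.isnan(f) or f == pytest.approx(0.0)

    def test_elevated_lg_detected(self):
        rng = np.random.default_rng(4)
        rows = []
        for lg in ("LG1", "LG2", "LG3"):
            base = 0.35 if lg == "LG2" else 0.25
            rows += [{"linkage_group": lg, "fst_wc": v}
                     for v in rng.normal(base, 0.05, 80)]
        f, _, p = anova_fst_by_lg(pd.DataFrame(rows))
        assert p < 0.05

    def test_degenerate_grouping_rejected(self):
        df = pd.DataFrame({"linkage_group": ["A", "A"], "fst_wc": [0.1, 0.2]})
        with pytest.raises(ValueError):
            anova_fst_by_lg(df)


class TestEmpiricalOutliers:
    def test_zero_quantile_flags_everything(self, sim_small):
        df = scan(sim_small.genotypes, sim_small.groups, sim_small.marker_map)
        flagged = empirical_outliers(df, top_quantile=0.0)
        assert len(flagged) == df["fst_wc"].notna().sum()
        assert (flagged["method"] == "empirical_quantile").all()

    def test_flagged_set_is_quantile_sized(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"marker": [f"m{i}" for i in range(1000)],
                           "fst_wc": rng.uniform(0, 1, 1000)})
        flagged = empirical_outliers(df, top_quantile=0.99)
        assert 10 <= len(flagged) <= 12

    def test_ranked_by_fst(self):
        df = pd.DataFrame({"marker": list("abcd"), "fst_wc": [0.1, 0.9, 0.5, 0.7]})
        flagged = empirical_outliers(df, top_quantile=0.5)
        assert flagged["marker"].tolist() == ["b", "d"]
        assert flagged["rank"].tolist() == [1, 2]
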