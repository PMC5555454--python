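import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germscan.gio import GenotypeMatrix
from germscan.ldcalc import (
    intra_lg_ld,
    ld_decay_profile,
    ld_matrix,
    pairwise_r2,
    physical_ld,
    r2v,
)
from germscan.relmat import kinship
from germscan.syndata import SimulationConfig, simulate

NA = np.nan


def make_map(entries):
    df = pd.DataFrame(entries, columns=["marker", "linkage_group", "cM"])
    df["scaffold"] = pd.NA
    df["bp"] = np.nan
    return df


class TestPairwiseR2:
    def test_perfect_correlation(self):
        g = [0, 1, 2, 0, 2]
        assert pairwise_r2(g, g) == pytest.approx(1.0)

    def test_flip_gives_one(self):
        g = np.array([0, 1, 2, 0, 2.0])
        assert pairwise_r2(g, 2 - g) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert pairwise_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_zero_variance_undefined(self):
        assert np.isnan(pairwise_r2([2, 2, 2], [0, 1, 2]))

    def test_pairwise_complete_deletion(self):
        a = [0, 2, NA, 2, 0]
        b = [0, 2, 2, NA, 0]
        assert pairwise_r2(a, b) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=4, max_size=30),
           st.booleans(), st.booleans())
    def test_flip_invariance(self, xs, flip_a, flip_b):
        rng = np.random.default_rng(len(xs))
        a = np.array(xs)
        b = rng.choice([0.0, 1.0, 2.0], size=len(xs))
        base = pairwise_r2(a, b)
        flipped = pairwise_r2(2 - a if flip_a else a, 2 - b if flip_b else b)
        if np.isnan(base):
            assert np.isnan(flipped)
        else:
            assert flipped == pytest.approx(base, abs=1e-12)


class TestR2V:
    def test_identity_kinship_equals_r2(self):
        rng = np.random.default_rng(8)
        a = rng.choice([0.0, 2.0], 40)
        b = rng.choice([0.0, 2.0], 40)
        assert abs(r2v(a, b, np.eye(40)) - pairwise_r2(a, b)) < 1e-10

    def test_identical_vectors_give_one(self):
        rng = np.random.default_rng(9)
        a = rng.choice([0.0, 2.0], 40)
        k = np.eye(40) + 0.3
        assert r2v(a, a, k) == pytest.approx(1.0)

    def test_structure_induced_ld_reduced(self):
        """Between-group frequency divergence at unlinked markers inflates r²
        but not r²_V once kinship is accounted for."""
        diffs = []
        for seed in range(5):
            res = simulate(SimulationConfig(seed=seed + 100, n_groups=2,
                                            group_names=("a", "b"), drift_F=0.4,
                                            n_per_group=60, markers_per_lg=60,
                                            n_linkage_groups=4, n_founders=200,
                                            missing_rate=0.0))
            g = res.genotypes
            kin = kinship(g)
            truth = res.truth.markers
            div = (truth["p_a"] - truth["p_b"]).abs()
            # diverged markers from different linkage groups -> no physical LD
            top = truth.loc[div > 0.4]
            pairs = []
            for lg_a, sub_a in top.groupby("linkage_group"):
                for lg_b, sub_b in top.groupby("linkage_group"):
                    if lg_a < lg_b:
                        pairs.append((sub_a["marker"].iloc[0], sub_b["marker"].iloc[0]))
            for ma, mb in pairs[:10]:
                ja, jb = g.marker_indices([ma, mb])
                raw = pairwise_r2(g.dosage[:, ja], g.dosage[:, jb])
                corrected = r2v(g.dosage[:, ja], g.dosage[:, jb], kin)
                if not (np.isnan(raw) or np.isnan(corrected)):
                    diffs.append(raw - corrected)
        assert np.mean(diffs) > 0

    def test_bounded_by_one(self):
        rng = np.random.default_rng(10)
        a = rng.choice([0.0, 2.0], 30)
        b = rng.choice([0.0, 2.0], 30)
        x = rng.normal(size=(30, 5))
        k = x @ x.T / 5 + np.eye(30)
        assert 0.0 <= r2v(a, b, k) <= 1.0


class TestIntraLG:
    def test_pair_counts_single_lg(self, sim_small):
        g = sim_small.genotypes.subset_markers(sim_small.genotypes.marker_ids[:4])
        mm = make_map([(m, "LG1", i * 1.0) for i, m in enumerate(g.marker_ids)])
        assert len(intra_lg_ld(g, mm)) == 6

    def test_no_inter_lg_pairs(self, sim_small):
        g = sim_small.genotypes.subset_markers(sim_small.genotypes.marker_ids[:6])
        mm = make_map([(m, f"LG{1 + i // 3}", float(i)) for i, m in enumerate(g.marker_ids)])
        pairs = intra_lg_ld(g, mm)
        assert len(pairs) == 6
        assert (pairs.groupby("linkage_group").size() == 3).all()

    def test_distance_cap(self, sim_small):
        g = sim_small.genotypes.subset_markers(sim_small.genotypes.marker_ids[:4])
        mm = make_map([(m, "LG1", i * 10.0) for i, m in enumerate(g.marker_ids)])
        pairs = intra_lg_ld(g, mm, max_dist_cM=10.0)
        assert (pairs["dist_cM"] <= 10).all() and len(pairs) == 3

    def test_short_range_ld_exceeds_long_range(self, sim_default):
        res = sim_default
        spring = [a for a in res.genotypes.accession_ids if a.startswith("spring")]
        pairs = intra_lg_ld(res.genotypes.subset_accessions(spring), res.marker_map)
        ok = pairs.dropna(subset=["r2"])
        near = ok.loc[ok.dist_cM < 1, "r2"].mean()
        far = ok.loc[ok.dist_cM > 20, "r2"].mean()
        assert near > far

    def test_matches_pairwise_function(self, sim_small):
        g = sim_small.genotypes.subset_markers(sim_small.genotypes.marker_ids[:5])
        mm = make_map([(m, "LG1", float(i)) for i, m in enumerate(g.marker_ids)])
        pairs = intra_lg_ld(g, mm)
        for _, row in pairs.iterrows():
            ja, jb = g.marker_indices([row.marker_a, row.marker_b])
            direct = pairwise_r2(g.dosage[:, ja], g.dosage[:, jb])
            if np.isnan(direct):
                assert np.isnan(row.r2)
            else:
                assert row.r2 == pytest.approx(direct, abs=1e-10)


class TestDecayProfile:
    def test_degenerate_distribution(self):
        pairs = pd.DataFrame({"dist_cM": np.linspace(0, 0.4, 20), "r2": 0.3})
        prof = ld_decay_profile(pairs, bin_width=0.5)
        assert (prof["r2"] == 0.3).all()

    def test_quantile_ordering_every_bin(self, sim_default):
        pairs = intra_lg_ld(sim_default.genotypes, sim_default.marker_map, max_dist_cM=20)
        prof = ld_decay_profile(pairs, bin_width=1.0)
        for _, sub in prof.groupby("bin_left"):
            ordered = sub.sort_values("quantile")["r2"].to_numpy()
            assert (np.diff(ordered) >= -1e-12).all()

    def test_sparse_bins_suppressed(self):
        pairs = pd.DataFrame({"dist_cM": [0.1] * 20 + [5.1] * 3, "r2": 0.2})
        prof = ld_decay_profile(pairs, bin_width=0.5, min_pairs=10)
        assert set(prof["bin_left"]) == {0.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ld_decay_profile(pd.DataFrame(columns=["dist_cM", "r2"]))


class TestPhysicalLD:
    def test_cross_scaffold_pairs_skipped(self, sim_small):
        g = sim_small.genotypes.subset_markers(sim_small.genotypes.marker_ids[:2])
        mm = make_map([(m, "LG1", float(i)) for i, m in enumerate(g.marker_ids)])
        mm["scaffold"] = ["s1", "s2"]
        mm["bp"] = [100.0, 1100.0]
        assert physical_ld(g, mm).empty

    def test_bp_distance(self, sim_small):
        g = sim_small.genotypes.subset_markers(sim_small.genotypes.marker_ids[:2])
        mm = make_map([(m, "LG1", float(i)) for i, m in enumerate(g.marker_ids)])
        mm["scaffold"] = "s1"
        mm["bp"] = [100.0, 1100.0]
        pairs = physical_ld(g, mm)
        assert len(pairs) == 1 and pairs["dist_bp"].iloc[0] == 1000

    def test_pair_count_matches_enumeration(self, sim_small):
        pairs = physical_ld(sim_small.genotypes, sim_small.marker_map)
        mm = sim_small.marker_map
        expected = sum(
            len(sub) * (len(sub) - 1) // 2
            for _, sub in mm[mm.scaffold.notna()].groupby("scaffold") if len(sub) > 1
        )
        assert len(pairs) == expected


class TestLDMatrix:
    def test_symmetric_unit_diagonal(self, sim_small):
        ids, mat = ld_matrix(sim_small.genotypes, sim_small.marker_map, "LG1")
        assert len(ids) == mat.shape[0]
        np.testing.assert_allclose(np.diag(mat), 1.0)
        finite = np.isfinite(mat)
        assert (finite == finite.T).all()
        np.testing.assert_allclose(mat[finite], mat.T[finite], atol=1e-10)

    def test_kinship_corrected_variant(self, sim_small):
        kin = kinship(sim_small.genotypes)
        ids, mat = ld_matrix(sim_small.genotypes, sim_small.marker_map, "LG1",
                             kin=kin, max_markers=15)
        assert mat.shape == (15, 15)
        vals = mat[np.isfinite(mat)]
        assert ((vals >= 0) & (vals <= 1)).all()
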