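"""Incidence-matrix construction and PCA: dual-route checks and invariants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

import rohscan
from rohscan.pca_structure import (
    build_incidence, kaiser_retain, run_pca, top_contributing_loci,
)


def _regions(n, chrom=1, width=200_000, step=1_000_000):
    starts = 1 + np.arange(n) * step
    return pd.DataFrame({"chrom": chrom, "start_bp": starts,
                         "end_bp": starts + width,
                         "n_snps": 10, "peak_freq": 0.5, "mean_freq": 0.4,
                         "group": "all"})


def _segments_covering(sample_ids, regions, carrier):
    """carrier[i][j] True -> sample i gets a ROH covering region j."""
    rows = []
    for i, sid in enumerate(sample_ids):
        for j, reg in enumerate(regions.itertuples(index=False)):
            if carrier[i][j]:
                rows.append({"sample_id": sid, "breed": "b", "chrom": reg.chrom,
                             "start_bp": reg.start_bp - 50_000,
                             "end_bp": reg.end_bp + 50_000, "n_snps": 120,
                             "length_kb": (reg.end_bp - reg.start_bp + 100_001) / 1000,
                             "detector": "sliding"})
    return pd.DataFrame(rows)


class TestBuildIncidence:
    def test_full_carrier_row_is_ones(self):
        regions = _regions(4)
        sample_ids = ["s0", "s1", "s2", "s3"]
        carrier = [[True] * 4, [True, False, True, False],
                   [False, True, False, True], [True, True, False, False]]
        segs = _segments_covering(sample_ids, regions, carrier)
        inc = build_incidence(segs, regions, sample_ids, min_freq=0.1, top_n=4)
        assert inc.loc["s0"].tolist() == [1, 1, 1, 1]

    def test_frequency_filter_and_cap(self):
        regions = _regions(3)
        sample_ids = [f"s{i}" for i in range(8)]
        carrier = [[True, i < 1, i < 4] for i in range(8)]
        segs = _segments_covering(sample_ids, regions, carrier)
        inc = build_incidence(segs, regions, sample_ids, min_freq=0.25, top_n=10)
        # region 1 (freq 1/8) filtered out; ranked by frequency descending
        assert inc.shape[1] == 2
        assert inc.columns[0].startswith("chr1:1-")  # freq 1.0 region first

    def test_top_n_larger_than_available_warns(self):
        regions = _regions(2)
        sample_ids = ["s0", "s1"]
        segs = _segments_covering(sample_ids, regions, [[True, True]] * 2)
        with pytest.warns(UserWarning, match="returning all"):
            inc = build_incidence(segs, regions, sample_ids, min_freq=0.1, top_n=170)
        assert inc.shape == (2, 2)

    def test_no_passing_region_raises(self):
        regions = _regions(2)
        with pytest.raises(ValueError, match="frequency"):
            build_incidence(pd.DataFrame([], columns=["sample_id", "breed", "chrom",
                                                      "start_bp", "end_bp", "n_snps",
                                                      "length_kb", "detector"]),
                            regions, ["s0", "s1"], min_freq=0.125)


class TestRunPCA:
    def _random_incidence(self, rng, n=20, m=50):
        x = (rng.random((n, m)) < rng.uniform(0.2, 0.8, size=m)).astype(np.int8)
        return pd.DataFrame(x, index=pd.Index([f"s{i}" for i in range(n)],
                                              name="sample_id"),
                            columns=[f"r{j}" for j in range(m)])

    def test_eigenvalues_match_sklearn(self, rng):
        """SVD route against scikit-learn's PCA on random binary matrices."""
        for _ in range(5):
            inc = self._random_incidence(rng)
            res = run_pca(inc)
            sk = SkPCA()
            sk.fit(inc.to_numpy(dtype=float)[:, inc.std(axis=0) > 0])
            k = min(len(res.eigenvalues), len(sk.explained_variance_))
            np.testing.assert_allclose(res.eigenvalues[:k],
                                       sk.explained_variance_[:k], atol=1e-8)
            # scores agree up to component sign
            scores = res.scores.to_numpy()
            sk_scores = sk.transform(inc.to_numpy(dtype=float)[:, inc.std(axis=0) > 0])
            np.testing.assert_allclose(np.abs(scores[:, :k]),
                                       np.abs(sk_scores[:, :k]), atol=1e-8)

    def test_explained_percentages_sum_to_hundred(self, rng):
        res = run_pca(self._random_incidence(rng))
        assert res.explained_pct.sum() == pytest.approx(100.0)
        assert (np.diff(np.cumsum(res.explained_pct)) >= -1e-9).all()

    def test_scores_orthogonal(self, rng):
        res = run_pca(self._random_incidence(rng))
        s = res.scores.to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_contributions_sum_to_hundred_per_component(self, rng):
        res = run_pca(self._random_incidence(rng))
        np.testing.assert_allclose(res.contributions.sum(axis=0), 100.0)

    def test_sign_convention_largest_loading_positive(self, rng):
        res = run_pca(self._random_incidence(rng))
        load = res.loadings.to_numpy()
        for k in range(load.shape[1]):
            assert load[np.argmax(np.abs(load[:, k])), k] >= 0

    def test_sample_order_invariance(self, rng):
        """Permuting samples permutes scores and leaves leading loadings
        unchanged (the near-null trailing subspace is basis-arbitrary, so
        only well-separated components are compared)."""
        inc = self._random_incidence(rng)
        perm = rng.permutation(len(inc))
        res1 = run_pca(inc)
        res2 = run_pca(inc.iloc[perm])
        lead = 5
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-9)
        np.testing.assert_allclose(res1.loadings.to_numpy()[:, :lead],
                                   res2.loadings.to_numpy()[:, :lead], atol=1e-8)
        np.testing.assert_allclose(res1.scores.to_numpy()[perm][:, :lead],
                                   res2.scores.to_numpy()[:, :lead], atol=1e-8)

    def test_two_correlated_columns(self):
        inc = pd.DataFrame({"a": [0, 0, 1, 1, 0, 1], "b": [0, 0, 1, 1, 0, 1]},
                           index=pd.Index([f"s{i}" for i in range(6)]))
        res = run_pca(inc)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_zero_variance_columns_dropped(self, rng):
        inc = self._random_incidence(rng, n=10, m=5)
        inc["const"] = 1
        with pytest.warns(UserWarning, match="zero-variance"):
            res = run_pca(inc)
        assert "const" not in res.loadings.index

    def test_single_sample_raises(self):
        inc = pd.DataFrame([[0, 1]], index=["s0"], columns=["a", "b"])
        with pytest.raises(ValueError):
            run_pca(inc)


class TestKaiser:
    def test_arithmetic_example(self):
        assert kaiser_retain([3.0, 1.0, 0.5, 0.5]) == 1

    def test_all_equal_retains_none_with_warning(self):
        with pytest.warns(UserWarning, match="Kaiser"):
            assert kaiser_retain([1.0, 1.0, 1.0]) == 0

    def test_correlation_scaled_matches_gt1_rule(self, rng):
        x = rng.normal(size=(40, 8))
        x[:, 0] += 2 * x[:, 1]  # induce correlation structure
        inc = pd.DataFrame(x, index=[f"s{i}" for i in range(40)],
                           columns=[f"c{j}" for j in range(8)])
        res = run_pca(inc, scale_mode="correlation")
        assert res.k_retained == int((res.eigenvalues > 1.0).sum())

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kaiser_retain([])


class TestContributions:
    def test_pc1_region_outranks_pc3_region(self):
        """A region loading on the dominant component beats one loading on a
        minor component."""
        rng = np.random.default_rng(4)
        n = 60
        pc1 = rng.normal(scale=4.0, size=n)
        pc3 = rng.normal(scale=0.5, size=n)
        inc = pd.DataFrame({
            "on_pc1": pc1, "on_pc1_b": pc1 + rng.normal(scale=0.1, size=n),
            "on_pc3": pc3,
            "noise1": rng.normal(scale=1.0, size=n),
            "noise2": rng.normal(scale=1.0, size=n)},
            index=[f"s{i}" for i in range(n)])
        res = run_pca(inc)
        ranked = top_contributing_loci(res, 5)
        assert ranked.index.get_loc("on_pc1") < ranked.index.get_loc("on_pc3")

    def test_m_equal_to_columns_returns_all(self, rng):
        x = (rng.random((15, 6)) < 0.5).astype(int)
        inc = pd.DataFrame(x, index=[f"s{i}" for i in range(15)],
                           columns=[f"r{j}" for j in range(6)])
        res = run_pca(inc)
        assert len(top_contributing_loci(res, 6)) == res.loadings.shape[0]
        assert len(top_contributing_loci(res, 100)) == res.loadings.shape[0]


class TestGroupSeparation:
    def test_groups_with_private_islands_separate_in_pc_space(self):
        """Three groups with group-specific planted islands: between-group
        distances in PC1-2 exceed mean within-group distances."""
        ok = 0
        for seed in range(3):
            cfg = rohscan.SimConfig(
                breeds=(rohscan.BreedConfig("g1", 10, (0.5, 0.3, 0, 0, 0), group="g1"),
                        rohscan.BreedConfig("g2", 10, (0.5, 0.3, 0, 0, 0), group="g2"),
                        rohscan.BreedConfig("g3", 10, (0.5, 0.3, 0, 0, 0), group="g3")),
                chrom_lengths_bp=(60_000_000, 60_000_000),
                islands=(rohscan.IslandSpec(1, 10_000_000, 13_000_000, "g1", 0.8),
                         rohscan.IslandSpec(1, 30_000_000, 33_000_000, "g2", 0.8),
                         rohscan.IslandSpec(2, 20_000_000, 23_000_000, "g3", 0.8)),
                seed=100 + seed)
            gm, _ = rohscan.simulate_panel(cfg)
            segs = rohscan.detect_roh_sliding(gm)
            curve = rohscan.support_curve(segs, gm.variants, gm.samples["sample_id"])
            regions = rohscan.call_islands(curve, min_freq=0.125)
            inc = build_incidence(segs, regions, gm.samples["sample_id"],
                                  min_freq=0.125, top_n=170)
            res = run_pca(inc)
            xy = res.scores.iloc[:, :2].to_numpy()
            labels = gm.samples.set_index("sample_id").loc[inc.index, "group"].to_numpy()
            cents = {g: xy[labels == g].mean(axis=0) for g in set(labels)}
            within = np.mean([np.linalg.norm(xy[labels == g] - cents[g], axis=1).mean()
                              for g in cents])
            gs = list(cents)
            between = np.mean([np.linalg.norm(cents[a] - cents[b])
                               for i, a in enumerate(gs) for b in gs[i + 1:]])
            ok += between > within
        assert ok >= 2
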