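from itertools import combinations

import numpy as np
import pytest

from reefcross.community import (
    bray_curtis,
    chao1,
    nb_wald_da,
    nmds,
    permanova,
    shifted_log,
    size_factors_median_ratio,
)
from reefcross.simulate import CommunityParams, simulate_symbiont_table


class TestSizeFactors:
    def test_identical_samples_all_one(self):
        mat = np.tile([[5], [9], [2]], (1, 4))
        assert size_factors_median_ratio(mat) == pytest.approx(np.ones(4))

    def test_doubled_sample_doubles_factor(self, rng):
        a = rng.integers(1, 50, size=20)
        mat = np.column_stack([a, 2 * a])
        f = size_factors_median_ratio(mat)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_single_otu_direct_formula(self):
        f = size_factors_median_ratio(np.array([[10, 20]]))
        assert f[1] / f[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_fallback_when_no_common_otu(self):
        mat = np.array([[4, 0], [0, 6]])
        with pytest.warns(UserWarning):
            f = size_factors_median_ratio(mat)
        assert np.all(f > 0)


class TestShiftedLog:
    @pytest.mark.parametrize(
        "count,factor,shift,expected",
        [(0, 1.0, 1.0, 0.0), (7, 1.0, 1.0, 3.0), (6, 2.0, 1.0, 2.0)],
    )
    def test_values(self, count, factor, shift, expected):
        out = shifted_log(np.array([[count]]), np.array([factor]), shift)
        assert out[0, 0] == pytest.approx(expected)

    def test_nonpositive_shift_rejected(self):
        with pytest.raises(ValueError):
            shifted_log(np.array([[1]]), np.array([1.0]), 0.0)


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3, 4, 5], 3.0),        # no singletons
            ([1, 1, 2, 5], 6.0),     # S=4, f1=2, f2=1
            ([1, 1], 3.0),           # bias-corrected branch, f2=0
            ([], 0.0),
            ([0, 0], 0.0),
        ],
    )
    def test_formula(self, counts, expected):
        assert chao1(np.array(counts, dtype=int)) == expected

    def test_at_least_observed_richness(self, rng):
        for _ in range(20):
            y = rng.integers(0, 20, size=30)
            assert chao1(y) >= np.count_nonzero(y)

    def test_high_mortality_class_richer(self, metadata_12v12):
        """Planted exclusive OTUs give the high-mortality class the larger
        mean Chao1, matching the direction of the richness difference
        between mortality classes."""
        wins = 0
        classes = metadata_12v12["mortality_class"].to_numpy()
        for seed in range(20):
            table, _, _ = simulate_symbiont_table(
                metadata_12v12, CommunityParams(), seed=300 + seed
            )
            ch = np.array([chao1(table.counts[:, j])
                           for j in range(table.shape[1])])
            wins += ch[classes == "high"].mean() > ch[classes == "low"].mean()
        assert wins >= 18

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chao1(np.array([1.5, 2.0]))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d[0, 1] == 0.0

    def test_disjoint_support_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 3.0]]))
        assert d[0, 1] == 1.0

    def test_hand_value(self):
        d = bray_curtis(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_symmetric_zero_diagonal(self, rng):
        d = bray_curtis(rng.random((6, 10)))
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all((0 <= d) & (d <= 1))

    def test_two_empty_samples_distance_zero_with_warning(self):
        mat = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
        with pytest.warns(UserWarning):
            d = bray_curtis(mat)
        assert d[0, 1] == 0.0


class TestNmds:
    def test_euclidean_configuration_recovered(self, rng):
        from scipy.spatial.distance import pdist, squareform

        pts = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(6, 1, (8, 2))])
        D = squareform(pdist(pts))
        res = nmds(D, n_starts=8, seed=1)
        assert res.stress < 0.01

    def test_stress_non_increasing_within_start(self, rng):
        comp = rng.dirichlet(np.ones(15) * 0.5, 12)
        res = nmds(bray_curtis(comp), n_starts=5, seed=2)
        hist = res.stress_history
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_separated_classes_stay_separated(self, rng):
        from scipy.spatial.distance import pdist

        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            comp = np.vstack([
                r.dirichlet([8, 2, 1, 1, 1], 7),
                r.dirichlet([1, 1, 1, 2, 8], 7),
            ])
            res = nmds(bray_curtis(comp), n_starts=8, seed=seed)
            X = res.coordinates
            within = np.concatenate([pdist(X[:7]), pdist(X[7:])]).mean()
            between = np.linalg.norm(
                X[:7, None, :] - X[None, 7:, :], axis=-1
            ).mean()
            wins += between > within
        assert wins >= 9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((3, 3)), k=2)


def permanova_exhaustive_p(D, labels):
    """Oracle: exhaustive enumeration over all relabelings that preserve
    the group sizes."""
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    lv = sorted(set(labels.tolist()))
    k0 = int(np.sum(labels == lv[0]))

    def pseudo_f(lab):
        res = permanova(D, lab, n_perm=0, seed=0)
        return res.pseudo_f

    f_obs = pseudo_f(labels)
    count = total = 0
    for idx in combinations(range(n), k0):
        lab = np.array([lv[0] if i in idx else lv[1] for i in range(n)],
                       dtype=object)
        total += 1
        count += pseudo_f(lab) >= f_obs - 1e-12
    return count / total


class TestPermanova:
    def test_p_close_to_exhaustive_enumeration(self, rng):
        comp = rng.random((6, 8))
        comp[:3] += 0.8
        D = bray_curtis(comp)
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        res = permanova(D, labels, n_perm=10_000, seed=3)
        p_exact = permanova_exhaustive_p(D, labels)
        assert abs(res.p - p_exact) < 0.01

    def test_agrees_with_independent_implementation(self, rng):
        import pandas as pd
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        comp = rng.random((12, 10))
        D = bray_curtis(comp)
        labels = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
        res = permanova(D, labels, n_perm=999, seed=0)
        ids = [f"s{i}" for i in range(12)]
        sk = skbio_permanova(DistanceMatrix(D, ids=ids),
                             pd.Series(labels, index=ids, name="grp"),
                             permutations=999)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_r2_zero_when_all_distances_equal(self):
        D = np.ones((6, 6)) - np.eye(6)
        res = permanova(D, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(0.1, abs=0.2)  # tiny, structureless
        assert res.p > 0.5

    def test_type_one_error_calibrated(self):
        """Labels independent of structure: rejection rate ~ alpha."""
        rej = 0
        n_sim = 400
        rng = np.random.default_rng(8)
        for _ in range(n_sim):
            comp = rng.random((12, 8))
            D = bray_curtis(comp)
            labels = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
            rng.shuffle(labels)
            if permanova(D, labels, n_perm=199, seed=int(rng.integers(1 << 30))).p <= 0.05:
                rej += 1
        assert 0.03 <= rej / n_sim <= 0.07

    def test_sample_order_invariance(self, rng):
        comp = rng.random((10, 8))
        D = bray_curtis(comp)
        labels = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        perm = rng.permutation(10)
        r1 = permanova(D, labels, n_perm=499, seed=4)
        r2 = permanova(D[np.ix_(perm, perm)], labels[perm], n_perm=499, seed=4)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)
        assert r1.r2 == pytest.approx(r2.r2)


class TestDifferentialAbundance:
    def test_planted_opportunist_fold_change_recovered(self, metadata_12v12):
        """A +2.8 log2 shift planted on one OTU (everything else null, so the
        compositional denominator stays comparable between classes) is
        recovered within half a log2 unit on average at 12 vs 12 samples."""
        cond = metadata_12v12["mortality_class"].to_numpy()
        l2fcs, sig = [], 0
        for seed in range(5):
            shift = np.zeros(60)
            shift[8] = 2.8  # OTU9
            params = CommunityParams(class_log2_shift=shift,
                                     n_exclusive_high=0, variant_pairs=[],
                                     sample_noise_sd=0.3)
            table, _, _ = simulate_symbiont_table(metadata_12v12, params,
                                                  seed=400 + seed)
            da = nb_wald_da(table, cond).set_index("otu_id")
            l2fcs.append(float(da.loc["OTU9", "log2_fold_change"]))
            sig += da.loc["OTU9", "p_adj"] < 0.05
        assert np.mean(l2fcs) == pytest.approx(2.8, abs=0.5)
        assert sig >= 4

    def test_default_opportunist_detected_as_enriched(self, symbiont,
                                                      metadata_12v12):
        table, _, truth = symbiont
        da = nb_wald_da(table, metadata_12v12["mortality_class"].to_numpy())
        row = da[da["otu_id"] == truth["opportunist_otu"]].iloc[0]
        assert row["log2_fold_change"] > 1.5
        assert row["p_adj"] < 0.05

    def test_contrast_swap_negates_fold_changes(self, metadata_12v12):
        # a table without class-exclusive OTUs, where every per-OTU fit is
        # well-posed in both contrast directions
        params = CommunityParams(n_exclusive_high=0, variant_pairs=[],
                                 sample_noise_sd=0.3)
        table, _, _ = simulate_symbiont_table(metadata_12v12, params, seed=31)
        cond = metadata_12v12["mortality_class"].to_numpy()
        da1 = nb_wald_da(table, cond, contrast=("high", "low"), min_nonzero=5)
        da2 = nb_wald_da(table, cond, contrast=("low", "high"), min_nonzero=5)
        both = da1["tested"] & da2["tested"]
        assert np.allclose(
            da1.loc[both, "log2_fold_change"],
            -da2.loc[both, "log2_fold_change"], atol=1e-3,
        )

    def test_otu_order_invariance_of_bh(self, symbiont, metadata_12v12):
        table, _, _ = symbiont
        cond = metadata_12v12["mortality_class"].to_numpy()
        da1 = nb_wald_da(table, cond).set_index("otu_id")
        rng = np.random.default_rng(0)
        order = rng.permutation(len(table.otu_ids))
        from reefcross.io import CountTable

        shuffled = CountTable(
            otu_ids=[table.otu_ids[i] for i in order],
            sample_ids=table.sample_ids,
            counts=table.counts[order],
        )
        da2 = nb_wald_da(shuffled, cond).set_index("otu_id")
        common = da1.index[da1["tested"]]
        assert np.allclose(da1.loc[common, "p_adj"], da2.loc[common, "p_adj"],
                           atol=1e-9, equal_nan=True)

    def test_bh_adjusted_at_least_raw(self, symbiont, metadata_12v12):
        table, _, _ = symbiont
        da = nb_wald_da(table, metadata_12v12["mortality_class"].to_numpy())
        ok = da["tested"] & da["wald_p"].notna()
        assert (da.loc[ok, "p_adj"] >= da.loc[ok, "wald_p"] - 1e-12).all()

    def test_all_zero_otu_excluded(self, metadata_12v12):
        mat = np.vstack([np.zeros(24, dtype=int),
                         np.random.default_rng(1).integers(1, 60, 24)])
        da = nb_wald_da(mat, metadata_12v12["mortality_class"].to_numpy())
        assert not da.iloc[0]["tested"]
        assert np.isnan(da.iloc[0]["log2_fold_change"])

    def test_realized_fdr_under_null(self):
        """Within-model null generator (NB counts, no class structure):
        the mean fraction of false discoveries at BH 0.05 stays at or
        below 0.08 (here every discovery is false)."""
        from conftest import class_metadata

        meta = class_metadata(5, 5, 4)  # 20 vs 20 samples
        cond = meta["mortality_class"].to_numpy()
        fdrs = []
        for seed in range(30):
            params = CommunityParams(
                n_otus=40, class_log2_shift=np.zeros(40),
                n_exclusive_high=0, variant_pairs=[], sample_noise_sd=0.0,
            )
            table, _, _ = simulate_symbiont_table(meta, params, seed=900 + seed)
            da = nb_wald_da(table, cond)
            n_disc = int((da["p_adj"] < 0.05).sum())
            fdrs.append(1.0 if n_disc > 0 else 0.0)
        assert np.mean(fdrs) <= 0.08
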