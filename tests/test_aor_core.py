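import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aortax import aor_core
from aortax.aor_core import (anova_across_ranks, aor_strength, bh_adjust, build_records,
                             category_proportions, classify_category, compute_mean_abundance,
                             compute_occupancy, filter_low_abundance, fold_change_consecutive,
                             niche_width_index, rank_statistics, spearman_rho)
from aortax.preprocess import SubcommunityView
from aortax.synthetic_data import SyntheticConfig, generate_latent_views, generate_taxonomy
from aortax.taxonomy import RANKS


# ---------------------------------------------------------------- oracles

def spearman_oracle(x, y):
    """Midrank transform + explicit covariance formula."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))


def bh_oracle(p):
    """Direct step-up: sort, p(i)*m/i, cumulative min from the largest."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def ols_slope_oracle(x, y):
    """Normal-equation arithmetic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return b, y.mean() - b * x.mean()


def anova_f_oracle(groups):
    """Between/within mean squares from first principles."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b, df_w = len(groups) - 1, len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


# ---------------------------------------------------------------- records

class TestRecordBuilding:
    def test_occupancy_counts_nonzero_stations(self, simple_view):
        occ = compute_occupancy(simple_view)
        assert occ.to_dict() == {"OTU1": 2, "OTU2": 2, "OTU3": 3}

    def test_all_zero_taxon_dropped(self, simple_view):
        simple_view.abundance.loc["OTU1"] = 0.0
        assert "OTU1" not in compute_occupancy(simple_view).index

    def test_mean_includes_zero_stations(self):
        """A taxon at 0.9% on one of nine stations has mean 0.1%, not 0.9%."""
        abund = pd.DataFrame([np.r_[0.9, np.zeros(8)]], index=["t"],
                             columns=[f"st{i}" for i in range(9)])
        view = SubcommunityView("surface", "FL", abund)
        assert compute_mean_abundance(view)["t"] == pytest.approx(0.1)

    def test_constant_row_mean_identity(self):
        abund = pd.DataFrame([[2.0] * 9], index=["t"], columns=[f"s{i}" for i in range(9)])
        view = SubcommunityView("CIL", "PA", abund)
        assert compute_mean_abundance(view)["t"] == pytest.approx(2.0)

    @pytest.mark.parametrize("mean,kept", [(0.0019, False), (0.002, True), (0.5, True)])
    def test_low_abundance_filter_strictly_less(self, mean, kept):
        records = pd.DataFrame({"mean_rel_abund": [mean]})
        assert (len(filter_low_abundance(records)) == 1) is kept

    def test_zero_threshold_is_identity(self):
        records = pd.DataFrame({"mean_rel_abund": [1e-9, 5.0]})
        assert len(filter_low_abundance(records, threshold=0.0)) == 2

    @pytest.mark.parametrize("occ,expected", [
        (6, "generalist"), (7, "generalist"), (9, "generalist"),
        (2, "specialist"), (1, "specialist"),
        (3, "neither"), (4, "neither"), (5, "neither"),
    ])
    def test_category_boundaries_at_nine_stations(self, occ, expected):
        assert classify_category(occ, 9) == expected

    def test_category_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_category(0, 9)
        with pytest.raises(ValueError):
            classify_category(10, 9)

    def test_category_proportions(self):
        records = pd.DataFrame({"category": ["generalist", "generalist", "specialist", "neither"]})
        assert category_proportions(records) == (0.5, 0.25, 0.25)


# ---------------------------------------------------------------- statistics

class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        rho, p = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0) and p == pytest.approx(0.0)

    def test_matches_midrank_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 31)
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n).round(1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_input_undefined(self):
        rho, p = spearman_rho([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)

    def test_p_value_t_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p = spearman_rho(x, y)
        t = rho * np.sqrt((20 - 2) / (1 - rho ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=18), rel=1e-9)


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_capped_at_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(2, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])


class TestAORStrength:
    def test_permutation_invariance(self):
        records = pd.DataFrame({"occupancy": [1, 5, 9, 3, 7],
                                "mean_rel_abund": [0.1, 0.5, 2.0, 0.2, 1.1]})
        r1 = aor_strength(records)
        r2 = aor_strength(records.sample(frac=1, random_state=0))
        assert r1[0] == pytest.approx(r2[0])

    def test_constant_occupancy_undefined(self):
        records = pd.DataFrame({"occupancy": [9, 9, 9], "mean_rel_abund": [1.0, 2.0, 3.0]})
        rho, p, n = aor_strength(records)
        assert np.isnan(rho) and n == 3

    def test_too_few_records_missing(self):
        records = pd.DataFrame({"occupancy": [1, 2], "mean_rel_abund": [0.1, 0.2]})
        assert np.isnan(aor_strength(records)[0])


class TestNicheWidth:
    def test_exact_exponential_fit(self):
        records = pd.DataFrame({"occupancy": [1, 2, 3],
                                "mean_rel_abund": np.exp([1.0, 2.0, 3.0])})
        slope, intercept = niche_width_index(records)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_abundance_zero_slope(self):
        records = pd.DataFrame({"occupancy": [1, 5, 9], "mean_rel_abund": [2.0, 2.0, 2.0]})
        assert niche_width_index(records)[0] == pytest.approx(0.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        occ = rng.integers(1, 10, size=50).astype(float)
        ab = np.exp(rng.normal(size=50))
        records = pd.DataFrame({"occupancy": occ, "mean_rel_abund": ab})
        slope, intercept = niche_width_index(records)
        b, a = ols_slope_oracle(occ, np.log(ab))
        assert slope == pytest.approx(b, abs=1e-10)
        assert intercept == pytest.approx(a, abs=1e-10)

    def test_zero_abundance_rejected(self):
        records = pd.DataFrame({"occupancy": [1, 2, 3], "mean_rel_abund": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            niche_width_index(records)


class TestFoldChange:
    def test_ratio_arithmetic(self):
        slopes = dict(zip(RANKS, [0.2, 0.3, 0.4, 0.45, 0.5, 1.5]))
        fc = fold_change_consecutive(slopes)
        last = fc.iloc[-1]
        assert last["finer_rank"] == "class" and last["ratio"] == pytest.approx(3.0)
        assert bool(last["is_max"])

    def test_equal_slopes_all_one(self):
        fc = fold_change_consecutive({r: 0.7 for r in RANKS})
        np.testing.assert_allclose(fc["ratio"], 1.0)

    def test_sign_change_missing(self):
        slopes = dict(zip(RANKS, [0.2, -0.3, 0.4, 0.45, 0.5, 1.5]))
        fc = fold_change_consecutive(slopes)
        assert fc["ratio"].isna().sum() == 2  # species->genus and genus->family

    def test_missing_rank_rejected(self):
        with pytest.raises(ValueError):
            fold_change_consecutive({"species": 1.0})


class TestAnova:
    @staticmethod
    def _slopes_frame(values_by_rank):
        rows = []
        for rank, vals in values_by_rank.items():
            for (depth, fraction), v in zip(
                    [(d, f) for d in ("surface", "CIL") for f in ("FL", "PA")], vals):
                rows.append({"rank": rank, "depth": depth, "fraction": fraction, "slope": v})
        return pd.DataFrame(rows)

    def test_identical_groups_give_f_zero_single_letter(self):
        # every rank holds the same four replicate values -> equal means
        frame = self._slopes_frame({r: [0.8, 0.9, 1.1, 1.2] for r in RANKS})
        cmp_ = anova_across_ranks(frame)
        assert cmp_.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert len(set(cmp_.letters.values())) == 1
        assert not cmp_.tukey["significant"].any()

    def test_separated_groups_all_significant_distinct_letters(self):
        rng = np.random.default_rng(1)
        frame = self._slopes_frame({r: (10.0 * i + rng.normal(0, 1e-3, 4)).tolist()
                                    for i, r in enumerate(RANKS)})
        cmp_ = anova_across_ranks(frame)
        assert cmp_.tukey["significant"].all()
        assert len(set(cmp_.letters.values())) == 6

    def test_f_matches_mean_squares_oracle(self):
        rng = np.random.default_rng(9)
        frame = self._slopes_frame({r: rng.normal(size=4).tolist() for r in RANKS})
        cmp_ = anova_across_ranks(frame)
        groups = [g["slope"].to_numpy() for _, g in frame.groupby("rank")]
        assert cmp_.f_statistic == pytest.approx(anova_f_oracle(groups), abs=1e-10)

    def test_tukey_matches_monte_carlo_studentized_range(self):
        """Adjusted p for one pair vs a large Monte-Carlo draw of the
        studentized range at the error degrees of freedom."""
        rng = np.random.default_rng(11)
        frame = self._slopes_frame({r: rng.normal(i * 0.3, 1.0, 4).tolist()
                                    for i, r in enumerate(RANKS)})
        cmp_ = anova_across_ranks(frame)
        groups = {r: g["slope"].to_numpy() for r, g in frame.groupby("rank")}
        k, n = 6, 24
        df_err = n - k
        mse = np.mean([np.var(g, ddof=1) for g in groups.values()])
        row = cmp_.tukey.iloc[0]
        diff = abs(groups[row["rank_a"]].mean() - groups[row["rank_b"]].mean())
        q_obs = diff / np.sqrt(mse / 4)
        draws = 1_000_000
        z = rng.normal(size=(draws, k))
        q_null = (z.max(axis=1) - z.min(axis=1)) / np.sqrt(rng.chisquare(df_err, size=draws) / df_err)
        p_mc = np.mean(q_null >= q_obs)
        assert row["p_adjusted"] == pytest.approx(p_mc, abs=0.005)

    def test_letters_consistent_with_significance(self):
        rng = np.random.default_rng(5)
        frame = self._slopes_frame({r: rng.normal(i * 0.8, 0.4, 4).tolist()
                                    for i, r in enumerate(RANKS)})
        cmp_ = anova_across_ranks(frame)
        sig = {tuple(sorted((a, b))): s for a, b, s in
               zip(cmp_.tukey["rank_a"], cmp_.tukey["rank_b"], cmp_.tukey["significant"])}
        for a in RANKS:
            for b in RANKS:
                if a < b and set(cmp_.letters[a]) & set(cmp_.letters[b]):
                    assert not sig[tuple(sorted((a, b)))]

    def test_too_few_groups_rejected(self):
        frame = self._slopes_frame({"species": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            anova_across_ranks(frame)


class TestRankStatistics:
    def test_full_run_shape_and_bh_family(self):
        cfg = SyntheticConfig(n_species=300, seed=6)
        views, hier, _ = generate_latent_views(cfg)
        tax = generate_taxonomy(cfg)
        records, stats_df = rank_statistics(views, tax)
        assert len(stats_df) == 24  # 6 ranks x 4 subcommunities
        ok = stats_df.dropna(subset=["p_value"])
        assert (ok["p_adjusted"] >= ok["p_value"] - 1e-15).all()
        assert stats_df["p_adjusted"].dropna().between(0, 1).all()
        # per-subcommunity family never produces smaller adjusted values
        _, stats_sub = rank_statistics(views, tax, bh_family="per_subcommunity")
        assert len(stats_sub) == 24

    def test_drop_unclassified_removes_sentinels(self):
        cfg = SyntheticConfig(n_species=300, seed=6, sentinel_fraction=0.5)
        views, hier, _ = generate_latent_views(cfg)
        tax = generate_taxonomy(cfg)
        view = views[("surface", "FL")]
        from aortax.taxonomy import aggregate_to_rank
        agg = aggregate_to_rank(view, tax, "genus")
        with_s = build_records(agg)
        without_s = build_records(agg, drop_unclassified=True)
        assert len(without_s) < len(with_s)
        assert not without_s["taxon"].str.startswith("unclassified_").any()
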