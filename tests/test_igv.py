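"""IGV detection: curves, mixture threshold, classification, pair rules, tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from coraligv.config import DepthModel, FilterConfig, SimulationConfig
from coraligv.dissimilarity import AntimodeGap, pairwise_dissimilarity
from coraligv.exact_tests import fisher_exact_rxc
from coraligv.genotypes import apply_filters
from coraligv.igv import (
    DegenerateFitError,
    GMMFit,
    classify_colonies,
    colony_max_distance,
    enumerate_intra_colonial_pairs,
    evaluate_filter_grid,
    fit_gmm_2,
    gaussian_intersection,
    igv_curve,
    surface_correlation,
)
from coraligv.simulate import simulate_dataset
from coraligv.toy import toy_colony_structure


class TestColonyMaxAndCurve:
    def test_max_of_constructed_colony(self):
        cls, D, meta = toy_colony_structure(1, 0, 2, 1, seed=0)
        maxima = colony_max_distance(D, meta).set_index("colony_id")
        assert maxima.loc["C001", "max_percent_diff"] > 8.4   # the chimeric colony
        assert maxima.loc["C004", "max_percent_diff"] < 1.0   # a 2-nubbin colony

    def test_zero_variation_all_maxima_zero(self):
        cfg = SimulationConfig(n_colonies=4, n_sites_total=500, n_lineages=3,
                               p_mosaic_colony=0, p_chimera_colony=0,
                               mosaic_mutation_count=0, per_allele_error_rate=0,
                               missing_rate=0, error_rate_sample_cv=0, seed=2)
        ds = simulate_dataset(cfg)
        D = pairwise_dissimilarity(ds.genotypes)
        maxima = colony_max_distance(D, ds.meta)
        assert (maxima["max_percent_diff"] == 0).all()

    @pytest.mark.parametrize("maxima, t50", [
        ([1, 2, 3], 2.0),
        ([0, 0, 10, 10], 5.0),
    ])
    def test_t50_is_median_of_maxima(self, maxima, t50):
        assert igv_curve(maxima).t50 == t50

    def test_curve_non_increasing_and_crosses_half_at_t50(self):
        rng = np.random.default_rng(1)
        maxima = rng.exponential(2.0, size=51)
        curve = igv_curve(maxima, thresholds=np.linspace(0, 10, 400))
        assert (np.diff(curve.fraction_igv) <= 1e-12).all()
        assert curve.t50 == pytest.approx(np.percentile(maxima, 50))

    def test_t50_converges_to_distribution_median(self):
        """Monte-Carlo consistency: sample medians approach the true median."""
        rng = np.random.default_rng(7)
        errs = [abs(igv_curve(rng.lognormal(0.0, 0.5, n)).t50 - 1.0)
                for n in (100, 10_000) for _ in range(5)]
        small, large = np.mean(errs[:5]), np.mean(errs[5:])
        assert large < small


class TestGMM:
    def test_recovers_well_separated_clusters_exactly(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.01, 300), rng.normal(10, 0.01, 700)])
        fit = fit_gmm_2(x, seed=0, n_restarts=5)
        assert fit.weights == pytest.approx((0.3, 0.7), abs=1e-6)
        assert fit.means == pytest.approx((0.0, 10.0), abs=0.01)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_gmm_2(np.ones(100), seed=0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            fit_gmm_2(np.arange(10.0), seed=0)

    def test_matches_sklearn_on_overlapping_mixture(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        comp = rng.random(4000) < 0.7
        x = np.where(comp, rng.normal(1.0, 0.2, 4000), rng.normal(2.0, 0.3, 4000))
        fit = fit_gmm_2(x, seed=0)
        g = GaussianMixture(2, tol=1e-8, max_iter=500, n_init=5,
                            random_state=0).fit(x.reshape(-1, 1))
        order = np.argsort(g.means_.ravel())
        assert fit.means == pytest.approx(tuple(g.means_.ravel()[order]), abs=1e-3)
        assert fit.weights == pytest.approx(tuple(g.weights_[order]), abs=1e-3)


class TestIntersection:
    def test_symmetric_equal_weights_midpoint(self):
        fit = GMMFit(weights=(0.5, 0.5), means=(0.0, 2.0), sds=(1.0, 1.0))
        assert gaussian_intersection(fit) == pytest.approx(1.0)
        assert fit.intersection_between_means

    def test_unequal_weights_closed_form(self):
        fit = GMMFit(weights=(0.9, 0.1), means=(0.0, 2.0), sds=(1.0, 1.0))
        x = gaussian_intersection(fit)
        assert x == pytest.approx(1.0 + math.log(9) / 2.0, abs=1e-12)
        assert not fit.intersection_between_means  # 2.099 lies beyond both means

    def test_printed_fit_intersects_at_one_percent(self):
        fit = GMMFit(weights=(0.890, 0.110), means=(0.851, 1.054), sds=(0.067, 0.072))
        assert round(gaussian_intersection(fit), 1) == 1.0

    def test_root_satisfies_density_equality(self):
        from scipy.stats import norm

        fit = GMMFit(weights=(0.8, 0.2), means=(1.0, 3.0), sds=(0.5, 0.9))
        x = gaussian_intersection(fit)
        d1 = fit.weights[0] * norm.pdf(x, fit.means[0], fit.sds[0])
        d2 = fit.weights[1] * norm.pdf(x, fit.means[1], fit.sds[1])
        assert abs(d1 - d2) < 1e-10 * max(d1, d2, 1e-30)


class TestClassification:
    GAP = AntimodeGap(1.3, 8.4)

    def _frame(self, m):
        return pd.DataFrame({"colony_id": ["X"], "max_percent_diff": [m],
                             "n_nubbins": [3], "classifiable": [True]})

    @pytest.mark.parametrize("maximum, category", [
        (0.5, "invariable"),
        (1.1, "mosaic"),
        (9.0, "chimeric"),
    ])
    def test_threshold_rules(self, maximum, category):
        cls = classify_colonies(self._frame(maximum), t_err=1.0, chimera_gap=self.GAP)
        assert cls.category_of("X") == category
        assert not cls.table["ambiguous"].iloc[0]

    def test_in_gap_maximum_flagged_ambiguous(self):
        cls = classify_colonies(self._frame(5.0), t_err=1.0, chimera_gap=self.GAP)
        assert cls.category_of("X") == "chimeric"  # 5.0 above gap midpoint 4.85
        assert cls.table["ambiguous"].iloc[0]

    def test_no_gap_labels_all_igv_mosaic_with_warning(self):
        with pytest.warns(UserWarning, match="labelled mosaic"):
            cls = classify_colonies(self._frame(9.0), t_err=1.0,
                                    pairwise_values=None, chimera_gap=None)
        assert cls.category_of("X") == "mosaic"

    def test_igv_count_non_increasing_in_t_err(self):
        rng = np.random.default_rng(0)
        maxima = pd.DataFrame({
            "colony_id": [f"C{i}" for i in range(40)],
            "max_percent_diff": rng.uniform(0.2, 2.0, 40),
            "n_nubbins": 3, "classifiable": True,
        })
        counts = []
        for t in np.linspace(0.5, 2.0, 8):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cls = classify_colonies(maxima, t_err=t, chimera_gap=self.GAP)
            c = cls.counts()
            counts.append(c["mosaic"] + c["chimeric"])
        assert (np.diff(counts) <= 0).all()


class TestPairEnumeration:
    def test_single_three_nubbin_chimera(self):
        cls, D, meta = toy_colony_structure(1, 0, 0, 0, seed=4)
        pairs = enumerate_intra_colonial_pairs(cls, D, meta)
        assert (pairs["pair_type"] == "chimeric").sum() == 2
        assert (pairs["pair_type"] == "mosaic").sum() == 1

    def test_distant_nubbin_is_in_every_chimeric_pair(self):
        cls, D, meta = toy_colony_structure(3, 0, 0, 0, seed=5)
        pairs = enumerate_intra_colonial_pairs(cls, D, meta)
        for colony, grp in pairs[pairs["pair_type"] == "chimeric"].groupby("colony_id"):
            common = set(grp["sample_a"]) & set(grp["sample_b"])
            distant = common.pop() if common else set(grp["sample_a"]).pop()
            # the distant nubbin appears in both chimeric pairs of the colony
            members = list(grp["sample_a"]) + list(grp["sample_b"])
            assert members.count(distant) == 2

    def test_survey_scale_bookkeeping(self):
        cls, D, meta = toy_colony_structure(10, 1, 80, 2, seed=6)
        pairs = enumerate_intra_colonial_pairs(cls, D, meta)
        assert (pairs["pair_type"] == "chimeric").sum() == 21
        assert (pairs["pair_type"] == "mosaic").sum() == 252


class TestFisher:
    def test_perfect_independence(self):
        assert fisher_exact_rxc([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_2x2_matches_hypergeometric_enumeration(self):
        res = fisher_exact_rxc([[3, 0], [0, 3]])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_2x2_matches_scipy(self):
        from scipy.stats import fisher_exact

        table = [[7, 3], [2, 9]]
        assert fisher_exact_rxc(table).p_value == pytest.approx(
            fisher_exact(table)[1], abs=1e-10)

    def test_3x3_site_by_category_table(self):
        res = fisher_exact_rxc([[24, 3, 4], [22, 4, 6], [29, 0, 1]])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.062, abs=0.001)

    def test_monte_carlo_fallback_agrees_with_exact(self):
        table = [[24, 3, 4], [22, 4, 6], [29, 0, 1]]
        exact = fisher_exact_rxc(table).p_value
        mc = fisher_exact_rxc(table, max_tables=10, n_mc=40_000, seed=1)
        assert mc.method == "monte-carlo"
        assert mc.p_value == pytest.approx(exact, abs=0.01)

    def test_empty_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="empty rows"):
            res = fisher_exact_rxc([[5, 5, 0], [5, 5, 0]])
        assert res.p_value == pytest.approx(1.0)


class TestSurfaceCorrelation:
    def _setup(self, values):
        cls, D, meta = toy_colony_structure(0, 0, 6, 0, seed=7)
        pairs = enumerate_intra_colonial_pairs(cls, D, meta)
        meta = meta.copy()
        for i, colony in enumerate(sorted(meta["colony_id"].unique())):
            meta.loc[meta["colony_id"] == colony, "surface_length_cm"] = values[i]
            meta.loc[meta["colony_id"] == colony, "surface_width_cm"] = 1.0
        return meta, D, pairs

    def test_perfect_linear_relation(self):
        cls, D, meta = toy_colony_structure(0, 0, 6, 0, seed=7)
        pairs = enumerate_intra_colonial_pairs(cls, D, meta)
        meta = meta.copy()
        per_colony = {}
        for _, r in pairs.iterrows():
            per_colony.setdefault(r["colony_id"], []).append(
                D.value(r["sample_a"], r["sample_b"]))
        for colony, vals in per_colony.items():
            meta.loc[meta["colony_id"] == colony, "surface_length_cm"] = np.mean(vals)
            meta.loc[meta["colony_id"] == colony, "surface_width_cm"] = 1.0
        r2, p = surface_correlation(meta, D, pairs)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_dissimilarity_undefined(self):
        meta, D, pairs = self._setup([10, 20, 30, 40, 50, 60])
        D.percent[:, :] = 1.0
        np.fill_diagonal(D.percent, 0.0)
        with pytest.raises(ValueError, match="zero variance"):
            surface_correlation(meta, D, pairs)

    def test_too_few_colonies_rejected(self):
        meta, D, pairs = self._setup([10, 20, 30, 40, 50, 60])
        few = pairs[pairs["colony_id"].isin(["C001", "C002"])]
        with pytest.raises(ValueError, match="three colonies"):
            surface_correlation(meta, D, few)

    def test_permuted_surfaces_give_near_zero_r2(self):
        """Null simulation: with surfaces independent of dissimilarity the
        squared correlation stays small on average."""
        rng = np.random.default_rng(11)
        r2s = []
        for _ in range(20):
            meta, D, pairs = self._setup(rng.uniform(5, 50, 6))
            r2, _ = surface_correlation(meta, D, pairs)
            r2s.append(r2)
        assert np.mean(r2s) < 0.35


@pytest.fixture(scope="module")
def grid_dataset():
    cfg = SimulationConfig(n_colonies=10, n_sites_total=5000, n_lineages=4,
                           mosaic_mutation_count=50, missing_rate=0.1,
                           low_dp_error_multiplier=10.0,
                           depth_model=DepthModel(mean=25, shape=1.0),
                           n_replicated_nubbins=3, seed=31)
    return simulate_dataset(cfg)


class TestFilterGrid:

    def test_dp_filter_lowers_replicate_error(self, grid_dataset):
        grid = [FilterConfig(min_dp=0), FilterConfig(min_dp=12)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = evaluate_filter_grid(grid_dataset.genotypes, grid_dataset.meta, grid)
        assert out.loc[1, "delta_rep"] < out.loc[0, "delta_rep"]

    def test_nsnp_non_increasing_as_thresholds_tighten(self, grid_dataset):
        grid = [FilterConfig(min_qual=0, min_dp=0, max_sp=1e9),
                FilterConfig(min_qual=20, min_dp=0, max_sp=1e9),
                FilterConfig(min_qual=20, min_dp=12, max_sp=1e9),
                FilterConfig(min_qual=20, min_dp=12, max_sp=13),
                FilterConfig(min_qual=20, min_dp=12, max_sp=13, max_na_fraction=0.5)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = evaluate_filter_grid(grid_dataset.genotypes, grid_dataset.meta, grid)
        assert (out["n_snp"].diff().dropna() <= 0).all()

    def test_inactive_filter_changes_nothing(self, grid_dataset):
        # every genotype has SP well below 1e6, so the SP filter is inactive
        grid = [FilterConfig(max_sp=1e6), FilterConfig(max_sp=2e6)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = evaluate_filter_grid(grid_dataset.genotypes, grid_dataset.meta, grid)
        a, b = out.iloc[0], out.iloc[1]
        assert a["n_snp"] == b["n_snp"]
        assert a["t50"] == b["t50"] and a["delta_rep"] == b["delta_rep"]

    def test_config_with_no_sites_recorded_as_zero(self, grid_dataset):
        grid = [FilterConfig(min_qual=1e9)]
        out = evaluate_filter_grid(grid_dataset.genotypes, grid_dataset.meta, grid)
        assert out.loc[0, "n_snp"] == 0 and np.isnan(out.loc[0, "t50"])
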