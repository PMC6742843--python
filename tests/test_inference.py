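"""Two-sample inference: pooled t, BH-FDR, edge-wise and node-wise group
comparisons, seed restriction combinatorics, and a planted-hub power check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from roinet import (
    ConnectivityMatrix,
    GraphConfig,
    SeedRestriction,
    bh_fdr,
    edgewise_group_comparison,
    fisher_z,
    functional_connectivity,
    node_metrics,
    nodewise_metric_comparison,
    simulate_cohort,
    threshold_binarize,
    two_sample_t,
)
from roinet.atlas import conn_style_labels, synthetic_labels
from roinet.cohort import CohortSpec, PlantedEffect


class TestTwoSampleT:
    def test_closed_form_example(self):
        # means 2 vs 5, both variances 1 -> t = -3 / sqrt(2/3)
        t, df, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), abs=5e-4)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(3.674, 4), abs=1e-4)

    def test_identical_groups(self):
        t, _, p = two_sample_t([3.0, 1.0, 2.0], [3.0, 1.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_degenerate_zero_variance_equal_means(self):
        t, _, p = two_sample_t([0.0, 0.0], [0.0, 0.0])
        assert t == 0.0 and p == 1.0

    def test_degenerate_zero_variance_unequal_means(self):
        t, _, p = two_sample_t([1.0, 1.0], [0.0, 0.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(12), rng.standard_normal(9) + 0.4
        t, df, p = two_sample_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        assert df == 19

    def test_nonfinite_values_dropped(self):
        t1, _, _ = two_sample_t([1.0, 2.0, np.nan], [3.0, 4.0])
        t2, _, _ = two_sample_t([1.0, 2.0], [3.0, 4.0])
        assert t1 == t2


class TestBhFdr:
    def test_step_up_worked_example(self):
        adj = bh_fdr(np.array([0.001, 0.008, 0.039, 0.041]))
        assert np.allclose(adj, [0.004, 0.016, 0.041, 0.041])

    def test_single_pvalue_unchanged(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_all_ones_stay_ones(self):
        adj = bh_fdr(np.ones(10))
        assert np.all(adj == 1.0)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, p, rnd):
        p = np.asarray(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        adj = bh_fdr(p)
        adj_perm = bh_fdr(p[perm])
        assert np.allclose(adj[perm], adj_perm)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


def _random_z_matrices(labels, n_subjects, seed, shift=None):
    rng = np.random.default_rng(seed)
    n = len(labels)
    mats = []
    for _ in range(n_subjects):
        v = rng.normal(size=(n, n)) * 0.1
        v = (v + v.T) / 2
        if shift is not None:
            v = v + shift
        np.fill_diagonal(v, np.nan)
        mats.append(ConnectivityMatrix(v, kind="FUN", roi_labels=labels, is_z=True))
    return mats


class TestSeedRestriction:
    def test_tested_pair_count_on_full_atlas(self):
        """FUN tested pairs = seed-nonseed pairs + seed-seed pairs once."""
        atlas = conn_style_labels()
        restriction = SeedRestriction(seeds=atlas.seeds)
        pairs = restriction.tested_pairs(atlas.all_labels, "FUN")
        n_seeds = len(atlas.seeds)          # 8 + 2 + 26 = 36
        n_other = atlas.n_rois - n_seeds    # 96
        expected = n_seeds * n_other + n_seeds * (n_seeds - 1) // 2
        assert len(pairs) == expected == 36 * 96 + 36 * 35 // 2
        assert len(set(map(frozenset, pairs))) == len(pairs)  # no duplicates
        assert all(s != t for s, t in pairs)

    def test_eff_tests_both_directions(self):
        atlas = conn_style_labels()
        restriction = SeedRestriction(seeds=atlas.seeds)
        fun = restriction.tested_pairs(atlas.all_labels, "FUN")
        eff = restriction.tested_pairs(atlas.all_labels, "EFF")
        assert len(eff) == 2 * len(fun)
        assert len(set(eff)) == len(eff)

    def test_unknown_seed_rejected(self):
        restriction = SeedRestriction(seeds=["nope"])
        with pytest.raises(ValueError, match="not in matrix"):
            restriction.tested_pairs(["a", "b"], "FUN")


class TestEdgewiseComparison:
    def test_label_swap_negates_t_exactly(self):
        labels, seeds = synthetic_labels(8, 2)
        mats = _random_z_matrices(labels, 12, seed=3)
        groups = ["patient"] * 6 + ["control"] * 6
        swapped = ["control" if g == "patient" else "patient" for g in groups]
        restriction = SeedRestriction(seeds=seeds)
        a = edgewise_group_comparison(mats, groups, restriction)
        b = edgewise_group_comparison(mats, swapped, restriction)
        assert np.allclose(a["t"].to_numpy(), -b["t"].to_numpy())
        assert np.allclose(a["p"].to_numpy(), b["p"].to_numpy())

    def test_identical_groups_all_t_zero(self):
        labels, seeds = synthetic_labels(6, 2)
        mats = _random_z_matrices(labels, 4, seed=4)
        both = mats + mats  # each subject copied into both groups
        groups = ["patient"] * 4 + ["control"] * 4
        table = edgewise_group_comparison(both, groups, SeedRestriction(seeds=seeds))
        assert np.all(table["t"] == 0.0)
        assert np.all(table["p"] == 1.0)
        assert not table["significant"].any()

    def test_q_zero_retains_nothing(self):
        labels, seeds = synthetic_labels(6, 2)
        mats = _random_z_matrices(labels, 10, seed=5, shift=None)
        groups = ["patient"] * 5 + ["control"] * 5
        table = edgewise_group_comparison(
            mats, groups, SeedRestriction(seeds=seeds), q=0.0
        )
        assert not table["significant"].any()

    def test_significance_flag_matches_p_fdr(self):
        labels, seeds = synthetic_labels(10, 3)
        mats = _random_z_matrices(labels, 20, seed=6)
        groups = ["patient"] * 10 + ["control"] * 10
        table = edgewise_group_comparison(mats, groups, SeedRestriction(seeds=seeds))
        assert (table["significant"] == (table["p_fdr"] < 0.05)).all()
        assert np.all(table["p_fdr"] >= table["p"] - 1e-15)

    def test_per_seed_fdr_scope(self):
        labels, seeds = synthetic_labels(10, 3)
        mats = _random_z_matrices(labels, 12, seed=7)
        groups = ["patient"] * 6 + ["control"] * 6
        joint = edgewise_group_comparison(mats, groups, SeedRestriction(seeds=seeds))
        per_seed = edgewise_group_comparison(
            mats, groups, SeedRestriction(seeds=seeds, fdr_scope="per_seed")
        )
        for s in seeds:
            sub_p = joint.loc[joint["seed"] == s, "p"].to_numpy()
            sub_adj = per_seed.loc[per_seed["seed"] == s, "p_fdr"].to_numpy()
            assert np.allclose(sub_adj, bh_fdr(sub_p))

    def test_mismatched_labels_hard_error(self):
        m1 = _random_z_matrices(["a", "b", "c"], 4, seed=8)
        m2 = _random_z_matrices(["a", "b", "x"], 4, seed=9)
        with pytest.raises(ValueError, match="share"):
            edgewise_group_comparison(
                m1 + m2, ["patient"] * 4 + ["control"] * 4,
                SeedRestriction(seeds=["a"]),
            )


class TestNodewiseComparison:
    @staticmethod
    def _tables(labels, n, seed, bump=None):
        rng = np.random.default_rng(seed)
        tables = []
        for _ in range(n):
            vals = rng.normal(size=(len(labels), 7))
            df = pd.DataFrame(
                vals,
                index=pd.Index(labels, name="roi"),
                columns=[
                    "degree", "cost", "betweenness", "avg_path_length",
                    "global_efficiency", "local_efficiency", "clustering",
                ],
            )
            if bump is not None:
                df.loc[bump[0], bump[1]] += bump[2]
            tables.append(df)
        return tables

    def test_identical_groups_all_t_zero(self):
        labels = ["a", "b", "c"]
        tabs = self._tables(labels, 4, seed=0)
        table = nodewise_metric_comparison(
            tabs + tabs, ["patient"] * 4 + ["control"] * 4, "degree"
        )
        assert np.all(table["t"] == 0.0)

    def test_undefined_values_excluded_per_node(self):
        labels = ["a", "b"]
        tabs = self._tables(labels, 8, seed=1)
        for tab in tabs[:7]:
            tab.loc["b", "avg_path_length"] = np.nan  # isolated in 7 subjects
        table = nodewise_metric_comparison(
            tabs, ["patient"] * 4 + ["control"] * 4, "avg_path_length"
        )
        row_b = table[table["node"] == "b"].iloc[0]
        assert np.isnan(row_b["t"])  # fewer than 2 defined values per group
        row_a = table[table["node"] == "a"].iloc[0]
        assert np.isfinite(row_a["t"])

    def test_unknown_metric_rejected(self):
        tabs = self._tables(["a"], 4, seed=2)
        with pytest.raises(ValueError, match="unknown metric"):
            nodewise_metric_comparison(
                tabs, ["patient", "patient", "control", "control"], "pagerank"
            )

    def test_planted_hub_strengthening_detected(self):
        """Adding +0.3 correlation to every edge of one seed must raise
        that seed's degree, cost and global efficiency in patients, with a
        positive t in >=80% of replicate cohorts."""
        labels, seeds = synthetic_labels(20, 4)
        hub = seeds[0]
        # +0.3 on every hub edge into the second community: the patients'
        # hub joins that block (0.15 + 0.3 = 0.45, above the 0.4 z cut);
        # mutually correlated targets keep the matrix positive definite.
        effects = [PlantedEffect(hub, lab, 0.3) for lab in labels[10:]]
        hits = {"degree": 0, "cost": 0, "global_efficiency": 0}
        n_reps = 10
        for rep in range(n_reps):
            spec = CohortSpec(
                n_per_group=14, n_timepoints=220, roi_labels=labels,
                blocks=[labels[:10], labels[10:]],
                r_within=0.5, r_between=0.15,
                planted_effects=effects,
                drift_slope=0.0, sinusoid_amplitude=0.0,
                motion_noise_scale=0.0, nuisance_loading_scale=0.0,
                master_seed=3000 + rep,
            )
            cohort = simulate_cohort(spec)
            tables = [
                node_metrics(threshold_binarize(fisher_z(functional_connectivity(ts)),
                                                GraphConfig()))
                for ts in cohort.subjects
            ]
            for metric in hits:
                table = nodewise_metric_comparison(tables, cohort.groups, metric)
                row = table[table["node"] == hub].iloc[0]
                hits[metric] += int(row["t"] > 0)
        for metric, n_hit in hits.items():
            assert n_hit / n_reps >= 0.8, metric
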