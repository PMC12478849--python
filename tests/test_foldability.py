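"""RMSD thresholding, foldability aggregation and Shapley attribution."""

import numpy as np
import pandas as pd
import pytest

from g4topo.foldability import (
    ThresholdSet,
    attribution_by_level,
    exact_shapley_attribution,
    featurize,
    fit_foldability_classifier,
    foldability_by_feature,
    foldability_map,
    label_foldable,
    rmsd_threshold,
    shapley_values,
    two_loop_combination_table,
)


def make_records(rows):
    """Minimal records frame from (topology, polarity, lengths, rmsd)."""
    data = []
    for topology, polarity, (i, j, k), rmsd in rows:
        data.append(
            {
                "conformation_id": f"3T-RH|{topology}|{polarity}|{i}.{j}.{k}",
                "n_tetrads": 3,
                "helicity": "RH",
                "topology": topology,
                "polarity": polarity,
                "len_I": i,
                "len_II": j,
                "len_III": k,
                "rmsd_nm": rmsd,
            }
        )
    return pd.DataFrame(data)


class TestThresholding:
    def test_percentile_linear_interpolation(self):
        assert rmsd_threshold(np.arange(1, 101), 99) == pytest.approx(99.01)

    def test_constant_series(self):
        assert rmsd_threshold([0.07] * 10, 42.0) == pytest.approx(0.07)

    def test_percentile_exceeds_median(self):
        rng = np.random.default_rng(0)
        samples = rng.gamma(2.0, 0.03, size=1000)
        assert rmsd_threshold(samples, 99) > np.median(samples)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd_threshold([])

    def test_strict_inequality_at_boundary(self):
        records = make_records(
            [
                ("-p-p-p", "LP.LP.LP", (1, 1, 1), 0.05),
                ("-p-p-p", "LP.LP.LP", (1, 1, 2), 0.104),
                ("-p-p-p", "LP.LP.LP", (1, 1, 3), 0.1039999),
            ]
        )
        labeled = label_foldable(records)
        assert labeled["foldable"].tolist() == [True, False, True]

    def test_missing_class_threshold_raises(self):
        records = make_records([("-p-p-p", "LP.LP.LP", (1, 1, 1), 0.05)])
        records["helicity"] = "LH"  # no 3T-LH default threshold
        with pytest.raises(KeyError, match="3T-LH"):
            label_foldable(records)

    def test_extreme_thresholds(self, labeled_records):
        everything = ThresholdSet(thresholds_nm={"3T-RH": 1e9})
        nothing = ThresholdSet(thresholds_nm={"3T-RH": 1e-12})
        assert label_foldable(labeled_records, everything)["foldable"].all()
        assert not label_foldable(labeled_records, nothing)["foldable"].any()

    def test_partition_sizes_match_direct_scan(self, labeled_records):
        n_foldable = int(labeled_records["foldable"].sum())
        direct = int((labeled_records["rmsd_nm"] < 0.104).sum())
        assert n_foldable == direct


class TestAggregation:
    def test_all_foldable_gives_unit_cells(self):
        records = make_records(
            [
                ("-p-p-p", "LP.LP.LP", (1, 1, 1), 0.02),
                ("-p-p-p", "LP.LP.LP", (2, 2, 2), 0.02),
                ("+l+l+l", "LP.LP.LP", (2, 2, 2), 0.02),
            ]
        )
        table = foldability_map(label_foldable(records))
        assert np.nanmax(table.to_numpy()) == 1.0
        assert np.nanmin(table.to_numpy()) == 1.0

    def test_single_record_cells_are_binary_and_empty_cells_missing(self):
        records = make_records(
            [
                ("-p-p-p", "LP.LP.LP", (1, 1, 1), 0.02),
                ("+l+l+l", "LP.LP.LP", (2, 2, 2), 0.5),
            ]
        )
        table = foldability_map(label_foldable(records))
        assert set(np.unique(table.to_numpy()[~np.isnan(table.to_numpy())])) <= {0.0, 1.0}
        assert np.isnan(table.loc["-p-p-p", 6])  # no record at total length 6

    def test_rows_ordered_by_decreasing_mean_foldability(self, labeled_records):
        table = foldability_map(labeled_records)
        means = labeled_records.groupby("topology")["foldable"].mean()
        assert list(table.index) == list(means.sort_values(ascending=False).index)

    def test_ld_rows_increase_with_total_length(self, labeled_records):
        """For LD-bearing topologies the generated foldability rises with
        total loop length (length relief of the LD penalty)."""
        table = foldability_map(labeled_records)
        for topology in ("+p+p+l", "-l-p-p"):
            row = table.loc[topology].dropna()
            assert row.iloc[-1] > row.iloc[0]

    def test_feature_table_uniform_labels(self):
        records = make_records(
            [("-p-p-p", "LP.LP.LP", (1, 1, 1), 0.02),
             ("+l+l+l", "LP.LP.LP", (2, 2, 2), 0.03)]
        )
        table = foldability_by_feature(label_foldable(records), "type")
        assert (table["foldability"] == 1.0).all()

    def test_feature_table_position_effect(self, labeled_records):
        """An anticlockwise propeller at position I (always short-distance
        under RH) beats the same loop at position II (often long-distance)."""
        table = foldability_by_feature(labeled_records, "type")
        get = lambda pos: table.query(
            "position == @pos and value == '-p'"
        )["foldability"].iloc[0]
        assert get("I") > get("II")

    def test_two_loop_combination_single_topology(self, labeled_records):
        table = two_loop_combination_table(labeled_records)
        singles = table[~table["topologies"].str.contains(",")]
        assert len(singles) > 0
        by_topo = labeled_records.groupby("topology")["foldable"].mean()
        for row in singles.itertuples():
            assert row.foldability == pytest.approx(by_topo[row.topologies])

    def test_unfavorable_pair_below_marginal(self, labeled_records):
        """-l at I followed by -p at II (a long-distance context) scores
        below the marginal mean of -p at II."""
        pairs = two_loop_combination_table(labeled_records)
        pair = pairs.query(
            "position_a == 'I' and type_a == '-l' and "
            "position_b == 'II' and type_b == '-p'"
        )["foldability"].iloc[0]
        marginal = foldability_by_feature(labeled_records, "type").query(
            "position == 'II' and value == '-p'"
        )["foldability"].iloc[0]
        assert pair < marginal


class TestClassifier:
    def test_perfectly_separable_data(self, labeled_records):
        sep = labeled_records.copy()
        sep["foldable"] = sep["len_I"] >= 3  # label is a feature function
        result = fit_foldability_classifier(sep, n_folds=5, seed=0)
        assert result.precision_mean == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_precision(self, labeled_records):
        rng = np.random.default_rng(0)
        shuffled = labeled_records.copy()
        shuffled["foldable"] = rng.permutation(shuffled["foldable"].to_numpy())
        result = fit_foldability_classifier(shuffled, n_folds=5, seed=0)
        prevalence = shuffled["foldable"].mean()
        assert abs(result.precision_mean - prevalence) < 0.05

    def test_recovers_signal_above_prevalence(self, labeled_records):
        result = fit_foldability_classifier(labeled_records, n_folds=10, seed=0)
        assert result.precision_mean > result.prevalence + 0.2

    def test_single_class_rejected(self, labeled_records):
        allsame = labeled_records.copy()
        allsame["foldable"] = True
        with pytest.raises(ValueError):
            fit_foldability_classifier(allsame)

    def test_deterministic_given_seed(self, labeled_records):
        sub = labeled_records.sample(2000, random_state=0)
        a = fit_foldability_classifier(sub, n_folds=5, seed=11)
        b = fit_foldability_classifier(sub, n_folds=5, seed=11)
        assert a.precision_mean == b.precision_mean


class TestShapley:
    def test_efficiency_for_arbitrary_value_function(self):
        rng = np.random.default_rng(0)
        table = {
            frozenset(S): rng.normal()
            for r in range(5)
            for S in __import__("itertools").combinations(range(4), r)
        }
        phi = shapley_values(lambda S: table[S], 4)
        assert phi.sum() == pytest.approx(
            table[frozenset(range(4))] - table[frozenset()], abs=1e-9
        )

    def test_symmetry_for_exchangeable_features(self):
        v = lambda S: float(len(S & {0, 1})) ** 2 + 0.3 * (2 in S)
        phi = shapley_values(v, 3)
        assert phi[0] == pytest.approx(phi[1], abs=1e-9)

    def test_dummy_feature_gets_zero(self):
        v = lambda S: 1.5 * (0 in S) + 0.7 * (1 in S)
        phi = shapley_values(v, 3)
        assert phi[2] == pytest.approx(0.0, abs=1e-9)

    def test_single_feature_model_takes_full_attribution(self):
        v = lambda S: 2.0 if 1 in S else 0.5
        phi = shapley_values(v, 4)
        assert phi[1] == pytest.approx(1.5, abs=1e-9)
        assert np.allclose(np.delete(phi, 1), 0.0, atol=1e-9)

    def test_feature_limit_enforced(self):
        with pytest.raises(ValueError, match="sampl"):
            shapley_values(lambda S: 0.0, 13)

    def test_retrained_attribution_efficiency(self, labeled_records):
        """Per record, attributions sum to full prediction minus base rate."""
        from sklearn.tree import DecisionTreeClassifier

        sub = labeled_records.sample(800, random_state=1).reset_index(drop=True)
        att = exact_shapley_attribution(
            sub,
            model_factory=lambda s: DecisionTreeClassifier(max_depth=4, random_state=s),
            seed=1,
            features=["type_I", "type_II", "len_I"],
        )
        totals = att.per_record.sum(axis=1)
        assert np.allclose(totals, att.full_prediction - att.base_value, atol=1e-9)

    def test_attribution_sign_pattern(self, labeled_records):
        """Position-I propeller direction dominates: -p at I (always SD
        under RH) is the top favorable level, +p at I (always LD) the most
        unfavorable; the pattern reverses under LH (mirror grid)."""
        from sklearn.tree import DecisionTreeClassifier

        import g4topo as g
        from g4topo.simulate import GenerativeParams

        factory = lambda s: DecisionTreeClassifier(max_depth=6, random_state=s)
        att = exact_shapley_attribution(labeled_records, model_factory=factory, seed=2)
        levels = attribution_by_level(labeled_records, att)
        types = levels[levels["feature"].str.startswith("type")]
        get = lambda f, v: types.query("feature == @f and value == @v")[
            "mean_attribution"
        ].iloc[0]
        assert types.iloc[0]["feature"] == "type_I" and types.iloc[0]["value"] == "-p"
        assert get("type_I", "+p") == types["mean_attribution"].min()

        lh_grid = g.enumerate_conformations(3, (1, 4), "LH")
        lh = label_foldable(
            g.generate_records(lh_grid, GenerativeParams(seed=20250911)),
            ThresholdSet(thresholds_nm={"3T-LH": 0.104}),
        )
        att_lh = exact_shapley_attribution(lh, model_factory=factory, seed=2)
        lh_types = attribution_by_level(lh, att_lh)
        lh_types = lh_types[lh_types["feature"].str.startswith("type")]
        get_lh = lambda f, v: lh_types.query("feature == @f and value == @v")[
            "mean_attribution"
        ].iloc[0]
        assert get_lh("type_I", "+p") > 0 > get_lh("type_I", "-p")
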