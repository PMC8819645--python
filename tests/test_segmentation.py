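"""Behavior naming, subsegments, transitions, duration bins, summaries."""

import numpy as np
import pandas as pd
import pytest

from flightmodes.cluster import KMeansResult
from flightmodes.config import FOCAL_VARIABLES
from flightmodes.features import ScalingParams
from flightmodes.segmentation import (
    SEGMENT_END,
    LabelingError,
    cluster_summaries,
    crosstab_by_group,
    duration_bins,
    find_subsegments,
    label_behaviors,
    transition_matrix,
)


def identity_scaling():
    return ScalingParams(
        sqrt_flags={v: False for v in FOCAL_VARIABLES},
        means={v: 0.0 for v in FOCAL_VARIABLES},
        sds={v: 1.0 for v in FOCAL_VARIABLES},
    )


def model_with_centroids(rows):
    cents = np.zeros((len(rows), 6))
    for i, (speed, vr) in enumerate(rows):
        cents[i, 0] = speed  # kph
        cents[i, 1] = speed  # sn
        cents[i, 4] = vr  # vr
    return KMeansResult(
        k=len(rows), centroids=cents, labels=np.arange(len(rows)) + 1,
        wss=0.0, n_starts=1, seed=0, scaling=identity_scaling(),
    )


class TestLabelBehaviors:
    def test_speed_and_vertical_rate_rule(self):
        m = model_with_centroids([(0.5, 0.0), (30, 2.0), (25, 0.0), (50, -2.0)])
        assert label_behaviors(m) == {
            1: "perching", 2: "ascending", 3: "flapping", 4: "gliding"
        }

    def test_other_k_gets_generic_names_with_warning(self):
        m = model_with_centroids([(0.5, 0.0), (30, 2.0), (50, -2.0)])
        with pytest.warns(UserWarning):
            names = label_behaviors(m)
        assert names == {1: "cluster_1", 2: "cluster_2", 3: "cluster_3"}

    def test_vertical_rate_tie_raises(self):
        m = model_with_centroids([(0.5, 0.0), (30, 2.0), (25, 2.0), (50, 2.0)])
        with pytest.raises(LabelingError):
            label_behaviors(m)


def labeled_frame(clusters, times=None, segments=None, animal="a1"):
    n = len(clusters)
    times = times if times is not None else np.arange(n) * 5.0
    return pd.DataFrame(
        {
            "animal_id": animal,
            "t": pd.to_datetime("2021-01-01", utc=True)
            + pd.to_timedelta(np.asarray(times, dtype=float), unit="s"),
            "segment_id": segments if segments is not None else 0,
            "cluster": clusters,
            "behavior": [f"b{c}" for c in clusters],
        }
    )


def subsegment_oracle(labels):
    """Run-length encoding of a label sequence."""
    runs = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    return runs


class TestFindSubsegments:
    def test_run_length_example(self):
        sub = find_subsegments(labeled_frame(["A", "A", "B", "A"]))
        assert sub["cluster"].tolist() == ["A", "B", "A"]
        assert sub["n_points"].tolist() == [2, 1, 1]
        assert sub["subsegment_id"].tolist() == [0, 1, 2]

    def test_uniform_segment_single_subsegment_with_duration(self):
        sub = find_subsegments(labeled_frame(["A"] * 5, times=[0, 10, 20, 30, 40]))
        assert len(sub) == 1
        assert sub.loc[0, "duration"] == 40.0

    def test_single_point_subsegment_has_zero_duration(self):
        sub = find_subsegments(labeled_frame(["A", "B", "A"]))
        assert (sub["duration"] == 0.0).all()
        assert (sub["n_points"] == 1).all()

    def test_unlabeled_fix_raises(self):
        df = labeled_frame(["A", "B"])
        df.loc[1, "cluster"] = np.nan
        with pytest.raises(ValueError):
            find_subsegments(df)

    def test_segment_boundary_breaks_runs(self):
        df = labeled_frame(["A", "A", "A", "A"], segments=[0, 0, 1, 1])
        sub = find_subsegments(df)
        assert len(sub) == 2
        assert sub["subsegment_id"].tolist() == [0, 0]

    def test_matches_run_length_oracle_on_random_sequences(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            labels = rng.choice(list("ABCD"), size=n).tolist()
            segs = np.sort(rng.integers(0, 3, size=n))
            sub = find_subsegments(labeled_frame(labels, segments=segs))
            expected = []
            for s in np.unique(segs):
                expected += subsegment_oracle(
                    [l for l, g in zip(labels, segs) if g == s]
                )
            assert sub["cluster"].tolist() == [r[0] for r in expected]
            assert sub["n_points"].tolist() == [r[1] for r in expected]
            assert sub["n_points"].sum() == n


class TestTransitionMatrix:
    def test_three_subsegment_example(self):
        sub = find_subsegments(labeled_frame(["A", "B", "A"]))
        sub["behavior"] = sub["cluster"]
        tm = transition_matrix(sub, states=["A", "B"])
        assert tm.counts.loc["A", "B"] == 1
        assert tm.counts.loc["B", "A"] == 1
        assert tm.counts.loc["A", SEGMENT_END] == 1
        assert tm.probabilities.loc["A", "B"] == pytest.approx(0.5)
        assert tm.probabilities.loc["A", SEGMENT_END] == pytest.approx(0.5)
        assert tm.probabilities.loc["B", "A"] == pytest.approx(1.0)

    def test_single_subsegment_goes_to_segment_end(self):
        sub = find_subsegments(labeled_frame(["A", "A"]))
        sub["behavior"] = sub["cluster"]
        tm = transition_matrix(sub, states=["A"])
        assert tm.probabilities.loc["A", SEGMENT_END] == 1.0

    def test_rows_stochastic_with_zero_diagonal(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(list("ABC"), size=500).tolist()
        segs = np.sort(rng.integers(0, 40, size=500))
        sub = find_subsegments(labeled_frame(labels, segments=segs))
        tm = transition_matrix(sub)
        sums = tm.probabilities.sum(axis=1)
        assert np.allclose(sums[tm.counts.sum(axis=1) > 0], 1.0, atol=1e-12)
        for s in tm.states:
            assert tm.counts.loc[s, s] == 0
        # every subsegment contributes exactly one transition
        assert tm.counts.to_numpy().sum() == len(sub)

    def test_zero_total_row_is_undefined(self):
        sub = find_subsegments(labeled_frame(["A", "A"]))
        sub["behavior"] = sub["cluster"]
        tm = transition_matrix(sub, states=["A", "Z"])
        assert tm.probabilities.loc["Z"].isna().all()


class TestDurationBins:
    def sub(self, durations, behavior="b"):
        return pd.DataFrame({"behavior": behavior, "duration": durations})

    def test_three_way_split(self):
        out = duration_bins(self.sub([0.0, 5.0, 30.0]))
        row = out.loc["b"]
        assert row["0s"] == pytest.approx(1 / 3)
        assert row["0-22s"] == pytest.approx(1 / 3)
        assert row[">22s"] == pytest.approx(1 / 3)
        assert row["count"] == 3

    def test_all_single_points(self):
        out = duration_bins(self.sub([0.0, 0.0]))
        assert out.loc["b", "0s"] == 1.0
        assert out.loc["b", ">22s"] == 0.0

    def test_boundary_value_falls_in_closed_right_bin(self):
        out = duration_bins(self.sub([22.0]))
        assert out.loc["b", "0-22s"] == 1.0

    def test_proportions_sum_to_one_per_behavior(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "behavior": rng.choice(["x", "y"], size=100),
                "duration": rng.exponential(15, size=100).round(0),
            }
        )
        out = duration_bins(df)
        assert np.allclose(out.drop(columns="count").sum(axis=1), 1.0)

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            duration_bins(self.sub([1.0]), edges=(10.0, 5.0))


class TestClusterSummaries:
    def test_hand_quantiles(self):
        feats = pd.DataFrame({v: [1.0, 2, 3, 4, 5] for v in FOCAL_VARIABLES})
        out = cluster_summaries(feats, [1] * 5)
        row = out[out["variable"] == "kph"].iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (2.0, 3.0, 4.0)
        assert row["min"] == 1.0 and row["max"] == 5.0

    def test_single_value_collapses(self):
        feats = pd.DataFrame({v: [7.0] for v in FOCAL_VARIABLES})
        out = cluster_summaries(feats, [1])
        row = out.iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"]

    def test_whiskers_clipped_at_data_and_iqr_rule(self):
        vals = [0.0, 10, 11, 12, 13, 14, 100]
        feats = pd.DataFrame({v: vals for v in FOCAL_VARIABLES})
        out = cluster_summaries(feats, [1] * len(vals))
        row = out[out["variable"] == "kph"].iloc[0]
        q1, q3 = np.percentile(vals, [25, 75])
        assert row["whisker_hi"] == pytest.approx(min(100.0, q3 + 1.5 * (q3 - q1)))
        assert row["whisker_lo"] == pytest.approx(max(0.0, q1 - 1.5 * (q3 - q1)))


class TestCrosstab:
    def toy(self):
        return pd.DataFrame(
            {
                "stage": ["local", "local", "local", "mig", "mig", "mig"],
                "behavior": ["p", "g", "g", "g", "g", "p"],
            }
        )

    def test_proportions_match_enumeration(self):
        out = crosstab_by_group(self.toy(), "stage")
        assert out.loc["local", "g"] == pytest.approx(2 / 3)
        assert out.loc["mig", "p"] == pytest.approx(1 / 3)
        assert out.loc["local", "pct_points"] == pytest.approx(50.0)

    def test_single_group_sums_to_one(self):
        df = self.toy().assign(stage="local")
        out = crosstab_by_group(df, "stage")
        assert out.drop(columns="pct_points").sum(axis=1).tolist() == pytest.approx([1.0])

    def test_empty_input_gives_empty_table(self):
        assert crosstab_by_group(pd.DataFrame(), "stage").empty

    def test_unknown_group_value_kept_verbatim(self):
        df = self.toy()
        df.loc[0, "stage"] = "mystery"
        out = crosstab_by_group(df, "stage")
        assert "mystery" in out.index
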