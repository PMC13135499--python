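"""Disclosure-risk metrics against planted constructions and O(n²) oracles."""

import numpy as np
import pandas as pd
import pytest

from tabsafe.privacy import (
    baseline_match_rate,
    cap_score,
    cluster_k_anonymity,
    delta_presence,
    identifiability_score,
    inference_risk,
    k_map,
    l_diversity,
    linkability_score,
    match_rate,
    mia_density,
    single_out_score,
)
from tabsafe.schema import MatchConfig


def planted_clusters(rng, groups=10, per_group=10, dim=3, spread=0.01, sep=50.0):
    centers = rng.standard_normal((groups, dim)) * sep
    rows = np.vstack(
        [c + rng.standard_normal((per_group, dim)) * spread for c in centers]
    )
    labels = np.repeat(np.arange(groups), per_group)
    df = pd.DataFrame(rows, columns=[f"x{j}" for j in range(dim)])
    return df, labels


class TestClusterKAnonymity:
    def test_planted_groups_recovered(self, rng):
        df, _ = planted_clusters(rng, groups=10, per_group=10)
        score = cluster_k_anonymity(
            df, list(df.columns), granularities=[10], seed=0
        )
        assert score == 10

    def test_degenerate_duplicates_fall_back(self, rng):
        df = pd.DataFrame({"x": [1.0] * 100, "y": [2.0] * 100})
        det = {}
        score = cluster_k_anonymity(df, ["x", "y"], granularities=[2], seed=0,
                                    details=det)
        assert score == 100
        assert det["fallbacks"]

    def test_too_few_rows_guarded(self, rng):
        df = pd.DataFrame({"x": [1.0]})
        with pytest.raises(ValueError, match="at least"):
            cluster_k_anonymity(df, ["x"], granularities=[2])


class TestLDiversity:
    def test_constant_sensitive_gives_one(self, rng):
        df, _ = planted_clusters(rng)
        df["disease"] = "flu"
        assert l_diversity(df, ["x0", "x1", "x2"], ["disease"],
                           granularities=[10]) == 1

    def test_planted_three_distinct_values(self, rng):
        df, labels = planted_clusters(rng, groups=5, per_group=9)
        df["disease"] = np.tile(["a", "b", "c"], 15)
        assert l_diversity(df, ["x0", "x1", "x2"], ["disease"],
                           granularities=[5]) == 3

    def test_all_unique_sensitive_equals_occupancy(self, rng):
        df, _ = planted_clusters(rng, groups=5, per_group=8)
        df["disease"] = [f"d{i}" for i in range(len(df))]
        assert l_diversity(df, ["x0", "x1", "x2"], ["disease"],
                           granularities=[5]) == 8


class TestKMapDeltaPresence:
    def test_kmap_self_copy_equals_own_minimum(self, rng):
        df, _ = planted_clusters(rng, groups=4, per_group=12)
        own = cluster_k_anonymity(df, list(df.columns), granularities=[4], seed=0)
        assert k_map(df, df.copy(), list(df.columns), granularities=[4]) == own

    def test_kmap_concentrated_synth_zero(self, rng):
        df, _ = planted_clusters(rng, groups=4, per_group=12)
        synth = pd.concat([df.iloc[:1]] * 30, ignore_index=True)
        assert k_map(df, synth, list(df.columns), granularities=[4]) == 0

    def test_kmap_uniform_synth_expectation(self, rng):
        df, _ = planted_clusters(rng, groups=4, per_group=25, sep=100.0)
        synth = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        score = k_map(df, synth, list(df.columns), granularities=[4])
        assert abs(score - 25) <= 5  # ≈ n_synth / granularity

    def test_delta_presence_full_overlap(self, rng):
        df, _ = planted_clusters(rng, groups=4, per_group=12)
        df["disease"] = np.tile(["a", "b"], 24)
        assert delta_presence(df, df.copy(), ["x0", "x1", "x2"], ["disease"],
                              granularities=[4]) == 1.0

    def test_delta_presence_disjoint_vocabulary(self, rng):
        df, _ = planted_clusters(rng, groups=4, per_group=12)
        df["disease"] = "real_only"
        synth = df.copy()
        synth["disease"] = "synth_only"
        assert delta_presence(df, synth, ["x0", "x1", "x2"], ["disease"],
                              granularities=[4]) == 0.0

    def test_delta_presence_planted_half_overlap(self, rng):
        df, labels = planted_clusters(rng, groups=4, per_group=10, sep=100.0)
        # per cluster: real has sensitive {a, b}; synth replicates only {a}
        df["disease"] = np.tile(["a", "b"], 20)
        synth = df[df["disease"] == "a"].copy()
        score = delta_presence(df, synth, ["x0", "x1", "x2"], ["disease"],
                               granularities=[4])
        assert score == pytest.approx(0.5)


class TestIdentifiability:
    def test_exact_copy_scores_one(self, rng):
        real = rng.standard_normal((40, 4))
        assert identifiability_score(real, real.copy()) == 1.0

    def test_far_displaced_scores_zero(self, rng):
        real = rng.standard_normal((40, 4))
        assert identifiability_score(real, real + 1e4) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_30_rows(self, seed):
        r = np.random.default_rng(seed)
        real = r.standard_normal((30, 3))
        synth = r.standard_normal((25, 3))
        got = identifiability_score(real, synth)
        # oracle: explicit O(n²) double loop on standardized data
        mu, sd = real.mean(0), real.std(0)
        R = (real - mu) / sd
        S = (synth - mu) / sd
        hits = 0
        for i in range(len(R)):
            ds = min(np.linalg.norm(R[i] - s) for s in S)
            dr = sorted(
                np.linalg.norm(R[i] - R[j]) for j in range(len(R)) if j != i
            )[1]
            hits += ds < dr
        assert got == pytest.approx(hits / len(R))

    def test_single_out_matches_identifiability(self, rng):
        real = rng.standard_normal((30, 3))
        synth = rng.standard_normal((30, 3))
        assert single_out_score(real, synth) == identifiability_score(real, synth)

    def test_row_order_invariance(self, rng):
        real = rng.standard_normal((30, 3))
        synth = rng.standard_normal((20, 3))
        perm = rng.permutation(20)
        assert identifiability_score(real, synth) == identifiability_score(
            real, synth[perm]
        )


class TestMIADensity:
    def test_independent_synth_near_chance(self, rng):
        train = rng.standard_normal((500, 4))
        holdout = rng.standard_normal((500, 4))
        synth = rng.standard_normal((800, 4))
        acc, auc = mia_density(train, holdout, synth)
        assert abs(auc - 0.5) <= 0.07
        assert 0.0 <= acc <= 1.0

    def test_planted_leakage_detected(self, rng):
        train = rng.standard_normal((150, 6)) * 4
        holdout = rng.standard_normal((150, 6)) * 4
        synth = np.vstack([train + rng.standard_normal(train.shape) * 0.01] * 2)
        _, auc = mia_density(train, holdout, synth, neighbors=2)
        assert auc > 0.9

    def test_same_records_exact_symmetry(self, rng):
        x = rng.standard_normal((100, 3))
        synth = rng.standard_normal((200, 3))
        _, auc = mia_density(x, x.copy(), synth)
        assert auc == pytest.approx(0.5)

    def test_neighbors_guard(self, rng):
        with pytest.raises(ValueError, match="neighbors"):
            mia_density(
                rng.standard_normal((10, 2)),
                rng.standard_normal((10, 2)),
                rng.standard_normal((5, 2)),
                neighbors=5,
            )


class TestCAP:
    def test_deterministic_attribution(self):
        real = pd.DataFrame(
            {"age": [30.0, 40.0, 50.0], "sex": ["F", "M", "F"],
             "disease": ["a", "b", "c"]}
        )
        assert cap_score(real, real.copy(), ["age", "sex"], "disease", "zero") == 1.0
        assert cap_score(real, real.copy(), ["age", "sex"], "disease",
                         "generalized") == 1.0

    def test_shuffled_sensitive_near_chance(self, rng):
        n, c = 2000, 4
        keys = rng.integers(0, 50, size=n).astype(float)
        real = pd.DataFrame({"k": keys, "s": rng.choice(list("abcd"), n)})
        synth = real.copy()
        synth["s"] = rng.permutation(synth["s"].to_numpy())
        score = cap_score(real, synth, ["k"], "s", "zero")
        assert abs(score - 1 / c) < 0.08

    def test_no_key_overlap_zero_mode(self):
        real = pd.DataFrame({"k": ["a", "b"], "s": ["x", "y"]})
        synth = pd.DataFrame({"k": ["c", "d"], "s": ["x", "y"]})
        assert cap_score(real, synth, ["k"], "s", "zero") == 0.0

    def test_missing_sensitive_column_rejected(self):
        real = pd.DataFrame({"k": ["a"], "s": ["x"]})
        synth = pd.DataFrame({"k": ["a"]})
        with pytest.raises(ValueError, match="sensitive"):
            cap_score(real, synth, ["k"], "s")


class TestInferenceRisk:
    def test_deterministic_function_gives_one(self):
        real = pd.DataFrame({"k": [1.0, 2.0, 3.0] * 5, "s": ["a", "b", "c"] * 5})
        assert inference_risk(real, real.copy(), ["k"], "s") == 1.0

    def test_independent_secret_near_chance(self, rng):
        n = 1500
        real = pd.DataFrame(
            {"k": rng.standard_normal(n), "s": rng.choice(list("ab"), n)}
        )
        synth = pd.DataFrame(
            {"k": rng.standard_normal(n), "s": rng.choice(list("ab"), n)}
        )
        assert abs(inference_risk(real, synth, ["k"], "s") - 0.5) < 0.1

    def test_empty_known_set_is_modal_frequency(self):
        real = pd.DataFrame({"s": ["a"] * 7 + ["b"] * 3})
        synth = pd.DataFrame({"s": ["a"] * 6 + ["b"] * 4})
        assert inference_risk(real, synth, [], "s") == pytest.approx(0.7)


class TestLinkability:
    def test_self_copy_links(self, rng):
        real = pd.DataFrame(
            {
                "a1": rng.standard_normal(40),
                "a2": rng.standard_normal(40),
                "b1": rng.standard_normal(40),
                "b2": rng.standard_normal(40),
            }
        )
        score = linkability_score(real, real.copy(), (["a1", "a2"], ["b1", "b2"]))
        assert score == pytest.approx(1.0)

    def test_independent_synth_near_zero(self, rng):
        cols = ["a1", "a2", "b1", "b2"]
        real = pd.DataFrame(rng.standard_normal((500, 4)), columns=cols)
        synth = pd.DataFrame(rng.standard_normal((500, 4)), columns=cols)
        score = linkability_score(real, synth, (["a1", "a2"], ["b1", "b2"]))
        assert score < 0.05

    def test_overlapping_subsets_rejected(self, rng):
        real = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="disjoint"):
            linkability_score(real, real.copy(), (["a"], ["a", "b"]))

    def test_single_row_guarded(self):
        real = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match="at least 2"):
            linkability_score(real, real.copy(), (["a"], ["b"]))


class TestMatchRate:
    def test_self_match_any_config(self):
        real = pd.DataFrame({"age": [30.0, 40.0], "sex": ["F", "M"]})
        mc = MatchConfig("1", {"age": 0.0, "sex": 0.0})
        assert match_rate(real, real.copy(), mc) == 1.0

    def test_disjoint_ranges_zero(self):
        real = pd.DataFrame({"age": [30.0, 40.0]})
        synth = pd.DataFrame({"age": [300.0, 400.0]})
        assert match_rate(real, synth, MatchConfig("1", {"age": 5.0})) == 0.0

    def test_hand_built_instance_vs_exhaustive_scan(self):
        real = pd.DataFrame({"age": [30.0, 40.0, 50.0, 60.0],
                             "sex": ["F", "F", "M", "M"]})
        synth = pd.DataFrame({"age": [31.0, 44.0, 49.0, 90.0],
                              "sex": ["F", "F", "M", "F"]})
        mc = MatchConfig("1", {"age": 2.0, "sex": 0.0})
        got = match_rate(real, synth, mc)
        # exhaustive pair scan
        hits = 0
        for _, s in synth.iterrows():
            hits += any(
                abs(s["age"] - r["age"]) <= 2.0 and s["sex"] == r["sex"]
                for _, r in real.iterrows()
            )
        assert got == pytest.approx(hits / len(synth)) == pytest.approx(0.5)

    def test_missing_cells_never_match(self):
        real = pd.DataFrame({"age": [np.nan, 40.0]})
        synth = pd.DataFrame({"age": [np.nan, 40.0]})
        mc = MatchConfig("1", {"age": 1.0})
        assert match_rate(real, synth, mc) == 0.5

    def test_date_spans_in_days(self):
        real = pd.DataFrame({"d": pd.to_datetime(["2010-01-01"])})
        close = pd.DataFrame({"d": pd.to_datetime(["2010-01-03"])})
        far = pd.DataFrame({"d": pd.to_datetime(["2010-02-01"])})
        mc = MatchConfig("1", {"d": 5.0})
        assert match_rate(real, close, mc) == 1.0
        assert match_rate(real, far, mc) == 0.0


class TestBaselineMatchRate:
    def test_identical_individuals_full_match(self):
        real = pd.DataFrame(
            {"pid": ["p1", "p2", "p3"], "age": [30.0, 30.0, 30.0]}
        )
        mc = MatchConfig("1", {"age": 0.0})
        assert baseline_match_rate(real, mc, "pid") == 1.0

    def test_unique_individuals_no_match(self):
        real = pd.DataFrame({"pid": ["p1", "p2"], "age": [30.0, 90.0]})
        assert baseline_match_rate(real, MatchConfig("1", {"age": 1.0}), "pid") == 0.0

    def test_self_rows_excluded(self):
        # two rows of the same person match each other but nobody else
        real = pd.DataFrame({"pid": ["p1", "p1", "p2"], "age": [30.0, 30.0, 50.0]})
        assert baseline_match_rate(real, MatchConfig("1", {"age": 0.0}), "pid") == 0.0

    def test_planted_twin_construction(self):
        # 4 individuals; p1/p2 are cross-individual twins, p3/p4 unique
        real = pd.DataFrame(
            {"pid": ["p1", "p2", "p3", "p4"], "age": [30.0, 30.0, 60.0, 90.0]}
        )
        assert baseline_match_rate(real, MatchConfig("1", {"age": 0.0}), "pid") == 0.5
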