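"""Sharing calls, rates, relationship classification and networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strainshare.calibration import StrainThreshold
from strainshare.cohort import subject_table
from strainshare.phylo import SGBDistanceSet
from strainshare.sharing import (
    acquisition_rate,
    aggregate_subject_pairs,
    build_sharing_network,
    call_sharing_events,
    classify_pair,
    classify_pairs,
    collapse_to_subjects,
    flag_food_strains,
    rate_by_relationship,
    select_sgbs_for_profiling,
    sharing_rate,
)


def _thr(sgb, value):
    return StrainThreshold(
        sgb_id=sgb, threshold_ngd=value, method="youden", n_same_pairs=50,
        n_unrelated_pairs=500, fp_fraction=0.0, youden_j=1.0,
        unrelated_percentile=0.0,
    )


def _dset(sgb, leaves, ngd):
    return SGBDistanceSet(sgb_id=sgb, leaves=leaves, ngd=np.asarray(ngd, float),
                          total_branch_length=1.0)


class TestProfileSelection:
    def test_boundary_and_any_dataset_rule(self):
        detection = pd.DataFrame(
            [
                ("S1", "D1", 20),   # 20/100: both criteria exactly met
                ("S2", "D1", 19),   # 19/100: fails count
                ("S3", "D1", 25),   # 25/300 in D1 = 8.3% fails fraction...
                ("S3", "D2", 30),   # ...but 30/100 in D2 passes
                ("S4", "D2", 9),
            ],
            columns=["sgb_id", "dataset_id", "n_detected"],
        )
        sizes = {"D1": 100, "D2": 100}
        sizes_s3 = {"D1": 300, "D2": 100}
        assert select_sgbs_for_profiling(
            detection[detection["sgb_id"] != "S3"], sizes
        ) == ["S1"]
        assert "S3" in select_sgbs_for_profiling(detection, sizes_s3)

    def test_unknown_dataset_rejected(self):
        detection = pd.DataFrame(
            [("S1", "DX", 20)], columns=["sgb_id", "dataset_id", "n_detected"]
        )
        with pytest.raises(ValueError, match="unknown datasets"):
            select_sgbs_for_profiling(detection, {"D1": 100})


class TestFoodFilter:
    def _snv(self, rows):
        return pd.DataFrame(rows, columns=["id_a", "id_b", "snv_rate"])

    def test_inclusive_boundary(self):
        snv = self._snv([("s1", "F1", 0.0015), ("s2", "F1", 0.002)])
        assert flag_food_strains(snv, ["F1"]) == {"s1"}

    def test_minimum_over_references(self):
        snv = self._snv(
            [("s1", "F1", 0.01), ("s1", "F2", 0.001), ("s2", "F1", 0.01),
             ("s2", "F2", 0.02)]
        )
        assert flag_food_strains(snv, ["F1", "F2"]) == {"s1"}

    def test_no_food_refs_excludes_nothing(self):
        snv = self._snv([("s1", "F1", 0.0001)])
        assert flag_food_strains(snv, []) == set()
        assert flag_food_strains(None, ["F1"]) == set()

    def test_planted_food_strains_recovered(self, suite):
        """Every sample planted as food-origin (and only those) is flagged."""
        truth, snv = suite["truth"], suite["snv"]
        any_food = False
        for dset in suite["dsets"]:
            refs = truth.food_refs[dset.sgb_id]
            if not refs:
                continue
            sub = snv[snv["sgb_id"] == dset.sgb_id][["id_a", "id_b", "snv_rate"]]
            flagged = flag_food_strains(sub, refs)
            assert flagged == truth.food_samples[dset.sgb_id]
            any_food = any_food or bool(flagged)
        assert any_food  # the default suite plants at least one food strain


class TestSharingCalls:
    def test_identity_and_inclusive_boundary(self):
        ngd = [[0.0, 0.0, 0.1], [0.0, 0.0, 0.3], [0.1, 0.3, 0.0]]
        dset = _dset("A", ["x", "y", "z"], ngd)
        calls = call_sharing_events(dset, _thr("A", 0.1))
        lookup = {
            (a, b): s
            for a, b, s in zip(calls["sample_a"], calls["sample_b"], calls["shared"])
        }
        assert lookup[("x", "y")]  # nGD 0 with positive threshold
        assert lookup[("x", "z")]  # nGD == threshold, inclusive rule
        assert not lookup[("y", "z")]
        strict = call_sharing_events(dset, _thr("A", 0.1), strict=True)
        assert strict["shared"].sum() == 1

    def test_event_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        n = 40
        mat = rng.uniform(0, 1, size=(n, n))
        ngd = (mat + mat.T) / 2
        np.fill_diagonal(ngd, 0)
        dset = _dset("A", [f"s{i}" for i in range(n)], ngd)
        counts = [
            call_sharing_events(dset, _thr("A", t))["shared"].sum()
            for t in np.linspace(0, 1, 21)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_sgb_mismatch_rejected(self):
        dset = _dset("A", ["x", "y"], [[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError, match="applied to"):
            call_sharing_events(dset, _thr("B", 0.1))

    def test_excluded_samples_form_no_pairs(self):
        dset = _dset("A", ["x", "y", "z"], np.zeros((3, 3)))
        calls = call_sharing_events(dset, _thr("A", 0.1), excluded={"z"})
        assert set(calls["sample_a"]) | set(calls["sample_b"]) == {"x", "y"}


class TestCollapse:
    def test_any_time_point_rule(self):
        calls = pd.DataFrame(
            {
                "sgb_id": "A",
                "sample_a": ["a1", "a2"],
                "sample_b": ["b1", "b1"],
                "ngd": [0.5, 0.001],
                "shared": [False, True],
            }
        )
        out = collapse_to_subjects(calls, {"a1": "A", "a2": "A", "b1": "B"})
        assert len(out) == 1
        assert bool(out["shared"].iloc[0])
        assert out["min_ngd"].iloc[0] == pytest.approx(0.001)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(12)]
        mapping = {s: f"subj{i % 5}" for i, s in enumerate(samples)}
        rows = []
        for i in range(12):
            for j in range(i + 1, 12):
                v = rng.uniform(0, 1)
                rows.append(("A", samples[i], samples[j], v, v < 0.3))
        calls = pd.DataFrame(
            rows, columns=["sgb_id", "sample_a", "sample_b", "ngd", "shared"]
        )
        base = collapse_to_subjects(calls, mapping)
        perm = collapse_to_subjects(
            calls.sample(frac=1.0, random_state=1).reset_index(drop=True), mapping
        )
        pd.testing.assert_frame_equal(base, perm)

    def test_unmapped_sample_rejected(self):
        calls = pd.DataFrame(
            {"sgb_id": ["A"], "sample_a": ["x"], "sample_b": ["y"],
             "ngd": [0.1], "shared": [True]}
        )
        with pytest.raises(ValueError, match="not mapped"):
            collapse_to_subjects(calls, {"x": "X"})


class TestRates:
    def _counts(self, strains, sgbs):
        return pd.DataFrame(
            {
                "subject_a": ["A"],
                "subject_b": ["B"],
                "n_shared_sgbs": [sgbs],
                "n_shared_strains": [strains],
            }
        )

    @pytest.mark.parametrize(
        "strains,sgbs,expected",
        [(5, 20, 25.0), (0, 15, 0.0), (3, 9, None)],
    )
    def test_rate_and_minimum_gate(self, strains, sgbs, expected):
        out = sharing_rate(self._counts(strains, sgbs))
        v = out["sharing_rate_pct"].iloc[0]
        if expected is None:
            assert pd.isna(v)
        else:
            assert v == pytest.approx(expected)

    def test_rate_bounds_on_suite(self, suite):
        summ = suite["result"]["share"]["pair_summaries"]
        rates = summ["sharing_rate_pct"].dropna()
        assert ((rates >= 0) & (rates <= 100)).all()
        assert (summ["n_shared_strains"] <= summ["n_shared_sgbs"]).all()


class TestAcquisition:
    def _fixture(self, n_off_sgbs, n_common, n_shared):
        profiles, calls = {}, {}
        for k in range(n_off_sgbs):
            sgb = f"S{k}"
            profs = {"kid"}
            if k < n_common:
                profs.add("mom")
            profiles[sgb] = profs
            calls[sgb] = pd.DataFrame(
                {
                    "sgb_id": [sgb],
                    "subject_a": ["kid"],
                    "subject_b": ["mom"],
                    "shared": [k < n_shared],
                    "min_ngd": [0.0],
                }
            )
        return calls, profiles

    def test_proportion_of_offspring_strains(self):
        calls, profiles = self._fixture(20, 15, 4)
        assert acquisition_rate("kid", "mom", calls, profiles) == pytest.approx(0.2)

    def test_all_strains_shared(self):
        calls, profiles = self._fixture(12, 12, 12)
        assert acquisition_rate("kid", "mom", calls, profiles) == pytest.approx(1.0)

    def test_below_minimum_common_sgbs_missing(self):
        calls, profiles = self._fixture(20, 9, 4)
        assert acquisition_rate("kid", "mom", calls, profiles) is None

    def test_no_profiles_missing(self):
        assert acquisition_rate("kid", "mom", {}, {}) is None


class TestClassification:
    def test_known_relationships(self, small_cohort):
        subjects = subject_table(small_cohort)
        assert classify_pair("kid1", "mom1", subjects) == ("mother_offspring", "<=1y")
        assert classify_pair("kid1", "dad1", subjects) == ("father_offspring", "<=1y")
        assert classify_pair("mom1", "dad1", subjects) == ("partners", None)
        assert classify_pair("mom1", "solo", subjects)[0] == "same_village"
        assert classify_pair("mom1", "far", subjects)[0] == "same_population"
        assert classify_pair("mom1", "ext", subjects)[0] == "inter_population"
        with pytest.raises(ValueError, match="unknown subject"):
            classify_pair("mom1", "ghost", subjects)

    def test_twins_and_siblings(self, small_cohort):
        extra = small_cohort.copy()
        for sid, age in (("kid2", 0.5), ("kid3", 7.0)):
            extra.loc[len(extra)] = [
                f"{sid}_t0", sid, "D1", "gut", 5, age, "H1", "V1",
                "mom1", "dad1", True,
            ]
        subjects = subject_table(extra)
        assert classify_pair("kid1", "kid2", subjects) == ("twins", None)
        assert classify_pair("kid1", "kid3", subjects) == ("siblings", None)

    def test_household_without_kinship(self):
        rows = pd.DataFrame(
            {
                "sample_id": ["a0", "b0"],
                "subject_id": ["a", "b"],
                "dataset_id": "D1",
                "body_site": "gut",
                "collection_day": [0, 0],
                "age_years": [30.0, 40.0],
                "household_id": "H1",
                "village_id": "V1",
                "mother_id": [None, None],
                "father_id": [None, None],
                "westernized": True,
            }
        )
        assert classify_pair("a", "b", subject_table(rows)) == ("household", None)

    def test_vectorized_agrees_with_scalar(self, small_cohort):
        subjects = subject_table(small_cohort)
        table = classify_pairs(subjects)
        for row in table.itertuples(index=False):
            cat, bin_ = classify_pair(row.subject_a, row.subject_b, subjects)
            assert cat == row.category
            assert bin_ == row.offspring_age_bin

    def test_vectorized_agrees_with_scalar_on_random_cohort(self, suite):
        subjects = subject_table(suite["cohort"])
        table = classify_pairs(subjects)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(table), size=60, replace=False)
        for row in table.iloc[idx].itertuples(index=False):
            cat, bin_ = classify_pair(row.subject_a, row.subject_b, subjects)
            assert cat == row.category
            assert bin_ == row.offspring_age_bin


class TestGroupedRates:
    def _summ(self, cat_rates):
        rows = []
        for cat, rates in cat_rates.items():
            for r in rates:
                rows.append(
                    {
                        "subject_a": "a",
                        "subject_b": "b",
                        "category": cat,
                        "sharing_rate_pct": r,
                        "n_shared_strains": 0 if r == 0 else 3,
                        "n_shared_sgbs": 12,
                    }
                )
        return pd.DataFrame(rows)

    def test_median_and_zero_fraction(self):
        out = rate_by_relationship(self._summ({"household": [0.0, 25.0, 50.0]}))
        row = out.iloc[0]
        assert row["median_rate_pct"] == pytest.approx(25.0)
        assert row["zero_sharing_pct"] == pytest.approx(100 / 3)

    def test_all_zero_category(self):
        out = rate_by_relationship(self._summ({"inter_population": [0.0, 0.0]}))
        row = out.iloc[0]
        assert row["median_rate_pct"] == 0.0
        assert row["zero_sharing_pct"] == 100.0

    def test_unplanted_interpopulation_sharing_is_zero(self, suite):
        """No sharing is planted across populations, so the inter-population
        median sharing rate is 0."""
        grouped = suite["result"]["share"]["grouped_rates"]
        row = grouped[grouped["category"] == "inter_population"]
        assert row["median_rate_pct"].iloc[0] == 0.0


class TestNetwork:
    def _counts(self):
        return pd.DataFrame(
            {
                "subject_a": ["A", "A", "B"],
                "subject_b": ["B", "C", "C"],
                "n_shared_sgbs": [60, 40, 55],
                "n_shared_strains": [5, 4, 12],
            }
        )

    def test_strain_edge_threshold(self):
        edges = build_sharing_network(self._counts(), min_shared_strains=5)
        assert list(map(tuple, edges[["subject_a", "subject_b"]].values)) == [
            ("A", "B"),
            ("B", "C"),
        ]

    def test_species_variant(self):
        edges = build_sharing_network(self._counts(), 50, kind="species")
        assert set(map(tuple, edges[["subject_a", "subject_b"]].values)) == {
            ("A", "B"),
            ("B", "C"),
        }

    def test_no_self_loops_and_deterministic_order(self, suite):
        edges = suite["result"]["share"]["network"]
        assert (edges["subject_a"] != edges["subject_b"]).all()
        assert (edges["subject_a"] < edges["subject_b"]).all()
        resorted = edges.sort_values(["subject_a", "subject_b"], ignore_index=True)
        pd.testing.assert_frame_equal(edges, resorted)


class TestFoodExclusionMonotone:
    def test_excluding_food_never_increases_sharing(self, suite):
        """Recomputing subject-pair counts without the food filter can only
        raise (never lower) every pair's shared-strain count."""
        from strainshare.sharing import call_sharing_events as call

        res = suite["result"]
        cohort = suite["cohort"]
        s2s = dict(zip(cohort["sample_id"], cohort["subject_id"]))
        thr = {t.sgb_id: t for t in res["thresholds"]}
        unfiltered = {}
        for dset in suite["dsets"]:
            if dset.sgb_id not in thr:
                continue
            calls = call(dset, thr[dset.sgb_id], sample_ids=set(s2s))
            unfiltered[dset.sgb_id] = collapse_to_subjects(calls, s2s)
        base = aggregate_subject_pairs(res["share"]["per_sgb_calls"])
        free = aggregate_subject_pairs(unfiltered)
        merged = base.merge(
            free, on=["subject_a", "subject_b"], how="left", suffixes=("", "_free")
        )
        assert (
            merged["n_shared_strains"] <= merged["n_shared_strains_free"]
        ).all()
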