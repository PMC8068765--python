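"""Union combinations: enumeration, scoring, winner selection, tallies."""

import math

import numpy as np
import pandas as pd
import pytest

import snvbench as sb
from conftest import brute_combination_scores, make_callset


class TestEnumerate:
    @pytest.mark.parametrize(
        "n,max_size,expected",
        [(3, None, 7), (12, None, 4095), (12, 2, 78), (4, 1, 4), (2, 5, 3)],
    )
    def test_counts(self, n, max_size, expected):
        pipelines = [f"P{i:02d}" for i in range(n)]
        combos = list(sb.enumerate_combinations(pipelines, max_size))
        assert len(combos) == expected
        assert len({c.id for c in combos}) == expected  # each exactly once

    def test_deterministic_order_by_size_then_id(self):
        combos = list(sb.enumerate_combinations(["B", "A", "C"]))
        ids = [c.id for c in combos]
        assert ids == ["A", "B", "C", "A+B", "A+C", "B+C", "A+B+C"]

    def test_canonical_id_is_order_independent(self):
        assert sb.Combination(frozenset({"A", "B"})).id == sb.Combination(frozenset({"B", "A"})).id

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            list(sb.enumerate_combinations([], None))
        with pytest.raises(ValueError):
            list(sb.enumerate_combinations(["A"], 0))


class TestUnionCallset:
    def test_simple_union(self):
        cs = {
            "Bwa_Mutect2": make_callset("Bwa_Mutect2", "S1", [("chr1", 1, "A", "T"), ("chr1", 2, "C", "G")]),
            "Bwa_Varscan": make_callset("Bwa_Varscan", "S1", [("chr1", 2, "C", "G"), ("chr1", 3, "G", "A")]),
        }
        u = sb.union_callset(cs, ["Bwa_Mutect2", "Bwa_Varscan"])
        assert len(u) == 3
        assert u.pipeline_id == "Bwa_Mutect2+Bwa_Varscan"

    def test_self_union_is_identity(self):
        cs = {"Bwa_Mutect2": make_callset("Bwa_Mutect2", "S1", [("chr1", 1, "A", "T")])}
        u = sb.union_callset(cs, ["Bwa_Mutect2"])
        assert u.keys() == cs["Bwa_Mutect2"].keys()

    def test_metadata_from_deepest_member(self):
        k = ("chr1", 1, "A", "T")
        shallow = sb.CallSet("Bwa_Mutect2", "S1", "monoclone",
                             [sb.CallRecord(sb.VariantKey(*k), depth=20, alt_reads=4, vaf=0.2)])
        deep = sb.CallSet("Bwa_Varscan", "S1", "monoclone",
                          [sb.CallRecord(sb.VariantKey(*k), depth=90, alt_reads=30, vaf=1 / 3)])
        u = sb.union_callset({"Bwa_Mutect2": shallow, "Bwa_Varscan": deep},
                             ["Bwa_Mutect2", "Bwa_Varscan"])
        assert u.records[0].depth == 90

    def test_missing_member_named(self):
        cs = {"Bwa_Mutect2": make_callset("Bwa_Mutect2", "S1", [])}
        with pytest.raises(ValueError, match="Bwa_Varscan"):
            sb.union_callset(cs, ["Bwa_Mutect2", "Bwa_Varscan"])

    def test_union_of_all_pipelines_matches_index_support(self, small_study_eval):
        filtered, index, _ = small_study_eval
        sid = "Mono-1"
        sample_cs = {pid: cs for (pid, s), cs in filtered.items() if s == sid}
        u = sb.union_callset(sample_cs, list(sample_cs))
        from_index = {v for v, dets in index.detections.items() if any(s == sid for _, s in dets)}
        assert u.keys() == from_index


class TestScoreCombinations:
    def _toy(self):
        callsets = {
            "Bwa_Mutect2": make_callset("Bwa_Mutect2", "S1", [("chr1", 1, "A", "T"), ("chr1", 2, "C", "G")]),
            "Bwa_Varscan": make_callset("Bwa_Varscan", "S1", [("chr1", 2, "C", "G"), ("chr1", 3, "G", "A")]),
            "Novoalign_Strelka2": make_callset("Novoalign_Strelka2", "S1", [("chr1", 4, "T", "C")]),
        }
        # second sample replicates variants 1,2 so they validate
        others = [
            make_callset("Bwa_Mutect2", "S2", [("chr1", 1, "A", "T"), ("chr1", 2, "C", "G")]),
        ]
        index = sb.build_index(list(callsets.values()) + others)
        validated = sb.validate(index)
        return callsets, index, validated

    def test_matches_brute_force_exactly(self):
        callsets, index, validated = self._toy()
        res = sb.score_combinations(callsets, validated, index)
        in_sample = sb.validated_in_sample(validated, index, "S1")
        brute = brute_combination_scores(callsets, set(validated.validated), in_sample)
        assert len(res) == 7
        for _, row in res.iterrows():
            tp, fp, fn, f1 = brute[row["combination_id"]]
            assert (row["tp"], row["fp"], row["fn"]) == (tp, fp, fn)
            if f1 is None:
                assert math.isnan(row["f1"])
            else:
                assert row["f1"] == pytest.approx(f1)

    def test_brute_force_agreement_on_simulation(self, small_study_eval):
        """6-pipeline subset of a simulated sample vs explicit set algebra."""
        filtered, index, validated = small_study_eval
        sid = "InVivoPoly-1"
        pipelines = sorted({pid for (pid, s) in filtered if s == sid})[:6]
        sample_cs = {pid: filtered[(pid, sid)] for pid in pipelines}
        res = sb.score_combinations(sample_cs, validated, index)
        in_sample = sb.validated_in_sample(validated, index, sid)
        brute = brute_combination_scores(sample_cs, set(validated.validated), in_sample)
        assert len(res) == 63
        for _, row in res.iterrows():
            assert (row["tp"], row["fp"], row["fn"]) == brute[row["combination_id"]][:3]

    def test_global_fn_scope(self):
        callsets, index, validated = self._toy()
        res = sb.score_combinations(callsets, validated, index, fn_scope="global")
        full = res[res["size"] == 3].iloc[0]
        assert full["fn"] == len(validated) - full["tp"]

    def test_mixed_samples_rejected(self):
        callsets = {
            "Bwa_Mutect2": make_callset("Bwa_Mutect2", "S1", []),
            "Bwa_Varscan": make_callset("Bwa_Varscan", "S2", []),
        }
        index = sb.build_index(callsets.values())
        with pytest.raises(ValueError, match="multiple samples"):
            sb.score_combinations(callsets, sb.validate(index, min_samples=1), index)


class TestBestPerSample:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["combination_id", "size", "tp", "fp", "fn", "precision", "recall", "f1"]
        )

    def test_argmax(self):
        res = self._results([("A", 1, 1, 1, 1, 0.5, 0.5, 0.5), ("B", 1, 2, 1, 0, 0.7, 0.7, 0.7)])
        best = sb.best_per_sample(res)
        assert best.iloc[0]["combination_id"] == "B"

    def test_tie_prefers_smaller_then_lexicographic(self):
        res = self._results(
            [
                ("A+B+C", 3, 2, 0, 2, 1.0, 0.5, 0.5),
                ("A+B", 2, 2, 0, 2, 1.0, 0.5, 0.5),
                ("A+C", 2, 2, 0, 2, 1.0, 0.5, 0.5),
            ]
        )
        best = sb.best_per_sample(res)
        assert best.iloc[0]["combination_id"] == "A+B"

    def test_by_size_winners(self):
        res = self._results(
            [
                ("A", 1, 1, 0, 3, 1.0, 0.25, 0.4),
                ("B", 1, 2, 2, 2, 0.5, 0.5, 0.5),
                ("A+B", 2, 3, 2, 1, 0.6, 0.75, 0.667),
            ]
        )
        best = sb.best_per_sample(res, by_size=True)
        assert list(best["scope"]) == ["overall", "size_1", "size_2"]
        assert best[best["scope"] == "size_1"]["combination_id"].iloc[0] == "B"

    def test_all_f1_missing_gives_empty(self):
        res = self._results([("A", 1, 0, 0, 0, np.nan, np.nan, np.nan)])
        assert sb.best_per_sample(res).empty

    def test_matches_brute_force_argmax(self, small_study_eval):
        filtered, index, validated = small_study_eval
        sid = "Mono-2"
        pipelines = sorted({pid for (pid, s) in filtered if s == sid})[:5]
        sample_cs = {pid: filtered[(pid, sid)] for pid in pipelines}
        res = sb.score_combinations(sample_cs, validated, index)
        best = sb.best_per_sample(res)
        in_sample = sb.validated_in_sample(validated, index, sid)
        brute = brute_combination_scores(sample_cs, set(validated.validated), in_sample)
        best_f1 = max(v[3] for v in brute.values() if v[3] is not None)
        assert best.iloc[0]["f1"] == pytest.approx(best_f1)
        assert brute[best.iloc[0]["combination_id"]][3] == pytest.approx(best_f1)


class TestTallyAndDistribution:
    def test_tally_counts_and_conservation(self):
        winners = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S1", "S2", "S3"],
                "combination_id": ["A+B", "A+B", "A+B", "A", "A", "C"],
                "size": [2, 2, 2, 1, 1, 1],
                "scope": ["size_2"] * 3 + ["size_1"] * 3,
                "f1": [0.7] * 6, "precision": [0.7] * 6, "recall": [0.7] * 6,
                "tp": [1] * 6, "fp": [1] * 6, "fn": [1] * 6,
            }
        )
        types = {"S1": "monoclone", "S2": "monoclone", "S3": "parental"}
        tab = sb.tally_winners(winners, types, sizes=(1, 2))
        top = tab.iloc[0]
        assert top["combination_id"] == "A+B" and top["total"] == 3
        type_cols = [c for c in tab.columns if c in ("monoclone", "parental")]
        assert (tab[type_cols].sum(axis=1) == tab["total"]).all()

    def test_engineered_complementary_pair_dominates(self):
        """Two pipelines with disjoint halves of the validated set win as a pair."""
        half1 = [("chr1", i + 1, "A", "T") for i in range(10)]
        half2 = [("chr1", i + 101, "C", "G") for i in range(10)]
        callsets = []
        for sid in ("S1", "S2", "S3"):
            callsets += [
                make_callset("Bwa_Mutect2", sid, half1),
                make_callset("Bowtie2_Varscan", sid, half2),
                make_callset("Novoalign_Strelka2", sid, half1[:3] + half2[:3]),
            ]
        index = sb.build_index(callsets)
        validated = sb.validate(index)
        winner_rows = []
        for sid in ("S1", "S2", "S3"):
            sample_cs = {cs.pipeline_id: cs for cs in callsets if cs.sample_id == sid}
            res = sb.score_combinations(sample_cs, validated, index)
            best = sb.best_per_sample(res, by_size=True)
            best.insert(0, "sample_id", sid)
            winner_rows.append(best)
        winners = pd.concat(winner_rows, ignore_index=True)
        tab = sb.tally_winners(winners, {s: "monoclone" for s in ("S1", "S2", "S3")}, sizes=(2,))
        assert tab.iloc[0]["combination_id"] == "Bowtie2_Varscan+Bwa_Mutect2"
        assert tab.iloc[0]["total"] == 3

    def test_f1_by_size_shape(self, small_study_eval):
        filtered, index, validated = small_study_eval
        results = {}
        for sid in ("Mono-1", "Mono-2"):
            sample_cs = {pid: filtered[(pid, s)] for (pid, s) in filtered if s == sid}
            results[sid] = sb.score_combinations(sample_cs, validated, index, max_size=3)
        dist = sb.f1_by_size(results)
        assert set(dist["size"]) == {1, 2, 3}
        assert set(dist["sample_id"]) == {"Mono-1", "Mono-2"}
        # best-per-size is the max over that size's combinations
        for (sid, k), grp in dist.groupby(["sample_id", "size"]):
            res = results[sid]
            assert grp["f1"].iloc[0] == pytest.approx(res[res["size"] == k]["f1"].max())


class TestUnionMonotonicity:
    def test_tp_fp_recall_monotone_under_member_addition(self, small_study_eval):
        """Adding a pipeline to a union never loses TPs, FPs, or recall."""
        filtered, index, validated = small_study_eval
        sid = "Parental-1"
        sample_cs = {pid: filtered[(pid, s)] for (pid, s) in filtered if s == sid}
        res = sb.score_combinations(sample_cs, validated, index)
        pipelines = sorted(sample_cs)
        by_id = res.set_index("combination_id")
        for cid, row in by_id.iterrows():
            members = cid.split("+")
            if len(members) == 1:
                continue
            for m in members:
                sub_id = "+".join(sorted(set(members) - {m}))
                sub = by_id.loc[sub_id]
                assert row["tp"] >= sub["tp"]
                assert row["fp"] >= sub["fp"]
                if not (math.isnan(row["recall"]) or math.isnan(sub["recall"])):
                    assert row["recall"] >= sub["recall"] - 1e-12
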