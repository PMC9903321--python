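import itertools
import random

import pytest
from pyteomics import mass as pyteomics_mass

from qcatdesign.digest import Peptide, tryptic_limit_digest
from qcatdesign.records import ProteinRecord
from qcatdesign.scoring import (
    DEFAULT_WEIGHTS,
    DISABLED,
    HIGH,
    LOW,
    NORMAL,
    VERY_HIGH,
    VERY_LOW,
    AdapterError,
    Grade,
    MetricResult,
    ProteomeIndex,
    RuleSpec,
    ScoreCard,
    WeightCategory,
    compare_subjects,
    elimination_chain,
    evaluate_rule,
    evidence_lookup,
    external_scorer_adapter,
    proteome_repeats,
    rank_and_select,
    register_adapter,
    repeat_within_submission,
    score_subject,
)

from conftest import AA20, random_sequence


def make_peptide(seq, flank_n="AAA", flank_c="AAA", start=10):
    return Peptide(
        sequence=seq,
        parent_accession="P",
        start=start,
        end=start + len(seq) - 1,
        flank_n=flank_n,
        flank_c=flank_c,
    )


class TestWeights:
    def test_default_tier_values(self):
        assert DEFAULT_WEIGHTS == {
            "DISABLED": 0,
            "VERY_LOW": 1,
            "LOW": 100,
            "NORMAL": 10_000,
            "HIGH": 1_000_000,
            "VERY_HIGH": 100_000_000,
        }

    def test_negative_override_rejected(self):
        with pytest.raises(ValueError):
            WeightCategory("LOW", -1)


class TestEvaluateRule:
    def test_zero_comparator_passes_on_zero(self):
        r = evaluate_rule(0, RuleSpec("m", "zero"))
        assert r.grade is Grade.PASS

    def test_missing_value_is_error_not_exception(self):
        r = evaluate_rule(None, RuleSpec("m", "<=", 2))
        assert r.grade is Grade.ERROR
        assert "missing" in r.detail

    def test_threshold_fail(self):
        assert evaluate_rule(3, RuleSpec("m", "<=", 2)).grade is Grade.FAIL

    def test_informational_always_info(self):
        assert evaluate_rule(3, RuleSpec("m", "<=", 2, informational=True)).grade is Grade.INFO

    def test_type_mismatch_is_error_with_detail(self):
        r = evaluate_rule("abc", RuleSpec("m", "<=", 2))
        assert r.grade is Grade.ERROR
        assert r.detail


class TestScoreSubject:
    def test_single_high_outscores_five_normal(self):
        high = [MetricResult("a", 1, Grade.PASS, HIGH)]
        normals = [MetricResult(f"m{i}", 1, Grade.PASS, NORMAL) for i in range(5)]
        assert score_subject(high) == 10**6
        assert score_subject(normals) == 5 * 10**4
        assert score_subject(high) > score_subject(normals)

    def test_all_fail_is_zero(self):
        results = [MetricResult("m", 1, Grade.FAIL, VERY_HIGH)]
        assert score_subject(results) == 0

    def test_disabled_pass_contributes_nothing(self):
        assert score_subject([MetricResult("m", 1, Grade.PASS, DISABLED)]) == 0

    def test_info_and_error_contribute_nothing(self):
        results = [
            MetricResult("a", 1, Grade.INFO, VERY_HIGH),
            MetricResult("b", None, Grade.ERROR, VERY_HIGH),
            MetricResult("c", 1, Grade.PASS, VERY_LOW),
        ]
        assert score_subject(results) == 1

    def test_dominance_one_pass_beats_99_at_all_lower_tiers(self):
        tiers = [VERY_LOW, LOW, NORMAL, HIGH, VERY_HIGH]
        for i, tier in enumerate(tiers[1:], start=1):
            single = [MetricResult("t", 1, Grade.PASS, tier)]
            many = [
                MetricResult(f"m{j}_{t.name}", 1, Grade.PASS, t)
                for t in tiers[:i]
                for j in range(99)
            ]
            assert score_subject(single) > score_subject(many)

    def test_points_invariant_to_column_order(self):
        results = [
            MetricResult("a", 1, Grade.PASS, HIGH),
            MetricResult("b", 0, Grade.FAIL, NORMAL),
            MetricResult("c", 1, Grade.PASS, LOW),
        ]
        for perm in itertools.permutations(results):
            assert score_subject(perm) == score_subject(results)

    def test_fail_to_pass_never_decreases_points(self):
        rng = random.Random(3)
        tiers = [DISABLED, VERY_LOW, LOW, NORMAL, HIGH, VERY_HIGH]
        for _ in range(50):
            results = [
                MetricResult(f"m{i}", 1, rng.choice([Grade.PASS, Grade.FAIL]),
                             rng.choice(tiers))
                for i in range(8)
            ]
            base = score_subject(results)
            flips = [
                r if r.grade is Grade.PASS
                else MetricResult(r.metric_name, r.value, Grade.PASS, r.weight)
                for r in results
            ]
            assert score_subject(flips) >= base


def oracle_elimination(seq, flank_n, flank_c, k=3):
    """Independent string-scanning oracle for the elimination chain."""
    def motif_count(motif):
        return sum(1 for i in range(len(seq)) if seq[i:i + len(motif)] == motif)

    counts = {
        "C_count": sum(1 for ch in seq if ch == "C"),
        "M_count": sum(1 for ch in seq if ch == "M"),
        "H_count": sum(1 for ch in seq if ch == "H"),
    }
    for m in ("NG", "DG", "DP", "KP", "RP"):
        counts[f"{m}_count"] = motif_count(m)
    counts["Q_start"] = seq[:1] == "Q"
    counts["KR_in_linker"] = any(ch in "KR" for ch in flank_n + flank_c)
    counts["complete_linker"] = len(flank_n) == k and len(flank_c) == k
    counts["violations"] = (
        sum(counts[key] for key in counts if key.endswith("_count"))
        + counts["Q_start"] + counts["KR_in_linker"] + (not counts["complete_linker"])
    )
    return counts


class TestEliminationChain:
    def test_worked_example(self):
        res = elimination_chain(make_peptide("QNGMCK"))
        assert res["Q_start"] is True
        assert res["NG_count"] == 1
        assert res["M_count"] == 1
        assert res["C_count"] == 1
        assert res["KR_in_linker"] is False
        assert res["violations"] == 4

    def test_clean_peptide_has_no_violations(self):
        res = elimination_chain(make_peptide("VILEDK", "TAS", "SQA"))
        assert all(res[f"{m}_count"] == 0 for m in ("NG", "DG", "DP", "KP", "RP"))
        assert res["violations"] == 0

    def test_kr_in_c_flank_is_flagged(self):
        assert elimination_chain(make_peptide("VILEDK", "AAA", "ELK"))["KR_in_linker"]

    def test_kp_rp_overlap_cases(self):
        res = elimination_chain(make_peptide("KPKPA"))
        assert res["KP_count"] == 2
        res = elimination_chain(make_peptide("RPRP"))
        assert res["RP_count"] == 2
        res = elimination_chain(make_peptide("DPGK"))
        assert res["DP_count"] == 1

    def test_matches_oracle_on_10000_random_peptides(self):
        rng = random.Random(614)
        for _ in range(10_000):
            seq = random_sequence(rng, 4, 30)
            flank_n = random_sequence(rng, 0, 3) if rng.random() > 0.2 else ""
            flank_c = random_sequence(rng, 0, 3) if rng.random() > 0.2 else ""
            got = elimination_chain(make_peptide(seq, flank_n, flank_c))
            want = oracle_elimination(seq, flank_n, flank_c)
            assert {k: int(v) for k, v in got.items()} == {
                k: int(v) for k, v in want.items()
            }


class TestRepeats:
    def test_within_submission_counts(self):
        peptides = [make_peptide(s, start=i * 50 + 1) for i, s in
                    enumerate(["AAK", "CCK", "AAK"])]
        scores = repeat_within_submission(peptides)
        assert scores[peptides[0]] == 2
        assert scores[peptides[1]] == 1

    def test_singleton_is_one(self):
        (p,) = [make_peptide("AAK")]
        assert repeat_within_submission([p]) == {p: 1}

    def test_duplicate_peptide_across_two_proteins(self):
        proteome = [
            ProteinRecord("A", "MMKELRTTT"),
            ProteinRecord("B", "GGGKELRCC"),
        ]
        pep = make_peptide("ELR")
        n_seq, n_mmi, dups = proteome_repeats(pep, proteome)
        assert n_seq == 2
        assert set(dups) == {"A", "B"}
        assert n_mmi >= 2

    def test_unique_peptide_floors_at_self_match(self):
        proteome = [ProteinRecord("A", "MMKWWWDDK")]
        n_seq, n_mmi, _ = proteome_repeats(make_peptide("WWWDDK"), proteome)
        assert n_seq == 1
        assert n_mmi >= 1

    def test_empty_proteome_is_an_error(self):
        with pytest.raises(ValueError):
            proteome_repeats(make_peptide("ELR"), [])

    def test_matches_quadratic_oracle(self, small_proteome):
        tol = 0.001
        index = ProteomeIndex(small_proteome)
        universe = [
            (pep.sequence, prot.accession)
            for prot in small_proteome
            for pep in tryptic_limit_digest(prot)
        ]
        rng = random.Random(11)
        probes = rng.sample(universe, 40)
        for seq, _ in probes:
            probe_mass = pyteomics_mass.calculate_mass(sequence=seq, monoisotopic=True)
            want_seq = sum(1 for s, _ in universe if s == seq)
            want_mmi = sum(
                1
                for s, _ in universe
                if abs(pyteomics_mass.calculate_mass(sequence=s, monoisotopic=True)
                       - probe_mass) <= tol + 1e-9
            )
            n_seq, n_mmi, _ = proteome_repeats(make_peptide(seq), index, tol)
            assert n_seq == want_seq
            assert n_mmi == want_mmi


class TestEvidence:
    def test_presence_and_absence(self):
        evidence = {"ELR", "VILEDK"}
        assert evidence_lookup(make_peptide("ELR"), evidence)
        assert not evidence_lookup(make_peptide("TTT"), evidence)

    def test_empty_list_flags_warning(self):
        with pytest.warns(UserWarning):
            assert not evidence_lookup(make_peptide("ELR"), set())


class TestRankAndSelect:
    def card(self, points_results, peptide):
        return ScoreCard("id", points_results, subject=peptide)

    def test_top_two_by_points(self):
        cards = [
            ScoreCard("a", [MetricResult("m", 1, Grade.PASS, HIGH)], make_peptide("AAK", start=5)),
            ScoreCard("b", [MetricResult("m", 1, Grade.PASS, NORMAL)], make_peptide("CCK", start=9)),
            ScoreCard("c", [], make_peptide("DDK", start=1)),
        ]
        top = rank_and_select(cards, n=2)
        assert [c.subject_id for c in top] == ["a", "b"]

    def test_tie_breaks_to_earlier_start(self):
        cards = [
            ScoreCard("late", [], make_peptide("AAK", start=50)),
            ScoreCard("early", [], make_peptide("CCK", start=2)),
        ]
        assert rank_and_select(cards, n=1)[0].subject_id == "early"

    def test_n_exceeding_candidates_warns_and_returns_all(self):
        cards = [ScoreCard("a", [], make_peptide("AAK"))]
        with pytest.warns(UserWarning):
            assert rank_and_select(cards, n=3) == cards


class TestAdapters:
    def test_unregistered_name_is_configuration_error(self):
        with pytest.raises(AdapterError):
            external_scorer_adapter("no_such_adapter", [make_peptide("ELR")])

    def test_mock_adapter_results_propagate(self):
        register_adapter("mock_fixed", lambda peps: {p.sequence: 0.9 for p in peps})
        results = external_scorer_adapter(
            "mock_fixed", [make_peptide("ELR")],
            rule=RuleSpec("mock_fixed", ">", 0.5, weight=NORMAL),
        )
        assert results[0].grade is Grade.PASS
        assert results[0].value == 0.9

    def test_adapter_exception_becomes_error_grade(self):
        def boom(peps):
            raise TimeoutError("service unreachable")

        register_adapter("mock_timeout", boom)
        results = external_scorer_adapter("mock_timeout", [make_peptide("ELR")])
        assert results[0].grade is Grade.ERROR
        assert "service unreachable" in results[0].detail

    def test_repeated_call_served_from_cache(self, tmp_path):
        calls = []

        def counting(peps):
            calls.append(len(peps))
            return {p.sequence: 1 for p in peps}

        register_adapter("mock_counting", counting)
        pep = make_peptide("ELR")
        for _ in range(3):
            external_scorer_adapter("mock_counting", [pep], cache_dir=tmp_path)
        assert calls == [1]


class TestPairwiseComparison:
    def test_metric_missing_on_either_side_is_skipped_for_both(self):
        a = ScoreCard("a", [
            MetricResult("m1", 1, Grade.PASS, HIGH),
            MetricResult("m2", 1, Grade.PASS, NORMAL),
        ])
        b = ScoreCard("b", [
            MetricResult("m1", None, Grade.ERROR, HIGH),
            MetricResult("m2", 0, Grade.FAIL, NORMAL),
        ])
        # m1 invalid on b, so only m2 counts: a passes it, b fails it
        assert compare_subjects(a, b) == NORMAL.value
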