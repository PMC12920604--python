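import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedsleep.evaluation import (
    AnnotationSpan,
    ConfusionMatrix,
    cohen_kappa,
    compute_metrics,
    confusion,
    recall_delta,
    round_half_up,
    span_coverage,
)
from pedsleep.matcher import Match


def lit(surface, start, end, cats=(("Snoring", 1),)):
    return Match(
        matched_text=surface, char_start=start, char_end=end,
        entry_surface=surface, categories=tuple(cats), kind="literal",
    )


class TestConfusion:
    def test_all_correct(self):
        preds = {"a": "positive", "b": "positive", "c": "positive",
                 "d": "negative", "e": "negative"}
        cm = confusion(preds, dict(preds))
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 2, 0, 0)

    def test_all_false_positive(self):
        preds = {k: "positive" for k in "abcd"}
        gold = {k: "negative" for k in "abcd"}
        cm = confusion(preds, gold)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 4, 0, 0)

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion({"a": "positive"}, {"b": "positive"})

    def test_random_case_against_independent_tally(self):
        rng = random.Random(42)
        ids = [f"n{i}" for i in range(20)]
        preds = {i: rng.choice(["positive", "negative"]) for i in ids}
        gold = {i: rng.choice(["positive", "negative"]) for i in ids}
        cm = confusion(preds, gold)
        # brute-force recount, cell by cell
        cells = {(p, g): sum(1 for i in ids if preds[i] == p and gold[i] == g)
                 for p in ("positive", "negative") for g in ("positive", "negative")}
        assert cm.tp == cells[("positive", "positive")]
        assert cm.fp == cells[("positive", "negative")]
        assert cm.fn == cells[("negative", "positive")]
        assert cm.tn == cells[("negative", "negative")]
        assert cm.n == 20


class TestMetrics:
    def test_published_dse_matrix(self):
        m = compute_metrics(ConfusionMatrix(tp=242, fp=42, fn=2, tn=14)).rounded()
        assert (m.precision, m.recall, m.f1) == (0.852, 0.992, 0.917)

    def test_published_sea_matrix(self):
        m = compute_metrics(ConfusionMatrix(tp=209, fp=35, fn=35, tn=21)).rounded()
        assert (m.precision, m.recall, m.f1) == (0.857, 0.857, 0.857)

    def test_no_positives_anywhere_all_undefined(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert m.precision is None and m.recall is None and m.f1 is None

    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionMatrix(tp=7, fp=0, fn=0, tn=3))
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_zero_tp_with_fp_and_fn(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=5, fn=5, tn=0))
        assert (m.precision, m.recall) == (0.0, 0.0)
        assert m.f1 is None  # precision + recall == 0

    @given(
        st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
        st.integers(0, 500),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_harmonic_mean_identity(self, tp, fp, fn, tn):
        m = compute_metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        if m.f1 is not None:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall)
            )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestRecallDelta:
    def test_published_vocabulary_comparison(self):
        dse = compute_metrics(ConfusionMatrix(tp=242, fp=42, fn=2, tn=14))
        sea = compute_metrics(ConfusionMatrix(tp=209, fp=35, fn=35, tn=21))
        assert recall_delta(dse, sea) == 13.5
        assert recall_delta(sea, dse) == -13.5  # antisymmetry

    def test_identical_metrics(self):
        m = compute_metrics(ConfusionMatrix(tp=5, fp=1, fn=1, tn=1))
        assert recall_delta(m, m) == 0.0

    def test_undefined_recall_rejected(self):
        ok = compute_metrics(ConfusionMatrix(tp=5, fp=1, fn=1, tn=1))
        bad = compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
        with pytest.raises(ValueError):
            recall_delta(ok, bad)


class TestRounding:
    @pytest.mark.parametrize(
        "x, d, expected",
        [(0.8525, 3, 0.853), (0.99180, 3, 0.992), (77.15, 1, 77.2), (0.5, 0, 1.0)],
    )
    def test_half_rounds_up(self, x, d, expected):
        assert round_half_up(x, d) == expected


class TestSpanCoverage:
    def test_hand_constructed_three_of_four(self):
        """4 annotations, exactly 3 embed a tier-1 keyword -> 75.0%."""
        matches = {
            "n1": [lit("snores", 10, 16)],
            "n2": [lit("melatonin", 0, 9, cats=(("Use of medication or supplements to aid sleep", 1),))],
            "n3": [],
            "n4": [lit("insomnia", 5, 13, cats=(("Insomnia", 1),))],
        }
        anns = [
            AnnotationSpan("n1", "sleep_behavior", 0, 30),
            AnnotationSpan("n2", "sleep_medication", 0, 20),
            AnnotationSpan("n3", "sleep_timing", 0, 15),
            AnnotationSpan("n4", "sleep_disorder", 0, 25),
        ]
        table = span_coverage(matches, anns)
        assert table.all_row.total_tags == 4
        assert table.all_row.tags_containing_keyword == 3
        assert table.all_row.percentage == 75.0

    def test_containment_is_strict_but_overlap_mode_credits(self):
        matches = {"n1": [lit("trouble sleeping", 5, 21)]}
        # annotation covers only part of the match
        ann = [AnnotationSpan("n1", "sleep_satisfaction", 0, 12)]
        strict = span_coverage(matches, ann)
        assert strict.all_row.tags_containing_keyword == 0
        loose = span_coverage(matches, ann, overlap="any-overlap")
        assert loose.all_row.tags_containing_keyword == 1

    def test_tier2_matches_do_not_count(self):
        matches = {"n1": [lit("wheezing", 0, 8, cats=(("Wheezing", 2),))]}
        ann = [AnnotationSpan("n1", "sleep_disorder", 0, 20)]
        table = span_coverage(matches, ann)
        assert table.all_row.tags_containing_keyword == 0

    def test_empty_dimension_has_undefined_percentage(self):
        table = span_coverage({"n1": []}, [AnnotationSpan("n1", "sleep_timing", 0, 5)])
        row = table.row("sleep_duration")
        assert row.total_tags == 0 and row.percentage is None

    def test_most_present_keyword_counts_annotations_not_occurrences(self):
        matches = {
            "n1": [lit("snores", 0, 6), lit("snores", 10, 16), lit("nap", 20, 23,
                   cats=(("Napping", 1),))],
            "n2": [lit("nap", 2, 5, cats=(("Napping", 1),))],
        }
        anns = [
            AnnotationSpan("n1", "sleep_behavior", 0, 30),
            AnnotationSpan("n2", "sleep_behavior", 0, 10),
        ]
        row = span_coverage(matches, anns).row("sleep_behavior")
        # "nap" is inside 2 annotations; "snores" inside 1 (twice)
        assert row.most_present_keyword == "nap"
        assert row.most_present_count == 2

    def test_tie_broken_lexicographically(self):
        matches = {"n1": [lit("nap", 0, 3, cats=(("Napping", 1),)),
                          lit("snores", 5, 11)]}
        anns = [AnnotationSpan("n1", "sleep_behavior", 0, 20)]
        row = span_coverage(matches, anns).row("sleep_behavior")
        assert row.most_present_keyword == "nap"

    def test_unknown_note_id_rejected(self):
        with pytest.raises(ValueError):
            span_coverage({}, [AnnotationSpan("ghost", "sleep_timing", 0, 5)])

    def test_monotone_under_added_tier1_match(self):
        matches = {"n1": [], "n2": [lit("snores", 0, 6)]}
        anns = [AnnotationSpan("n1", "sleep_behavior", 0, 10),
                AnnotationSpan("n2", "sleep_behavior", 0, 10)]
        before = span_coverage(matches, anns).all_row.percentage
        matches["n1"] = [lit("naps", 0, 4, cats=(("Napping", 1),))]
        after = span_coverage(matches, anns).all_row.percentage
        assert after >= before

    def test_all_row_totals_equal_column_sums(self):
        rng = random.Random(7)
        matches = {}
        anns = []
        from pedsleep.evaluation import DIMENSIONS
        for i in range(40):
            nid = f"n{i}"
            matches[nid] = [lit("snores", 2, 8)] if rng.random() < 0.6 else []
            anns.append(AnnotationSpan(nid, rng.choice(DIMENSIONS), 0, 12))
        table = span_coverage(matches, anns)
        dims = table.rows[:-1]
        assert sum(r.total_tags for r in dims) == table.all_row.total_tags
        assert (sum(r.tags_containing_keyword for r in dims)
                == table.all_row.tags_containing_keyword)


class TestCohenKappa:
    def test_identical_labelings(self):
        assert cohen_kappa(list("aabb"), list("aabb")) == 1.0

    def test_chance_level_agreement(self):
        assert cohen_kappa(["+", "+", "-", "-"], ["+", "-", "+", "-"]) == 0.0

    def test_constant_annotators(self):
        assert cohen_kappa(["x"] * 5, ["x"] * 5) == 1.0
        assert cohen_kappa(["x"] * 5, ["x"] * 4 + ["x"]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["a"], ["a", "b"])

    def test_against_sklearn_on_random_pairs(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = random.Random(99)
        for trial in range(10):
            a = [rng.choice("xyz") for _ in range(50)]
            b = [rng.choice("xyz") for _ in range(50)]
            ours = cohen_kappa(a, b)
            ref = sklearn_metrics.cohen_kappa_score(a, b)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_against_textbook_contingency_formula(self):
        rng = random.Random(3)
        a = [rng.choice(["pos", "neg"]) for _ in range(50)]
        b = [rng.choice(["pos", "neg"]) for _ in range(50)]
        n = 50
        labels = sorted(set(a) | set(b))
        table = {(x, y): sum(1 for u, v in zip(a, b) if (u, v) == (x, y))
                 for x in labels for y in labels}
        p_o = sum(table[(x, x)] for x in labels) / n
        p_e = sum(
            (sum(table[(x, y)] for y in labels) / n)
            * (sum(table[(y, x)] for y in labels) / n)
            for x in labels
        ) / 1.0
        expected = (p_o - p_e) / (1 - p_e)
        assert cohen_kappa(a, b) == pytest.approx(expected)


class TestAnnotationSpan:
    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSpan("n", "bogus_dimension", 0, 5)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSpan("n", "sleep_timing", 5, 5)
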