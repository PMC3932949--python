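import numpy as np
import pandas as pd
import pytest

from srnakit import annotate as ann


def _tag(seq, count=10, tid=None, lib="lib1"):
    return ann.ReadTag(tid or f"t_{seq[:8]}_{len(seq)}", seq, {lib: count})


class TestPreprocess:
    def test_length_and_abundance_filters(self):
        tags = [
            _tag("A" * 17, 10, "short"),
            _tag("ACGUACGUACGUACGUACGUACGUACGUACGUACGU", 10, "long"),  # 36 nt
            _tag("ACGUACGUACGUACGUAC", 2, "rare"),  # 18 nt, seen twice
            _tag("ACGUACGUACGUACGUACGUACGUACGUACGUACG", 3, "keep35"),  # 35 nt, 3x
            _tag("UGCAUGCAUGCAUGCAUGCA", 100, "keep20"),
        ]
        retained, report = ann.preprocess(tags)
        assert {t.id for t in retained} == {"keep35", "keep20"}
        assert report.n_length_filtered == 2
        assert report.n_abundance_filtered == 1
        assert report.n_retained == 2
        assert report.retained_counts == {"lib1": 103}

    def test_min_count_is_per_library_max(self):
        tag = ann.ReadTag("x", "ACGU" * 5, {"a": 1, "b": 3})
        retained, _ = ann.preprocess([tag])
        assert retained == [tag]

    def test_empty_input(self):
        retained, report = ann.preprocess([])
        assert retained == [] and report.n_input == 0


class TestSequenceIndex:
    REF = {"r1": "GGGGAAAACCCCUUUUGGGGAAAACCCC"}

    def test_exact_hit(self):
        hits = ann.SequenceIndex(self.REF).find("AAAACCCCUUUU")
        assert any(h.mismatches == 0 and h.strand == "+" for h in hits)

    def test_one_substitution(self):
        hits = ann.SequenceIndex(self.REF).find("AAAACGCCUUUU")
        assert hits and all(h.mismatches == 1 for h in hits)

    def test_two_substitutions_rejected(self):
        assert ann.SequenceIndex(self.REF).find("AAAACGCCUUGU") == []

    def test_reverse_strand_hit(self):
        # revcomp of r1[0:12] GGGGAAAACCCC -> GGGGUUUUCCCC
        hits = ann.SequenceIndex(self.REF).find("GGGGUUUUCCCC")
        assert any(h.strand == "-" and h.mismatches == 0 for h in hits)

    def test_multiple_positions_reported(self):
        hits = ann.SequenceIndex(self.REF).find("GGGGAAAACCCC")
        plus = [h for h in hits if h.strand == "+"]
        assert {h.start for h in plus} == {0, 16}

    def test_coordinates_half_open(self):
        (hit,) = [
            h for h in ann.SequenceIndex(self.REF).find("AAAACCCCUUUU") if h.strand == "+"
        ]
        assert self.REF["r1"][hit.start : hit.end] == "AAAACCCCUUUU"


def _references():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    trna_like_repeat = "GCAUUGGUGGUUCAGUGGUAGAAUUCUCGC"
    plain_repeat = "ACACACACACACACACACACACAC"
    pirna_in_repeat = "UGGCGCAAUUGGCCGGCGAUAACGGAGCAC"
    return {
        "miRNA": ann.ReferenceSet("miRNA", {"mir1": mirna + "GGGUUU"}),
        "ncRNA": ann.ReferenceSet(
            "ncRNA",
            {"rrna1": "CCGAUCGAUCGAUUCCGGAACCGGAACCGG"},
            classes={"rrna1": "rRNA"},
        ),
        "repeat": ann.ReferenceSet(
            "repeat",
            {
                "repA": plain_repeat + mirna,  # shares the miRNA sequence
                "repT": trna_like_repeat,
                "repP": pirna_in_repeat + plain_repeat,
            },
            classes={"repT": "tRNA"},
        ),
        "mRNA": ann.ReferenceSet("mRNA", {"m1": "AUGGCUAGCUAGCUAGCAUGCAUGCAUGGCAUGC"}),
        "piRNA": ann.ReferenceSet("piRNA", {"pi1": pirna_in_repeat}),
    }


class TestHierarchy:
    def test_mirna_beats_repeat(self):
        refs = _references()
        tag = _tag("UGAGGUAGUAGGUUGUAUAGUU", tid="q")
        (a,) = ann.hierarchical_annotate([tag], refs)
        assert a.category == "miRNA"

    def test_repeat_with_trna_class_is_recalled(self):
        refs = _references()
        tag = _tag("GCAUUGGUGGUUCAGUGGUAGA", tid="q")
        (a,) = ann.hierarchical_annotate([tag], refs)
        assert a.category == "tRNA" and a.recalled_ncRNA

    def test_repeat_pirna_rescue(self):
        refs = _references()
        tag = _tag("UGGCGCAAUUGGCCGGCGAUAACGGAGCAC", tid="q")
        (a,) = ann.hierarchical_annotate([tag], refs)
        assert a.category == "piRNA" and a.repeat_associated_piRNA

    def test_plain_repeat_stays_repeat(self):
        refs = _references()
        tag = _tag("ACACACACACACACACACACACAC"[:20], tid="q")
        (a,) = ann.hierarchical_annotate([tag], refs)
        assert a.category == "repeat" and not a.repeat_associated_piRNA

    def test_no_match_is_unclassified(self):
        refs = _references()
        tag = _tag("UUUAGAGCUAGAAAUAGCAAGUUAAAAU", tid="q")
        (a,) = ann.hierarchical_annotate([tag], refs)
        assert a.category == "unclassified" and a.n_positions == 0

    def test_deleting_mirna_reference_moves_tags_downstream(self):
        """Priority property: removing a level can only grow later categories."""
        refs = _references()
        tags = [
            _tag("UGAGGUAGUAGGUUGUAUAGUU", tid="q1"),
            _tag("GCAUUGGUGGUUCAGUGGUAGA", tid="q2"),
        ]
        with_mirna = ann.hierarchical_annotate(tags, refs)
        without = ann.hierarchical_annotate(
            tags, {k: v for k, v in refs.items() if k != "miRNA"}
        )
        counts_with = pd.Series([a.category for a in with_mirna]).value_counts()
        counts_without = pd.Series([a.category for a in without]).value_counts()
        for category in set(counts_with.index) | set(counts_without.index):
            if category != "miRNA":
                assert counts_without.get(category, 0) >= counts_with.get(category, 0)

    def test_fractional_counts_conserve_raw_count(self):
        refs = _references()
        tag = _tag("GGGGAAAACCCC", tid="q", count=9)
        refs["mRNA"] = ann.ReferenceSet(
            "mRNA", {"m1": "GGGGAAAACCCCUUGGGGAAAACCCC"}
        )
        (a,) = ann.hierarchical_annotate([tag], {"mRNA": refs["mRNA"]})
        frac = a.fractional_counts(tag.counts)
        assert a.n_positions >= 2
        assert frac["lib1"] * a.n_positions == pytest.approx(9)


class TestQuantifyMirnas:
    PRE = ann.PrecursorLocus("pre1", "chr1", 100, 180, "+")

    def _hits(self, spans):
        return {
            f"t{i}": [ann.TagHit("chr1", s, e, "+", 0)] for i, (s, e) in enumerate(spans)
        }

    def test_window_boundaries(self):
        tags = [
            ann.ReadTag("t0", "A" * 22, {"lib": 120}),
            ann.ReadTag("t1", "A" * 23, {"lib": 30}),
            ann.ReadTag("t2", "A" * 22, {"lib": 7}),
        ]
        hits = self._hits([(98, 120), (97, 120), (163, 185)])
        (group,) = ann.quantify_mirnas(tags, hits, [self.PRE])
        assert "t0" in group.member_tag_ids  # 98 >= 100 - 2
        assert "t1" not in group.member_tag_ids  # 97 < 98
        assert "t2" in group.member_tag_ids  # ends exactly at 180 + 5

    def test_most_abundant_isomir_is_expression(self):
        tags = [
            ann.ReadTag("t0", "A" * 22, {"lib": 120}),
            ann.ReadTag("t1", "A" * 21, {"lib": 30}),
            ann.ReadTag("t2", "A" * 23, {"lib": 7}),
        ]
        hits = self._hits([(100, 122), (101, 122), (100, 123)])
        (group,) = ann.quantify_mirnas(tags, hits, [self.PRE])
        assert group.expression["lib"] == 120
        assert group.representative == "t0"

    def test_minus_strand_window_mirrors(self):
        pre = ann.PrecursorLocus("pre2", "chr1", 100, 180, "-")
        tags = [ann.ReadTag("t0", "A" * 22, {"lib": 5})]
        # on '-', downstream extension is on the left: [start-5, end+2)
        hits = {"t0": [ann.TagHit("chr1", 95, 117, "-", 0)]}
        (group,) = ann.quantify_mirnas(tags, hits, [pre])
        assert group.member_tag_ids == ["t0"]

    def test_overlapping_precursors_count_tag_twice(self):
        pre_b = ann.PrecursorLocus("pre1b", "chr1", 110, 190, "+")
        tags = [ann.ReadTag("t0", "A" * 22, {"lib": 8})]
        hits = {"t0": [ann.TagHit("chr1", 120, 142, "+", 0)]}
        groups = ann.quantify_mirnas(tags, hits, [self.PRE, pre_b])
        assert all("t0" in g.member_tag_ids for g in groups)


class TestRPM:
    def test_simple_value(self):
        counts = pd.DataFrame({"lib": [5]}, index=["x"])
        rpm = ann.rpm_normalize(counts, {"lib": 2_000_000})
        assert rpm.loc["x", "lib"] == pytest.approx(2.5)

    def test_conservation_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"lib": rng.integers(1, 100, 50)})
        rpm = ann.rpm_normalize(counts, {"lib": counts["lib"].sum()})
        assert rpm["lib"].sum() == pytest.approx(1e6)

    def test_zero_count_and_zero_total(self):
        counts = pd.DataFrame({"lib": [0]})
        assert ann.rpm_normalize(counts, {"lib": 10}).iloc[0, 0] == 0.0
        with pytest.raises(ValueError):
            ann.rpm_normalize(counts, {"lib": 0})


class TestFixturePipeline:
    def test_category_conservation(self, annotated_fixture):
        """Per library: category totals + unclassified == retained totals, exactly."""
        retained, qc, assignments = annotated_fixture
        totals = ann.category_totals(retained, assignments)
        for lib, total in qc.retained_counts.items():
            assert int(totals[lib].sum()) == total

    def test_every_planted_read_recovers_its_category(
        self, pipeline_fixture, annotated_fixture
    ):
        retained, _, assignments = annotated_fixture
        truth = pipeline_fixture.truth
        wrong = [
            a for a in assignments if a.category != truth[a.tag_id]
        ]
        assert wrong == []

    def test_length_summary_modes(self, annotated_fixture):
        """Planted miRNA reads peak at 22 nt; piRNA reads near 28 nt."""
        retained, _, assignments = annotated_fixture
        summary = ann.length_category_summary(retained, assignments)
        pooled = summary.groupby(["category", "length"])["reads"].sum()
        assert pooled["miRNA"].idxmax() == 22
        assert pooled["piRNA"].idxmax() in (27, 28, 29)

    def test_proportions_sum_to_one(self, annotated_fixture):
        retained, _, assignments = annotated_fixture
        summary = ann.length_category_summary(retained, assignments)
        per_lib = summary.groupby("library")["reads"].sum()
        props = summary.groupby(["library", "category"])["reads"].sum() / per_lib
        assert np.allclose(props.groupby("library").sum(), 1.0)
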