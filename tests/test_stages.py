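"""Translation, segmentation and negation/exclusion fallbacks."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocuphen.stages import (
    ClinicalRecord,
    LexiconTranslationBackend,
    Segment,
    StageError,
    classify_segment,
    pathological_segments,
    segment,
    translate,
)


class TestTranslate:
    def test_english_record_is_identity(self):
        rec = ClinicalRecord("r1", anterior_text="Cornea clear", language="en")
        assert translate(rec) is rec

    def test_lexicon_phrase_substitution(self):
        rec = ClinicalRecord("r1", posterior_text="Amotio retinae", language="de")
        out = translate(rec)
        assert out.posterior_text == "retinal detachment"
        assert out.language == "en" and out.record_id == "r1"

    def test_unknown_tokens_pass_through_verbatim(self):
        backend = LexiconTranslationBackend({"kein": "no"})
        text = "kein Zykloplegie-Effekt sichtbar heute"
        out = translate(ClinicalRecord("r1", anterior_text=text, language="de"), backend)
        in_tokens = text.split()
        out_tokens = out.anterior_text.split()
        for token in in_tokens:
            if token != "kein":  # the only lexicon hit
                assert token in out_tokens

    def test_backend_failure_becomes_stage_error_with_record_id(self):
        class Boom:
            tag = "boom"

            def generate(self, prompt, text):
                raise RuntimeError("backend down")

        with pytest.raises(StageError, match="r7"):
            translate(ClinicalRecord("r7", anterior_text="x", language="de"), Boom())


class TestSegment:
    def test_empty_text_gives_empty_list(self):
        assert segment("", "anterior") == []

    def test_splits_on_commas_semicolons_and_keeps_order(self):
        segs = segment("Cornea clear, retinal detachment; Roth spot", "posterior", "r1")
        assert [s.text for s in segs] == ["Cornea clear", "retinal detachment", "Roth spot"]
        assert [s.ordinal for s in segs] == [0, 1, 2]
        assert all(s.scope == "posterior" and s.record_id == "r1" for s in segs)

    def test_commas_inside_parentheses_do_not_split(self):
        segs = segment("Pigment on endothelium (left, right); Roth spot", "anterior")
        assert [s.text for s in segs] == ["Pigment on endothelium (left, right)", "Roth spot"]

    def test_sentence_boundaries_and_newlines_split(self):
        segs = segment("Roth spot. Eyelash loss\nRed cataract", "anterior")
        assert [s.text for s in segs] == ["Roth spot", "Eyelash loss", "Red cataract"]

    @given(st.text(alphabet=st.characters(codec="latin-1"), max_size=120))
    @settings(derandomize=True)
    def test_alphanumerics_survive_in_order(self, text):
        # splitting only consumes delimiters and whitespace, never content
        joined = "".join(s.text for s in segment(text, "anterior"))
        assert [c for c in joined if c.isalnum()] == [c for c in text if c.isalnum()]


class TestClassify:
    @pytest.mark.parametrize(
        "text,status",
        [
            ("no retinal detachment", "negated"),
            ("kein Roth-Fleck", "negated"),
            ("macular hole ruled out", "negated"),
            ("Cornea clear", "normal"),
            ("Linse unauffällig", "normal"),
            ("Fundus within normal limits", "normal"),
            ("Roth spot", "pathological"),
            ("Choroidal nevus at the inferior vascular arcade", "pathological"),
            ("Absent Bell phenomenon", "pathological"),  # 'absent' is a finding here
            ("Lesion noted", "pathological"),  # 'no' must not fire inside 'noted'
        ],
    )
    def test_trigger_rules(self, text, status):
        seg = Segment("r1", "anterior", text, 0)
        assert classify_segment(seg).status == status

    def test_negation_beats_normal_marker(self):
        seg = Segment("r1", "anterior", "no clear view of the fundus", 0)
        assert classify_segment(seg).status == "negated"

    def test_custom_trigger_lists(self):
        seg = Segment("r1", "anterior", "Befund bland", 0)
        assert classify_segment(seg, markers=["bland"]).status == "normal"


class TestComposition:
    def test_fully_normal_record_yields_no_segments(self):
        rec = ClinicalRecord(
            "r1", anterior_text="Cornea clear; no Roth spot",
            posterior_text="Fundus within normal limits", language="en",
        )
        assert pathological_segments([rec]) == []

    def test_only_pathological_status_is_emitted(self):
        rec = ClinicalRecord(
            "r1",
            anterior_text="Eyelash loss; Cornea clear",
            posterior_text="Roth spot; no retinal detachment",
            language="en",
        )
        segs = pathological_segments([rec])
        assert [s.text for s in segs] == ["Eyelash loss", "Roth spot"]
        assert all(s.status == "pathological" for s in segs)

    def test_german_record_segments_are_translated_first(self):
        rec = ClinicalRecord("r1", posterior_text="Amotio retinae; Hornhaut klar", language="de")
        segs = pathological_segments([rec])
        assert [s.text for s in segs] == ["retinal detachment"]

    def test_record_order_invariance_up_to_grouping(self):
        records = [
            ClinicalRecord("a", anterior_text="Eyelash loss", language="en"),
            ClinicalRecord("b", posterior_text="Roth spot; Red cataract", language="en"),
            ClinicalRecord("c", anterior_text="Cornea clear", language="en"),
        ]
        forward = pathological_segments(records)
        backward = pathological_segments(records[::-1])
        key = lambda s: (s.record_id, s.scope, s.ordinal, s.text)
        assert sorted(forward, key=key) == sorted(backward, key=key)

    def test_failing_record_is_skipped_and_collected(self):
        class Boom:
            tag = "boom"

            def generate(self, prompt, text):
                raise RuntimeError("down")

        records = [
            ClinicalRecord("bad", anterior_text="Amotio retinae", language="de"),
            ClinicalRecord("good", anterior_text="Eyelash loss", language="en"),
        ]
        errors = []
        segs = pathological_segments(records, translation_backend=Boom(), errors=errors)
        assert [s.record_id for s in segs] == ["good"]
        assert len(errors) == 1 and errors[0].record_id == "bad"


class TestGenerationBackendParsing:
    def test_backend_segmentation_takes_one_segment_per_line(self):
        class OnePerLine:
            tag = "fake-llm"

            def generate(self, prompt, text):
                return "Roth spot\nEyelash loss\n"

        segs = segment("Roth spot and also Eyelash loss", "anterior", "r1", OnePerLine())
        assert [s.text for s in segs] == ["Roth spot", "Eyelash loss"]

    def test_backend_classification_parses_single_word_label(self):
        class SaysNegated:
            tag = "fake-llm"

            def generate(self, prompt, text):
                return " Negated.\n"

        seg = Segment("r1", "anterior", "whatever", 0)
        assert classify_segment(seg, SaysNegated()).status == "negated"

    def test_unparseable_backend_label_is_stage_error(self):
        class Gibberish:
            tag = "fake-llm"

            def generate(self, prompt, text):
                return "maybe?"

        with pytest.raises(StageError, match="classify"):
            classify_segment(Segment("r1", "anterior", "x", 0), Gibberish())
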