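import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carelex import (
    Category,
    Lexicon,
    WindowConfig,
    detect_visiting_nurse,
    expand_variants,
    match_terms,
    non_negated_institution_matches,
    segment_sentences,
    suppress_patient_terms_in_institution_sentences,
    tokenize,
    within_word_window,
)
from carelex.textmatch import Sentence


class TestSegmentation:
    @pytest.mark.parametrize(
        ("text", "n"),
        [
            ("pt called. sister present", 2),
            ("line one\nline two", 2),
            ("", 0),
            ("one! two? three.", 3),
            ("...\n\n", 0),  # only delimiters: everything dropped
        ],
    )
    def test_sentence_counts(self, text, n):
        assert len(segment_sentences(text)) == n

    def test_spans_ordered_nonoverlapping_and_indexed(self):
        text = "pt called. sister present\nwill follow up"
        sents = segment_sentences(text)
        assert [s.index for s in sents] == [0, 1, 2]
        for a, b in zip(sents, sents[1:]):
            assert a.char_span[1] <= b.char_span[0]
        for s in sents:
            lo, hi = s.char_span
            assert tokenize(text[lo:hi]) == list(s.tokens)


class TestTokenize:
    @pytest.mark.parametrize(
        ("text", "tokens"),
        [
            ("patient's dtr called", ["patient's", "dtr", "called"]),
            ("pt/ot", ["pt", "ot"]),
            ("", []),
            ("well-known (fact)!", ["well", "known", "fact"]),
            ("'quoted' word", ["quoted", "word"]),  # edge apostrophes stripped
        ],
    )
    def test_tokenization(self, text, tokens):
        assert tokenize(text) == tokens


class TestMatchTerms:
    def test_multitoken_institution_match(self, lex):
        sents = segment_sentences("transfer to glacier hills tomorrow")
        (m,) = match_terms(sents, lex, Category.INSTITUTION)
        assert m.term.surface == "glacier hills"
        assert m.token_span == (2, 4)

    def test_multiple_informal_matches_ordered(self, lex):
        sents = segment_sentences("her sister and daughter visited")
        matches = match_terms(sents, lex, Category.INFORMAL)
        assert [m.term.surface for m in matches] == ["sister", "daughter"]

    def test_no_terms_no_matches(self, lex):
        assert match_terms(segment_sentences("weather is fine"), lex, Category.INSTITUTION) == []

    def test_longest_match_wins(self):
        lex = Lexicon()
        lex.add("home", Category.FORMAL)
        lex.add("home care", Category.FORMAL)
        sents = segment_sentences("needs home care order")
        (m,) = match_terms(sents, lex, Category.FORMAL)
        assert m.term.surface == "home care"

    @settings(max_examples=150, derandomize=True)
    @given(
        tokens=st.lists(st.sampled_from("a b c d e".split()), max_size=50),
        surfaces=st.sets(
            st.lists(st.sampled_from("a b c d e".split()), min_size=1, max_size=3).map(" ".join),
            min_size=1,
            max_size=6,
        ),
    )
    def test_equals_brute_force_ngram_scan(self, tokens, surfaces):
        lex = Lexicon()
        for s in surfaces:
            lex.add(s, Category.INSTITUTION)
        sent = Sentence(index=0, tokens=tuple(tokens), char_span=(0, 0))
        got = [
            (m.term.surface, m.token_span)
            for m in match_terms([sent], lex, Category.INSTITUTION)
        ]
        # oracle: left-to-right scan, longest candidate at each position wins
        # and consumes its tokens
        term_tokens = sorted((s.split() for s in surfaces), key=len, reverse=True)
        expected = []
        i = 0
        while i < len(tokens):
            for cand in term_tokens:
                if tokens[i : i + len(cand)] == cand:
                    expected.append((" ".join(cand), (i, i + len(cand))))
                    i += len(cand) - 1
                    break
            i += 1
        assert got == expected


class TestWordWindow:
    @pytest.fixture
    def sent(self):
        return Sentence(index=0, tokens=tuple("t" * 12 for _ in range(12)), char_span=(0, 0))

    @pytest.mark.parametrize(
        ("span_a", "span_b", "k", "expected"),
        [
            ((0, 1), (1, 2), 4, True),  # adjacent: gap 0
            ((0, 1), (5, 6), 4, True),  # gap exactly 4
            ((0, 1), (6, 7), 4, False),  # gap 5
            ((2, 4), (2, 3), 0, True),  # overlap: gap 0
            ((0, 1), (2, 3), 0, False),
        ],
    )
    def test_gap_boundary(self, sent, span_a, span_b, k, expected):
        assert within_word_window(sent, span_a, span_b, WindowConfig(k=k)) is expected

    @settings(max_examples=100, derandomize=True)
    @given(
        a0=st.integers(0, 10), aw=st.integers(1, 3),
        b0=st.integers(0, 10), bw=st.integers(1, 3),
        k=st.integers(0, 6),
    )
    def test_symmetric_in_spans(self, a0, aw, b0, bw, k):
        sent = Sentence(index=0, tokens=tuple(["x"] * 16), char_span=(0, 0))
        a, b = (a0, a0 + aw), (b0, b0 + bw)
        cfg = WindowConfig(k=k)
        assert within_word_window(sent, a, b, cfg) == within_word_window(sent, b, a, cfg)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(k=-1)


class TestExpandVariants:
    def test_visit_inflections(self):
        assert expand_variants("visit") == {"visit", "visits", "visited", "visiting"}

    @pytest.mark.parametrize(
        ("stem", "expected_member"),
        [
            ("discharged from", "discharging from"),
            ("discharged from", "discharges from"),
            ("return from", "returning from"),
            ("return from", "returned from"),
            ("rehab", "rehabilitation"),
            ("rehabilitation", "rehab"),
            ("waiting list", "wait list"),
            ("waiting list", "waitlist"),
            ("cancel", "cancelled"),
            ("decline", "declined"),
        ],
    )
    def test_named_variants_present(self, stem, expected_member):
        assert expected_member in expand_variants(stem)

    def test_stem_always_in_its_own_expansion(self):
        for stem in ("suggest", "approve", "waiting list", "discharged from"):
            assert stem in expand_variants(stem)


class TestVisitingNurse:
    @pytest.mark.parametrize(
        ("text", "expected"),
        [
            ("will have a visit nurse in the near future", True),
            ("nurse called. will visit tomorrow", True),  # variant in following sentence
            ("nurse to visit on monday", True),  # variant after, same sentence
            ("nurse called back", False),
            ("visiting the office today", False),  # no nurse token
            ("will visit friends. two days later. nurse called", False),  # not adjacent
        ],
    )
    def test_detection(self, text, expected):
        assert detect_visiting_nurse(segment_sentences(text)) is expected

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from(["visit", "visiting", "called", "home", "today"]), max_size=20))
    def test_never_fires_without_nurse_token(self, tokens):
        sents = segment_sentences(" ".join(tokens))
        assert detect_visiting_nurse(sents) is False


class TestInstitutionNegation:
    def test_negation_suppresses_term_note_wide(self, lex):
        sents = segment_sentences(
            "on the waiting list for glacier hills. glacier hills has availability"
        )
        assert non_negated_institution_matches(sents, lex) == []

    def test_unnegated_mention_survives(self, lex):
        sents = segment_sentences("glacier hills is her final choice")
        (m,) = non_negated_institution_matches(sents, lex)
        assert m.term.surface == "glacier hills"

    def test_suppression_is_per_term(self, lex):
        sents = segment_sentences("discharged from glacier hills. now at atria ann arbor")
        matches = non_negated_institution_matches(sents, lex)
        assert [m.term.surface for m in matches] == ["atria ann arbor"]

    def test_inflected_negation_variant_matches(self, lex):
        sents = segment_sentences("declined glacier hills placement")
        assert non_negated_institution_matches(sents, lex) == []

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(
                ["glacier", "hills", "waiting", "list", "pt", "at", "now", "rehab", "."]
            ),
            max_size=25,
        )
    )
    def test_output_subset_of_all_institution_matches(self, lex, tokens):
        sents = segment_sentences(" ".join(tokens))
        surviving = set(non_negated_institution_matches(sents, lex))
        everything = set(match_terms(sents, lex, Category.INSTITUTION))
        assert surviving <= everything


class TestSuppression:
    def test_patient_tokens_removed_in_institution_sentence(self, lex):
        sents = segment_sentences("pt is settled at glacier hills")
        surviving = non_negated_institution_matches(sents, lex)
        (out,) = suppress_patient_terms_in_institution_sentences(sents, surviving)
        assert "pt" not in out.tokens
        assert "glacier" in out.tokens

    def test_caregiver_bigram_removed(self, lex):
        sents = segment_sentences("care giver at linden square helps. caregiver at home")
        surviving = non_negated_institution_matches(sents, lex)
        out = suppress_patient_terms_in_institution_sentences(sents, surviving)
        assert out[0].tokens == ("at", "linden", "square", "helps")
        # second sentence names no institution: untouched
        assert out[1].tokens == sents[1].tokens
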