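"""The six element scorers: unique-type counting, the habitual-opener rule,
the ENP slot grammar, and the score cap."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litlang.lexicon import ELEMENTS, load_default_banks
from litlang.scorers import (
    ElementScore,
    MISLMicroScores,
    find_elaborated_noun_phrases,
    habitual_opener_exclusions,
    score_adverbs,
    score_bank_element,
    score_coordinating,
    score_enp,
    score_transcript,
)
from litlang.tagger import tag_transcript

HABITUAL_PASSAGE = (
    "i went to the store",
    "and then i bought groceries",
    "and then i went home",
    "and i put the groceries away",
)


# --- bank elements ---------------------------------------------------------

def test_bank_score_counts_types_not_tokens(make_ct, banks):
    ct = make_ct(
        "he cried because he fell",
        "because he was sad",
        "when he got up he smiled",
    )
    res = score_bank_element(ct, banks["subordinating_conjunction"])
    assert res.unique_count == 2  # because (twice) + when
    assert res.score == 2


def test_five_distinct_subordinators_cap_at_three(make_ct, banks):
    ct = make_ct("because when although since while")
    res = score_bank_element(ct, banks["subordinating_conjunction"])
    assert res.unique_count == 5
    assert res.score == 3


def test_empty_transcript_scores_zero_everywhere(make_ct, banks, tagger):
    result = score_transcript(make_ct(), banks, tagger)
    assert all(s.score == 0 for s in result.scores)
    assert result.total == 0


# --- habitual openers ------------------------------------------------------

def test_three_consecutive_openers_are_excluded(make_ct, banks):
    ct = make_ct(*HABITUAL_PASSAGE)
    bank = banks["coordinating_conjunction"]
    excl = habitual_opener_exclusions(ct, bank)
    assert excl == {(1, 0), (2, 0), (3, 0)}
    assert score_coordinating(ct, bank).score == 0


def test_two_consecutive_openers_are_not_a_run(make_ct, banks):
    ct = make_ct("and he ran", "and he fell", "then he got up")
    excl = habitual_opener_exclusions(ct, banks["coordinating_conjunction"])
    assert excl == set()
    assert score_coordinating(ct, banks["coordinating_conjunction"]).score == 1


def test_mid_utterance_conjunction_survives_inside_run(make_ct, banks):
    ct = make_ct("and he ran", "and he hid", "and he ran and jumped")
    bank = banks["coordinating_conjunction"]
    assert habitual_opener_exclusions(ct, bank) == {(0, 0), (1, 0), (2, 0)}
    assert score_coordinating(ct, bank).score == 1


def test_whole_run_mode_excludes_mid_utterance_occurrences(make_ct, banks):
    ct = make_ct("and he ran", "and he hid", "and he ran and jumped")
    bank = banks["coordinating_conjunction"]
    assert score_coordinating(ct, bank, opener_exclusion="whole_run").score == 0


def test_run_of_four_excludes_all_four(make_ct, banks):
    ct = make_ct("and a", "and b", "and c", "and d", "but he fell and ran")
    bank = banks["coordinating_conjunction"]
    excl = habitual_opener_exclusions(ct, bank)
    assert excl == {(0, 0), (1, 0), (2, 0), (3, 0)}
    # "but" and mid-utterance "and" still count
    assert score_coordinating(ct, bank).unique_count == 2


def test_different_openers_do_not_chain_into_one_run(make_ct, banks):
    ct = make_ct("and he ran", "and he hid", "but he fell", "but he cried")
    bank = banks["coordinating_conjunction"]
    assert habitual_opener_exclusions(ct, bank) == set()
    assert score_coordinating(ct, bank).unique_count == 2


def _brute_force_coordinating(ct, bank):
    """Independent re-derivation: enumerate all utterance-initial runs."""
    openers = [u.tokens[0] if u.tokens else None for u in ct.utterances]
    excluded = set()
    n = len(openers)
    for i in range(n):
        for j in range(i + 3, n + 1):
            word = openers[i]
            if word is None or word not in bank:
                continue
            if all(openers[k] == word for k in range(i, j)):
                excluded |= {(ct.utterances[k].index, 0) for k in range(i, j)}
    types = {
        tok
        for idx, pos, tok in ct.iter_tokens()
        if tok in bank and (idx, pos) not in excluded
    }
    return min(3, len(types))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(
            st.sampled_from(["and", "but", "or", "he", "ran", "dogs"]),
            min_size=1, max_size=4,
        ),
        min_size=1, max_size=6,
    )
)
def test_coordinating_agrees_with_brute_force_oracle(utts):
    from litlang.transcript_io import CleanTranscript, Utterance

    ct = CleanTranscript(
        "t",
        tuple(Utterance(i, tuple(u)) for i, u in enumerate(utts)),
    )
    banks = load_default_banks()
    bank = banks["coordinating_conjunction"]
    assert score_coordinating(ct, bank).score == _brute_force_coordinating(
        ct, bank
    )


# --- adverbs ---------------------------------------------------------------

def test_adverb_types_counted_once_and_capped(make_ct, tagger):
    ct = make_ct(
        "he ran quickly", "he ran quickly", "she walked slowly",
        "they left suddenly and quietly",
    )
    tagged = tag_transcript(ct.utterances, tagger)
    res = score_adverbs(tagged)
    assert res.unique_count == 4
    assert res.score == 3


def test_no_adverbs_scores_zero(make_ct, tagger):
    ct = make_ct("the dog ran")
    assert score_adverbs(tag_transcript(ct.utterances, tagger)).score == 0


# --- elaborated noun phrases ----------------------------------------------

@pytest.mark.parametrize(
    "utterance, expected_max",
    [
        ("the big green frog", 3),
        ("the big black dog", 3),
        ("frog", 0),
        ("a frog", 1),
        ("the big frog", 2),
        ("my two very big scary dogs", 5),
        ("dogs ran", 0),
    ],
)
def test_enp_modifier_counts(make_ct, tagger, utterance, expected_max):
    ct = make_ct(utterance)
    res = score_enp(tag_transcript(ct.utterances, tagger))
    assert res.unique_count == expected_max
    assert res.score == min(3, expected_max)


def test_ordering_violation_truncates_at_determiner(make_ct, tagger):
    ct = make_ct("silly the girl")
    matches = find_elaborated_noun_phrases(tag_transcript(ct.utterances, tagger))
    girl = [m for m in matches if m.noun == "girl"]
    assert len(girl) == 1
    assert girl[0].modifier_tokens == ("the",)  # never 2


def test_adverb_only_admitted_immediately_before_adjective(make_ct, tagger):
    # "very" modifies "big": counts; a bare adverb before a noun does not.
    ct = make_ct("the very big frog")
    res = score_enp(tag_transcript(ct.utterances, tagger))
    assert res.unique_count == 3
    ct2 = make_ct("he ran quickly home")  # RB directly before NN
    matches = find_elaborated_noun_phrases(tag_transcript(ct2.utterances, tagger))
    home = [m for m in matches if m.noun == "home"]
    assert home and home[0].modifier_count == 0


def test_rightmost_noun_wins_overlaps(make_ct, tagger):
    # "the dog house": "house" claims nothing (NN is not a modifier),
    # then "dog" claims "the"; tokens belong to at most one match.
    ct = make_ct("the dog house")
    matches = find_elaborated_noun_phrases(tag_transcript(ct.utterances, tagger))
    spans = {m.noun: m.modifier_tokens for m in matches}
    assert spans == {"house": (), "dog": ("the",)}


def test_enp_transcript_max_across_utterances(make_ct, tagger):
    ct = make_ct("the big black dog ran", "a frog jumped")
    res = score_enp(tag_transcript(ct.utterances, tagger))
    assert res.unique_count == 3
    assert res.score == 3


# --- whole-transcript scoring ----------------------------------------------

def test_habitual_passage_full_transcript(make_ct, banks, tagger):
    result = score_transcript(make_ct(*HABITUAL_PASSAGE), banks, tagger)
    by = result.by_element()
    assert by["coordinating_conjunction"] == 0
    assert by["subordinating_conjunction"] == 0
    assert by["metalinguistic_verb"] == 0
    assert by["metacognitive_verb"] == 0


def test_total_is_sum_and_bounded(make_ct, banks, tagger):
    ct = make_ct(
        "the big green frog jumped quickly and quietly",
        "he said he thought it was scary because it was huge",
        "but then he suddenly laughed or cried when he decided to hide",
    )
    result = score_transcript(ct, banks, tagger)
    assert result.total == sum(s.score for s in result.scores)
    assert 0 <= result.total <= 18
    assert all(s.score in (0, 1, 2, 3) for s in result.scores)


def test_monotonicity_new_bank_word_never_decreases_score(make_ct, banks):
    base = make_ct("he fell because it was wet")
    bank = banks["subordinating_conjunction"]
    before = score_bank_element(base, bank).score
    extended = make_ct("he fell because it was wet", "he hid until night")
    after = score_bank_element(extended, bank).score
    assert after >= before


def test_duplicating_an_utterance_preserves_bank_scores(make_ct, banks):
    ct = make_ct("he fell because it was wet", "he cried when he fell")
    dup = make_ct(
        "he fell because it was wet",
        "he cried when he fell",
        "he cried when he fell",
    )
    for el in ("subordinating_conjunction", "metalinguistic_verb",
               "metacognitive_verb"):
        assert (
            score_bank_element(ct, banks[el]).score
            == score_bank_element(dup, banks[el]).score
        )


def test_scores_require_all_six_elements_in_order():
    with pytest.raises(ValueError):
        MISLMicroScores("t", tuple(
            ElementScore(el, 0) for el in ELEMENTS[:5]
        ))


@pytest.mark.parametrize("count, expected", [(0, 0), (1, 1), (2, 2), (3, 3),
                                             (4, 3), (10, 3)])
def test_score_cap(count, expected):
    assert ElementScore("adverb", count).score == expected
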