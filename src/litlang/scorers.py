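"""The six literate-language microstructure scorers.

Each element of the MISL microstructure rubric is scored 0-3 for a whole
transcript:

* coordinating conjunctions, subordinating conjunctions, meta-linguistic
  verbs, meta-cognitive verbs — the number of *distinct* bank-word types used
  anywhere in the transcript, capped at 3 (a child who says "and" ten times
  has shown one coordinator type);
* adverbs — the number of distinct word types the tagger classes as adverbs,
  capped at 3;
* elaborated noun phrase (ENP) — the largest number of admissible modifiers
  preceding any noun, capped at 3 (0 means every noun is bare).

Coordinating conjunctions carry one extra rule: the *habitual opener*. Young
narrators often open clause after clause with the same conjunction ("And then
... And then ... And ...") as a filler rather than a connective. When three or
more consecutive utterances open with the same coordinating conjunction, those
utterance-initial occurrences are suppressed from the count; mid-utterance
uses inside the run still count, because there the word is doing connective
work.

The ENP modifier template is a slot grammar read left-to-right:

    [determiner | possessive pronoun]? [number]? ([adverb]? adjective)* noun

with adverbs admitted only immediately before an adjective ("very big dog").
A sequence that violates ordering ("silly the girl") is truncated at the
violation — the grammatical sub-span still counts, the ungrammatical part
never does. Matching is rightmost-noun-first and each token belongs to at
most one noun phrase.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lexicon import ELEMENTS, WordBank
from .tagger import (
    ADJECTIVE,
    ADVERB,
    DETERMINER,
    NOUN,
    NUMBER,
    PRONOUN_POSSESSIVE,
    TaggedToken,
    Tagger,
    tag_transcript,
)
from .transcript_io import CleanTranscript

__all__ = [
    "MAX_SCORE",
    "ElementScore",
    "NounPhraseMatch",
    "MISLMicroScores",
    "score_bank_element",
    "habitual_opener_exclusions",
    "score_coordinating",
    "score_adverbs",
    "find_elaborated_noun_phrases",
    "score_enp",
    "score_transcript",
]

MAX_SCORE = 3
#: Minimum run length for the habitual-opener suppression rule.
OPENER_RUN_LENGTH = 3


@dataclass(frozen=True)
class ElementScore:
    """Score for one element: the capped count plus supporting evidence.

    ``unique_count`` is the uncapped quantity (distinct types, or for ENP the
    maximum modifier count); ``score = min(3, unique_count)``. ``evidence``
    lists ``(utterance_index, token_or_span)`` pairs supporting the count.
    """

    element: str
    unique_count: int
    evidence: tuple[tuple[int, str], ...] = ()

    @property
    def score(self) -> int:
        return min(MAX_SCORE, self.unique_count)


@dataclass(frozen=True)
class NounPhraseMatch:
    """A noun with its admissible preceding-modifier span."""

    utterance_index: int
    noun_position: int
    noun: str
    modifier_classes: tuple[str, ...]
    modifier_tokens: tuple[str, ...]

    @property
    def modifier_count(self) -> int:
        return len(self.modifier_classes)


@dataclass(frozen=True)
class MISLMicroScores:
    """The six element scores for one transcript; total is out of 18."""

    transcript_id: str
    scores: tuple[ElementScore, ...]

    def __post_init__(self) -> None:
        got = tuple(s.element for s in self.scores)
        if got != ELEMENTS:
            raise ValueError(f"need one score per element in order, got {got}")

    @property
    def total(self) -> int:
        return sum(s.score for s in self.scores)

    def by_element(self) -> dict[str, int]:
        return {s.element: s.score for s in self.scores}

    def as_row(self) -> dict[str, int | str]:
        """Flat mapping matching the score CSV schema."""
        row: dict[str, int | str] = {"id": self.transcript_id}
        short = dict(zip(ELEMENTS, (
            "coord_conj", "subord_conj", "metaling_verb", "metacog_verb",
            "adverb", "enp",
        )))
        for s in self.scores:
            row[short[s.element]] = s.score
        row["total"] = self.total
        return row


def score_bank_element(ct: CleanTranscript, bank: WordBank) -> ElementScore:
    """Count distinct bank-word types used anywhere in the transcript."""
    types: set[str] = set()
    evidence: list[tuple[int, str]] = []
    for utt_idx, _, tok in ct.iter_tokens():
        if tok in bank:
            types.add(tok)
            evidence.append((utt_idx, tok))
    return ElementScore(bank.element, len(types), tuple(evidence))


def habitual_opener_exclusions(
    ct: CleanTranscript, bank: WordBank, mode: str = "initial"
) -> set[tuple[int, int]]:
    """Positions suppressed by the habitual-opener rule.

    For every maximal run of at least three consecutive utterances opening
    with the same coordinating conjunction, the utterance-initial occurrences
    of that word across the whole run are excluded. With ``mode="whole_run"``
    every occurrence of the word inside the run's utterances is excluded
    instead (a stricter reading some scorers may prefer).
    """
    if mode not in ("initial", "whole_run"):
        raise ValueError(f"unknown opener exclusion mode {mode!r}")
    utts = ct.utterances
    openers = [u.tokens[0] if u.tokens else None for u in utts]
    excluded: set[tuple[int, int]] = set()
    i = 0
    while i < len(utts):
        word = openers[i]
        if word is None or word not in bank:
            i += 1
            continue
        j = i
        while j < len(utts) and openers[j] == word:
            j += 1
        if j - i >= OPENER_RUN_LENGTH:
            for k in range(i, j):
                if mode == "initial":
                    excluded.add((utts[k].index, 0))
                else:
                    for pos, tok in enumerate(utts[k].tokens):
                        if tok == word:
                            excluded.add((utts[k].index, pos))
        i = j
    return excluded


def score_coordinating(
    ct: CleanTranscript, bank: WordBank, opener_exclusion: str = "initial"
) -> ElementScore:
    """Bank scoring with habitual-opener occurrences made invisible."""
    excluded = habitual_opener_exclusions(ct, bank, opener_exclusion)
    types: set[str] = set()
    evidence: list[tuple[int, str]] = []
    for utt_idx, pos, tok in ct.iter_tokens():
        if tok in bank and (utt_idx, pos) not in excluded:
            types.add(tok)
            evidence.append((utt_idx, tok))
    return ElementScore(bank.element, len(types), tuple(evidence))


def score_adverbs(tagged: list[TaggedToken]) -> ElementScore:
    """Count distinct word types classed as adverbs, capped at 3.

    Uniqueness is by word type alone: "fast" tagged adjective in one utterance
    does not block "fast" counting once as an adverb elsewhere.
    """
    types: set[str] = set()
    evidence: list[tuple[int, str]] = []
    for tt in tagged:
        if tt.word_class == ADVERB:
            types.add(tt.token)
            evidence.append((tt.utterance_index, tt.token))
    return ElementScore("adverb", len(types), tuple(evidence))


_OPT_DET = (DETERMINER, PRONOUN_POSSESSIVE)


def find_elaborated_noun_phrases(
    tagged: list[TaggedToken],
) -> list[NounPhraseMatch]:
    """Find, per noun, the longest admissible preceding-modifier span.

    Works per utterance, scanning nouns right to left so that overlapping
    candidates resolve in favor of the rightmost noun; claimed tokens are
    unavailable to later (leftward) nouns. Extension stops at the first
    ordering violation, keeping the grammatical sub-span.
    """
    by_utt: dict[int, list[TaggedToken]] = {}
    for tt in tagged:
        by_utt.setdefault(tt.utterance_index, []).append(tt)
    matches: list[NounPhraseMatch] = []
    for utt_idx, toks in by_utt.items():
        toks = sorted(toks, key=lambda t: t.position)
        cls = [t.word_class for t in toks]
        claimed = [False] * len(toks)
        for i in range(len(toks) - 1, -1, -1):
            if cls[i] != NOUN or claimed[i]:
                continue
            claimed[i] = True
            span: list[int] = []
            j = i - 1
            # ([adverb]? adjective)* zone, read right-to-left
            while j >= 0 and not claimed[j] and cls[j] == ADJECTIVE:
                span.append(j)
                j -= 1
                if j >= 0 and not claimed[j] and cls[j] == ADVERB:
                    span.append(j)
                    j -= 1
            if j >= 0 and not claimed[j] and cls[j] == NUMBER:
                span.append(j)
                j -= 1
            if j >= 0 and not claimed[j] and cls[j] in _OPT_DET:
                span.append(j)
                j -= 1
            span.reverse()
            for k in span:
                claimed[k] = True
            matches.append(
                NounPhraseMatch(
                    utterance_index=utt_idx,
                    noun_position=toks[i].position,
                    noun=toks[i].token,
                    modifier_classes=tuple(cls[k] for k in span),
                    modifier_tokens=tuple(toks[k].token for k in span),
                )
            )
    return matches


def score_enp(tagged: list[TaggedToken]) -> ElementScore:
    """Score elaborated noun phrases by the transcript's longest modifier span."""
    matches = find_elaborated_noun_phrases(tagged)
    if not matches:
        return ElementScore("elaborated_noun_phrase", 0)
    best = max(matches, key=lambda m: m.modifier_count)
    evidence = tuple(
        (m.utterance_index, " ".join(m.modifier_tokens + (m.noun,)))
        for m in matches
        if m.modifier_count == best.modifier_count and m.modifier_count > 0
    )
    return ElementScore(
        "elaborated_noun_phrase", best.modifier_count, evidence
    )


def score_transcript(
    ct: CleanTranscript,
    banks: dict[str, WordBank],
    tagger: Tagger,
    opener_exclusion: str = "initial",
) -> MISLMicroScores:
    """Run all six scorers over one cleaned transcript.

    An empty transcript legitimately scores 0 on every element. Tagger
    configuration problems propagate; transcript content never raises.
    """
    tagged = tag_transcript(ct.utterances, tagger)
    scores = (
        score_coordinating(
            ct, banks["coordinating_conjunction"], opener_exclusion
        ),
        score_bank_element(ct, banks["subordinating_conjunction"]),
        score_bank_element(ct, banks["metalinguistic_verb"]),
        score_bank_element(ct, banks["metacognitive_verb"]),
        score_adverbs(tagged),
        score_enp(tagged),
    )
    return MISLMicroScores(transcript_id=ct.transcript_id, scores=scores)
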