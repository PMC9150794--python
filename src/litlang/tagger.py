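"""Part-of-speech tagging behind a stable, pluggable interface.

The adverb and elaborated-noun-phrase scorers need word classes, not surface
forms, because many English words are class-ambiguous in isolation ("like" can
be a preposition, verb, noun, or adverb). Tagging is therefore done over the
whole utterance, never word-by-word.

The default backend, :class:`RuleTagger`, is a deterministic lexicon + suffix +
context tagger emitting Penn Treebank tags. Its lexicon is tuned to the child
narrative register (ages ~5-10): a closed-class list, a few hundred open-class
words common in children's stories, suffix heuristics for out-of-vocabulary
words, and a small set of context rules for the class-ambiguous words that
matter to scoring ("fast", "so", "there", particles). It is intentionally
conservative: an unknown word defaults to noun, and wh-adverbs ("when",
"where") are kept out of the adverb class.

Any backend exposing ``name``, ``version`` and ``tag(tokens) -> list[str]``
(Penn tags) can be registered and selected by name; the scorers only ever see
the mapped word classes. The backend identity is echoed into score reports so
every run is reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol, Sequence

from .transcript_io import Utterance

__all__ = [
    "WordClass",
    "TaggedToken",
    "Tagger",
    "RuleTagger",
    "get_tagger",
    "register_tagger",
    "map_tag_to_class",
    "tag_utterance",
    "tag_transcript",
]

# Word classes the scorers consume.
NOUN = "NOUN"
ADJECTIVE = "ADJECTIVE"
ADVERB = "ADVERB"
DETERMINER = "DETERMINER"
NUMBER = "NUMBER"
PRONOUN_POSSESSIVE = "PRONOUN_POSSESSIVE"
VERB = "VERB"
OTHER = "OTHER"
WordClass = str


def map_tag_to_class(tag: str) -> WordClass:
    """Map a Penn Treebank tag onto a scorer word class. Total: unknown -> OTHER."""
    if tag in ("NN", "NNS", "NNP", "NNPS"):
        return NOUN
    if tag in ("JJ", "JJR", "JJS"):
        return ADJECTIVE
    if tag in ("RB", "RBR", "RBS"):
        return ADVERB
    if tag in ("DT", "PDT"):
        return DETERMINER
    if tag == "CD":
        return NUMBER
    if tag == "PRP$":
        return PRONOUN_POSSESSIVE
    if tag.startswith("VB"):
        return VERB
    return OTHER


@dataclass(frozen=True)
class TaggedToken:
    """A token with its Penn tag, mapped word class, and position."""

    token: str
    tag: str
    word_class: WordClass
    utterance_index: int
    position: int


class Tagger(Protocol):
    name: str
    version: str

    def tag(self, tokens: Sequence[str]) -> list[str]: ...


# ---------------------------------------------------------------------------
# Default rule-based backend
# ---------------------------------------------------------------------------

_DT = {"the", "a", "an", "this", "these", "those", "each", "every", "some",
       "any", "no", "another", "either", "neither"}
_PDT = {"all", "both", "half"}
_PRPS = {"my", "your", "his", "her", "its", "our", "their"}
_PRP = {"i", "you", "he", "she", "it", "we", "they", "me", "him", "them",
        "us", "himself", "herself", "itself", "myself", "yourself",
        "themselves", "ourselves", "someone", "somebody", "anyone", "anybody",
        "everyone", "everybody", "nobody", "something", "anything",
        "everything", "nothing"}
_CC = {"and", "but", "or", "nor"}
_IN = {"of", "in", "on", "at", "by", "with", "from", "into", "onto",
       "about", "after", "before", "because", "since", "until", "till",
       "while", "as", "than", "like", "beside", "between", "through",
       "across", "under", "above", "during", "without", "toward", "towards",
       "upon", "against", "along", "past", "although", "though", "unless",
       "if", "for", "cause", "cuz"}
_MD = {"can", "could", "will", "would", "shall", "should", "may", "might",
       "must"}
_WDT = {"what", "which"}
_WP = {"who", "whom", "whose"}
_WRB = {"when", "where", "why", "how", "whenever", "wherever"}
_UH = {"um", "uh", "oh", "ah", "hey", "wow", "yeah", "yay", "ooh", "ow",
       "oops", "mhm", "hm", "hmm", "huh", "okay", "ok", "please", "bye",
       "hi", "hello"}
_CD_WORDS = {"zero", "one", "two", "three", "four", "five", "six", "seven",
             "eight", "nine", "ten", "eleven", "twelve", "thirteen",
             "fourteen", "fifteen", "sixteen", "seventeen", "eighteen",
             "nineteen", "twenty", "thirty", "forty", "fifty", "hundred",
             "thousand", "million"}
_BE = {"am": "VBP", "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
       "be": "VB", "been": "VBN", "being": "VBG"}
_AUX = {"have": "VBP", "has": "VBZ", "had": "VBD", "having": "VBG",
        "do": "VBP", "does": "VBZ", "did": "VBD", "done": "VBN",
        "gonna": "VBG", "wanna": "VB", "gotta": "VB", "let": "VB",
        "lets": "VBZ"}

# Singular noun lemmas; plurals are recovered by the -s suffix rule.
_NOUNS = {"dog", "cat", "boy", "girl", "man", "woman", "frog", "bird",
          "house", "tree", "alien", "spaceship", "ship", "rocket", "star",
          "moon", "sun", "sky", "ground", "forest", "store", "school",
          "home", "mom", "dad", "mother", "father", "brother", "sister",
          "friend", "kid", "baby", "monster", "dragon", "bear", "lion",
          "tiger", "monkey", "rabbit", "turtle", "duck", "pig", "cow",
          "horse", "fox", "snake", "mouse", "car", "truck", "plane", "boat",
          "ball", "toy", "book", "hat", "box", "rock", "stick", "water",
          "food", "candy", "cake", "apple", "door", "window", "room", "bed",
          "chair", "table", "park", "yard", "town", "city", "king", "queen",
          "princess", "prince", "grandma", "grandpa", "teacher", "police",
          "farmer", "day", "night", "morning", "time", "thing", "stuff",
          "place", "way", "name", "story", "picture", "eye", "head", "hand",
          "foot", "leg", "arm", "hair", "face", "mouth", "nose", "tail",
          "wing", "space", "earth", "world", "planet", "grocery", "today",
          "tomorrow", "yesterday", "fish", "sheep", "deer", "cheese",
          "milk", "juice", "garden", "hill", "mountain", "river", "lake",
          "ocean", "beach", "sand", "grass", "flower", "leaf", "branch",
          "nest", "cave", "castle", "wizard", "fairy", "robot", "game",
          "bike", "kite", "shoe", "sock", "shirt", "coat", "pocket", "bag",
          "cup", "plate", "spoon", "egg", "cookie", "pizza", "sandwich"}
_PLURAL_NOUNS = {"children", "men", "women", "people", "mice", "feet",
                 "teeth", "groceries", "pants", "scissors", "leaves"}

_VERB_FORMS = {
    # movement / action verbs common in child narratives
    "run": "VB", "runs": "VBZ", "ran": "VBD", "running": "VBG",
    "jump": "VB", "jumps": "VBZ", "jumped": "VBD", "jumping": "VBG",
    "play": "VB", "plays": "VBZ", "played": "VBD", "playing": "VBG",
    "walk": "VB", "walks": "VBZ", "walked": "VBD", "walking": "VBG",
    "go": "VB", "goes": "VBZ", "went": "VBD", "gone": "VBN", "going": "VBG",
    "goed": "VBD", "come": "VB", "comes": "VBZ", "came": "VBD",
    "coming": "VBG", "see": "VB", "sees": "VBZ", "saw": "VBD", "seen": "VBN",
    "seeing": "VBG", "look": "VB", "looks": "VBZ", "looked": "VBD",
    "looking": "VBG", "eat": "VB", "eats": "VBZ", "ate": "VBD",
    "eaten": "VBN", "eating": "VBG", "sleep": "VB", "sleeps": "VBZ",
    "slept": "VBD", "sleeping": "VBG", "swim": "VB", "swims": "VBZ",
    "swam": "VBD", "swimming": "VBG", "climb": "VB", "climbs": "VBZ",
    "climbed": "VBD", "climbing": "VBG", "fly": "VB", "flies": "VBZ",
    "flew": "VBD", "flown": "VBN", "flying": "VBG", "fall": "VB",
    "falls": "VBZ", "fell": "VBD", "fallen": "VBN", "falling": "VBG",
    "hide": "VB", "hides": "VBZ", "hid": "VBD", "hidden": "VBN",
    "hiding": "VBG", "find": "VB", "finds": "VBZ", "found": "VBD",
    "finding": "VBG", "take": "VB", "takes": "VBZ", "took": "VBD",
    "taken": "VBN", "taking": "VBG", "give": "VB", "gives": "VBZ",
    "gave": "VBD", "given": "VBN", "giving": "VBG", "make": "VB",
    "makes": "VBZ", "made": "VBD", "making": "VBG", "put": "VB",
    "puts": "VBZ", "putting": "VBG", "get": "VB", "gets": "VBZ",
    "got": "VBD", "gotten": "VBN", "getting": "VBG", "want": "VB",
    "wants": "VBZ", "wanted": "VBD", "wanting": "VBG", "need": "VB",
    "needs": "VBZ", "needed": "VBD", "love": "VB", "loves": "VBZ",
    "loved": "VBD", "help": "VB", "helps": "VBZ", "helped": "VBD",
    "helping": "VBG", "stop": "VB", "stops": "VBZ", "stopped": "VBD",
    "stopping": "VBG", "start": "VB", "starts": "VBZ", "started": "VBD",
    "starting": "VBG", "try": "VB", "tries": "VBZ", "tried": "VBD",
    "trying": "VBG", "live": "VB", "lived": "VBD", "sit": "VB",
    "sits": "VBZ", "sat": "VBD", "sitting": "VBG", "stand": "VB",
    "stands": "VBZ", "stood": "VBD", "standing": "VBG", "hold": "VB",
    "holds": "VBZ", "held": "VBD", "holding": "VBG", "throw": "VB",
    "throws": "VBZ", "threw": "VBD", "thrown": "VBN", "throwing": "VBG",
    "catch": "VB", "catches": "VBZ", "caught": "VBD", "catching": "VBG",
    "kick": "VB", "kicked": "VBD", "push": "VB", "pushed": "VBD",
    "pull": "VB", "pulled": "VBD", "turn": "VB", "turned": "VBD",
    "move": "VB", "moved": "VBD", "dance": "VB", "danced": "VBD",
    "dancing": "VBG", "smile": "VB", "smiled": "VBD", "wave": "VB",
    "waved": "VBD", "hop": "VB", "hopped": "VBD", "crawl": "VB",
    "crawled": "VBD", "chase": "VB", "chased": "VBD", "grab": "VB",
    "grabbed": "VBD", "drop": "VB", "dropped": "VBD", "build": "VB",
    "built": "VBD", "break": "VB", "broke": "VBD", "broken": "VBN",
    "fix": "VB", "fixed": "VBD", "save": "VB", "saved": "VBD",
    "meet": "VB", "met": "VBD", "leave": "VB", "left": "VBD",
    "land": "VB", "landed": "VBD", "bring": "VB", "brought": "VBD",
    "buy": "VB", "bought": "VBD", "show": "VB", "showed": "VBD",
    "watch": "VB", "watched": "VBD", "hear": "VB", "hears": "VBZ",
    "heard": "VBD", "listen": "VB", "listened": "VBD",
    # dialogue verbs
    "say": "VB", "says": "VBZ", "said": "VBD", "saying": "VBG",
    "sayed": "VBD", "tell": "VB", "tells": "VBZ", "told": "VBD",
    "telling": "VBG", "ask": "VB", "asks": "VBZ", "asked": "VBD",
    "asking": "VBG", "yell": "VB", "yells": "VBZ", "yelled": "VBD",
    "yelling": "VBG", "shout": "VB", "shouted": "VBD", "shouting": "VBG",
    "scream": "VB", "screamed": "VBD", "whisper": "VB", "whispered": "VBD",
    "call": "VB", "calls": "VBZ", "called": "VBD", "calling": "VBG",
    "talk": "VB", "talks": "VBZ", "talked": "VBD", "talking": "VBG",
    "speak": "VB", "spoke": "VBD", "answer": "VB", "answered": "VBD",
    "reply": "VB", "replied": "VBD", "laugh": "VB", "laughs": "VBZ",
    "laughed": "VBD", "laughing": "VBG", "cry": "VB", "cries": "VBZ",
    "cried": "VBD", "crying": "VBG", "sing": "VB", "sings": "VBZ",
    "sang": "VBD", "singing": "VBG",
    # mental-state verbs
    "think": "VB", "thinks": "VBZ", "thought": "VBD", "thinking": "VBG",
    "know": "VB", "knows": "VBZ", "knew": "VBD", "knowing": "VBG",
    "wonder": "VB", "wonders": "VBZ", "wondered": "VBD", "wondering": "VBG",
    "decide": "VB", "decides": "VBZ", "decided": "VBD", "deciding": "VBG",
    "remember": "VB", "remembers": "VBZ", "remembered": "VBD",
    "forget": "VB", "forgets": "VBZ", "forgot": "VBD", "believe": "VB",
    "believes": "VBZ", "believed": "VBD", "wish": "VB", "wishes": "VBZ",
    "wished": "VBD", "hope": "VB", "hopes": "VBZ", "hoped": "VBD",
    "guess": "VB", "guesses": "VBZ", "guessed": "VBD", "imagine": "VB",
    "imagined": "VBD", "pretend": "VB", "pretends": "VBZ",
    "pretended": "VBD", "realize": "VB", "realized": "VBD",
    "figure": "VB", "figured": "VBD", "feel": "VB", "feels": "VBZ",
    "felt": "VBD", "feeling": "VBG",
}

_ADJS = {"big", "little", "small", "tiny", "huge", "quick", "slow", "tall",
         "short", "long", "old", "new", "young", "good", "bad", "nice",
         "mean", "happy", "sad", "angry", "mad", "scared", "scary", "funny",
         "silly", "crazy", "weird", "strange", "loud", "quiet", "red",
         "blue", "green", "yellow", "orange", "purple", "pink", "black",
         "white", "brown", "gray", "dark", "bright", "shiny", "furry",
         "fuzzy", "slimy", "hungry", "thirsty", "sleepy", "tired", "brave",
         "beautiful", "ugly", "dirty", "wet", "dry", "hot", "cold", "warm",
         "cool", "friendly", "lonely", "favorite", "special", "real",
         "whole", "other", "magic", "great", "afraid", "sorry", "sure",
         "full", "empty", "heavy", "soft", "hard", "smart", "sneaky"}

_ADVS = {"quickly", "quietly", "suddenly", "slowly", "carefully", "loudly",
         "softly", "gently", "happily", "sadly", "safely", "bravely",
         "finally", "really", "very", "too", "also", "again", "away",
         "soon", "now", "later", "never", "always", "often", "sometimes",
         "usually", "maybe", "almost", "just", "still", "even", "already",
         "together", "everywhere", "somewhere", "anywhere", "here", "then",
         "once", "twice", "not", "far", "instead", "anymore", "forever",
         "secretly", "actually", "probably"}

# Ambiguous words resolved by context; each maps to a resolver key.
_JJ_OR_RB = {"fast", "early", "late", "high", "low", "deep", "right",
             "first", "second", "third", "last", "next"}
_IN_OR_RB = {"up", "down", "out", "off", "over", "around", "inside",
             "outside", "behind", "near", "below", "underneath"}
_JJ_OR_NN = {"giant", "baby", "pet", "toy", "gold", "silver", "pirate",
             "alien", "monster", "christmas", "birthday"}

_NOMINAL_TAGS = {"NN", "NNS", "NNP", "NNPS", "PRP", "CD", "JJ", "JJR",
                 "JJS", "DT", "PRP$", "PDT"}
_NOUNY_TAGS = {"NN", "NNS", "NNP", "NNPS"}

_DIGIT_RE = re.compile(r"^\d+(st|nd|rd|th)?$")


def _suffix_guess(word: str) -> str:
    if _DIGIT_RE.match(word):
        return "CD"
    if word.endswith("ly") and len(word) > 3:
        return "RB"
    if word.endswith("ing") and len(word) > 4:
        return "VBG"
    if word.endswith("ed") and len(word) > 3:
        return "VBD"
    if word.endswith("est") and len(word) > 4:
        stem = word[:-3]
        if stem in _ADJS or stem + "e" in _ADJS or (stem[:-1] if stem else "") in _ADJS:
            return "JJS"
        return "JJS" if len(word) <= 8 else "NN"
    if word.endswith("er") and len(word) > 3:
        stem = word[:-2]
        if stem in _ADJS or stem + "e" in _ADJS or (stem[:-1] if stem else "") in _ADJS:
            return "JJR"
        return "NN"
    if word.endswith("s") and not word.endswith("ss") and len(word) > 2:
        stem = word[:-1]
        if word.endswith("ies") and len(word) > 4:
            stem_y = word[:-3] + "y"
            if stem_y in _NOUNS:
                return "NNS"
            if stem_y in _VERB_FORMS:
                return "VBZ"
        if word.endswith("es"):
            stem_e = word[:-2]
            if stem_e in _NOUNS:
                return "NNS"
            if stem_e in _VERB_FORMS:
                return "VBZ"
        if stem in _NOUNS:
            return "NNS"
        if stem in _VERB_FORMS:
            return "VBZ"
        return "NNS"
    return "NN"


def _provisional(word: str) -> str:
    """First-pass tag ignoring context; ambiguity resolved in the second pass."""
    if word in _DT:
        return "DT"
    if word in _PDT:
        return "PDT"
    if word in _PRPS:
        return "PRP$"
    if word in _PRP:
        return "PRP"
    if word in _CC:
        return "CC"
    if word == "to":
        return "TO"
    if word in _MD:
        return "MD"
    if word in _BE:
        return _BE[word]
    if word in _AUX:
        return _AUX[word]
    if word in _IN:
        return "IN"
    if word in _WRB:
        return "WRB"
    if word in _WDT:
        return "WDT"
    if word in _WP:
        return "WP"
    if word in _UH:
        return "UH"
    if word in _CD_WORDS:
        return "CD"
    if word in _IN_OR_RB:
        return "RB"
    if word in _JJ_OR_RB:
        return "JJ"
    if word in _JJ_OR_NN:
        return "JJ"
    if word in _ADVS or word == "there" or word == "so" or word == "yet" or word == "well":
        return "RB"
    if word in _ADJS:
        return "JJ"
    if word in _VERB_FORMS and word not in _NOUNS:
        return _VERB_FORMS[word]
    if word in _PLURAL_NOUNS:
        return "NNS"
    if word in _NOUNS:
        return "NN"
    return _suffix_guess(word)


class RuleTagger:
    """Deterministic lexicon/suffix/context tagger for child narrative English.

    Two passes over the utterance: a context-free provisional assignment, then
    a left-to-right pass that resolves the enumerated ambiguous words using
    the resolved tag to the left and the provisional tag to the right.
    """

    name = "rule-en-child"
    version = "1.0"

    def tag(self, tokens: Sequence[str]) -> list[str]:
        words = [t.lower() for t in tokens]
        prov = [_provisional(w) for w in words]
        tags: list[str] = []
        n = len(words)
        for i, w in enumerate(words):
            prev = tags[i - 1] if i > 0 else None
            nxt = prov[i + 1] if i + 1 < n else None
            tags.append(self._resolve(w, prov[i], prev, nxt, i, n))
        return tags

    @staticmethod
    def _resolve(
        word: str, prov: str, prev: str | None, nxt: str | None,
        pos: int, n: int,
    ) -> str:
        if word == "there":
            if pos == 0 and nxt in ("VBZ", "VBD", "VBP"):
                return "EX"
            return "RB"
        if word == "so":
            return "RB" if nxt in ("JJ", "RB", "JJR") else "CC"
        if word == "yet":
            return "RB" if pos == n - 1 else "CC"
        if word == "well":
            return "UH" if pos == 0 else "RB"
        if word in _JJ_OR_RB:
            return "JJ" if nxt in _NOUNY_TAGS or nxt == "JJ" else "RB"
        if word == "pretty":
            return "RB" if nxt in ("JJ", "RB") else "JJ"
        if word in _IN_OR_RB:
            return "IN" if nxt in _NOMINAL_TAGS else "RB"
        if word in _JJ_OR_NN:
            return "JJ" if nxt in _NOUNY_TAGS else "NN"
        if word in _NOUNS and word in _VERB_FORMS:
            if prev in ("TO", "MD"):
                return "VB"
            if prev == "PRP":
                return _VERB_FORMS[word]
            return "NN"
        # Base-form verb after determiner is being used nominally ("the jump").
        if prov == "VB" and prev in ("DT", "PRP$", "JJ", "CD"):
            return "NN"
        return prov


_REGISTRY: dict[str, type] = {"rule-en-child": RuleTagger}


def register_tagger(name: str, factory: type) -> None:
    """Register an alternative tagging backend under ``name``."""
    _REGISTRY[name] = factory


def get_tagger(name: str = "rule-en-child") -> Tagger:
    """Instantiate a registered tagging backend by name."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise ValueError(
            f"unknown tagger {name!r}; registered: {sorted(_REGISTRY)}. "
            "Register a backend with register_tagger() or use the default."
        ) from None


def tag_utterance(utt: Utterance, tagger: Tagger) -> list[TaggedToken]:
    """Tag one utterance with full-utterance context.

    Returns one :class:`TaggedToken` per input token, order preserved.
    """
    tags = tagger.tag(utt.tokens)
    if len(tags) != len(utt.tokens):
        raise RuntimeError(
            f"tagger {tagger.name} returned {len(tags)} tags for "
            f"{len(utt.tokens)} tokens"
        )
    return [
        TaggedToken(
            token=tok, tag=tag, word_class=map_tag_to_class(tag),
            utterance_index=utt.index, position=i,
        )
        for i, (tok, tag) in enumerate(zip(utt.tokens, tags))
    ]


def tag_transcript(utterances, tagger: Tagger) -> list[TaggedToken]:
    """Tag every utterance of a cleaned transcript; flat list in order."""
    out: list[TaggedToken] = []
    for utt in utterances:
        if utt.tokens:
            out.extend(tag_utterance(utt, tagger))
    return out
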