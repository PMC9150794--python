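"""Synthetic SALT-dialect narrative transcripts with known element scores.

Real scored corpora of child narratives are rarely shareable, so every scorer
here is exercised against generated stories whose ground-truth scores are
known by construction. A generated transcript emulates the shape of an
elicited child narrative sample: 1-41 communication units per story, SALT
speaker codes with a header and an occasional examiner turn, parenthesized
mazes, bound-morpheme markers, and a controllable habitual-opener run ("And
... And ... And ...").

Construction is compositional: each requested element instance is carried by
one short carrier clause built from a *tagger-safe* vocabulary pool — words
whose part-of-speech is stable for the pinned default tagger (plural bare
nouns, unambiguous past-tense verbs, -ly adverbs, color/size adjectives).
Bank words are placed non-utterance-initially so the habitual-opener rule
cannot touch them; mazes contain only filler words and are removed in
cleaning, so they never move a score. The generator shares no code with the
scorers beyond the word banks themselves, which is what makes round-trip
tests meaningful.

Generation is deterministic given the seed; corpus generation derives the
per-transcript seed as ``seed + index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lexicon import BANK_ELEMENTS, ELEMENTS
from .scorers import ElementScore, MISLMicroScores
from .transcript_io import CHILD_SPEAKER, RawTranscript

__all__ = ["FixtureSpec", "generate_transcript", "generate_corpus"]

# Tagger-safe vocabulary pools. Bank-word pools deliberately avoid forms the
# tagger reads as adverbs ("so", "yet", "therefore") so that inserting a
# conjunction never perturbs the adverb count.
_SAFE_COORD = ("and", "but", "or")
_SAFE_SUBORD = ("because", "when", "if", "while", "until")
_SAFE_METALING = ("said", "yelled", "whispered", "shouted", "asked")
_SAFE_METACOG = ("thought", "wondered", "decided", "knew", "remembered")
_SAFE_ADVERBS = ("quickly", "quietly", "suddenly", "slowly", "carefully",
                 "loudly", "softly", "gently")
_SAFE_ADJS = ("big", "little", "green", "red", "blue", "purple", "furry",
              "scary", "tiny", "brown")
_PLURAL_NOUNS = ("dogs", "frogs", "boys", "girls", "birds", "cats", "bears",
                 "ducks", "pigs", "cows", "horses", "rabbits", "turtles",
                 "monkeys", "lions", "tigers")
_SING_NOUNS = ("frog", "dog", "cat", "bird", "bear", "duck", "rabbit",
               "turtle")
_PAST_VERBS = ("ran", "jumped", "played", "walked", "slept", "swam",
               "climbed", "danced", "waved", "hopped", "crawled", "fell",
               "flew", "hid")
_MAZE_FILLERS = ("um", "uh", "the", "a", "well")

# Surface form -> SALT bound-morpheme spelling, used to exercise cleaning.
_MORPHEME_SPELLINGS = {
    "dogs": "dog/s", "cats": "cat/s", "birds": "bird/s", "frogs": "frog/s",
    "ducks": "duck/s", "cows": "cow/s", "pigs": "pig/s", "bears": "bear/s",
    "jumped": "jump/ed", "played": "play/ed", "walked": "walk/ed",
    "climbed": "climb/ed", "danced": "dance/ed", "waved": "wave/ed",
    "yelled": "yell/ed", "whispered": "whisper/ed", "shouted": "shout/ed",
    "asked": "ask/ed", "wondered": "wonder/ed", "decided": "decide/ed",
    "remembered": "remember/ed", "hopped": "hop/ed", "crawled": "crawl/ed",
}
# Spellings that would not collapse back to the surface form are a bug; the
# dubious ones ("dance/ed" -> "danceed") are excluded here.
_MORPHEME_SPELLINGS = {
    k: v for k, v in _MORPHEME_SPELLINGS.items()
    if v.replace("/", "") == k
}

_OPENER_RUN = 3


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic transcript.

    ``target_scores`` gives the intended 0-3 score per element in canonical
    order (coordinating, subordinating, meta-linguistic, meta-cognitive,
    adverb, ENP). ``n_utterances`` of None lets the generator pick the
    minimum feasible length plus seeded padding.
    """

    transcript_id: str
    target_scores: tuple[int, int, int, int, int, int]
    n_utterances: int | None = None
    maze_rate: float = 0.0
    habitual_opener: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.target_scores) != 6:
            raise ValueError("target_scores must have six entries")
        if any(t not in (0, 1, 2, 3) for t in self.target_scores):
            raise ValueError("each target score must be in {0,1,2,3}")
        if not 0.0 <= self.maze_rate <= 1.0:
            raise ValueError("maze_rate must be in [0,1]")
        if self.n_utterances is not None and self.n_utterances < 1:
            raise ValueError("n_utterances must be >= 1")

    @property
    def min_utterances(self) -> int:
        coord, sub, ml, mc, adv, enp = self.target_scores
        needed = coord + sub + ml + mc + adv + (1 if enp > 0 else 0)
        if self.habitual_opener:
            needed += _OPENER_RUN
        return max(1, needed)


def _truth(spec: FixtureSpec) -> MISLMicroScores:
    scores = tuple(
        ElementScore(element=el, unique_count=t)
        for el, t in zip(ELEMENTS, spec.target_scores)
    )
    return MISLMicroScores(transcript_id=spec.transcript_id, scores=scores)


def _carrier_utterances(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[list[list[str]], list[list[str]]]:
    """Build (opener_run, shuffled carriers+fillers) as token lists."""
    coord, sub, ml, mc, adv, enp = spec.target_scores
    nouns = list(_PLURAL_NOUNS)
    rng.shuffle(nouns)
    verbs = list(_PAST_VERBS)
    rng.shuffle(verbs)

    def noun(i: int) -> str:
        return nouns[i % len(nouns)]

    def verb(i: int) -> str:
        return verbs[i % len(verbs)]

    carriers: list[list[str]] = []
    w = 0  # rolling index into the noun/verb pools
    for c in range(coord):
        carriers.append([noun(w), verb(w), _SAFE_COORD[c], verb(w + 1)])
        w += 2
    for s in range(sub):
        carriers.append(
            [noun(w), verb(w), _SAFE_SUBORD[s], noun(w + 1), verb(w + 1)]
        )
        w += 2
    for m in range(ml):
        carriers.append([noun(w), _SAFE_METALING[m]])
        w += 1
    for m in range(mc):
        carriers.append([noun(w), _SAFE_METACOG[m]])
        w += 1
    for a in range(adv):
        carriers.append([noun(w), verb(w), _SAFE_ADVERBS[a]])
        w += 1
    if enp > 0:
        adjs = list(_SAFE_ADJS)
        rng.shuffle(adjs)
        mods = ["the"] + adjs[: enp - 1] if enp >= 1 else []
        head = _SING_NOUNS[int(rng.integers(len(_SING_NOUNS)))]
        carriers.append(mods + [head, verb(w)])
        w += 1

    n_target = spec.n_utterances
    if n_target is None:
        n_target = spec.min_utterances + int(rng.integers(0, 6))
    n_element_utts = len(carriers) + (_OPENER_RUN if spec.habitual_opener else 0)
    n_fillers = n_target - n_element_utts
    if n_fillers < 0:
        raise ValueError(
            f"{spec.transcript_id}: n_utterances={spec.n_utterances} cannot "
            f"host the requested elements (needs >= {spec.min_utterances})"
        )
    for f in range(n_fillers):
        carriers.append([noun(w), verb(w)])
        w += 1
    rng.shuffle(carriers)

    opener_run: list[list[str]] = []
    if spec.habitual_opener:
        for r in range(_OPENER_RUN):
            opener_run.append(["and", noun(w), verb(w)])
            w += 1
    return opener_run, carriers


def _render_salt_line(
    tokens: list[str], rng: np.random.Generator, maze_rate: float
) -> str:
    words = []
    for tok in tokens:
        spelled = _MORPHEME_SPELLINGS.get(tok)
        if spelled is not None and rng.random() < 0.3:
            words.append(spelled)
        else:
            words.append(tok)
    if rng.random() < maze_rate:
        k = int(rng.integers(1, 3))
        fillers = [
            _MAZE_FILLERS[int(rng.integers(len(_MAZE_FILLERS)))]
            for _ in range(k)
        ]
        maze = "(" + " ".join(fillers) + ")"
        pos = int(rng.integers(0, len(words) + 1))
        words = words[:pos] + [maze] + words[pos:]
    return f"{CHILD_SPEAKER} " + " ".join(words) + " ."


def generate_transcript(
    spec: FixtureSpec,
) -> tuple[RawTranscript, MISLMicroScores]:
    """Generate one SALT-dialect transcript and its ground-truth scores.

    The transcript contains exactly the requested number of distinct bank
    types per bank element (placed non-utterance-initially), exactly the
    requested number of distinct adverbs, and one noun phrase whose modifier
    count is the transcript's maximum and equals the ENP target. Raises if
    ``n_utterances`` is too small to host the requested elements.
    """
    rng = np.random.default_rng(spec.seed)
    opener_run, carriers = _carrier_utterances(spec, rng)
    lines: list[tuple[str, str]] = [("$", "$ Child, Examiner")]
    ordered = opener_run + carriers
    examiner_after = (
        int(rng.integers(0, len(ordered))) if rng.random() < 0.4 else -1
    )
    for i, tokens in enumerate(ordered):
        lines.append(
            (CHILD_SPEAKER, _render_salt_line(tokens, rng, spec.maze_rate))
        )
        if i == examiner_after:
            lines.append(("E", "E and then what happened ?"))
    # read_transcript-style line tuples: (code, body-without-code)
    parsed = []
    for code, text in lines:
        if code == "$":
            parsed.append(("$", text))
        else:
            parsed.append((code, text.split(" ", 1)[1]))
    raw = RawTranscript(
        transcript_id=spec.transcript_id, lines=tuple(parsed), dialect="salt"
    )
    return raw, _truth(spec)


def write_salt_file(raw: RawTranscript, path) -> None:
    """Serialize a raw SALT transcript back to disk, one line per entry."""
    with open(path, "w", encoding="utf-8") as fh:
        for code, text in raw.lines:
            if code == "$":
                fh.write(text + "\n")
            else:
                fh.write(f"{code} {text}\n")


def generate_corpus(
    n: int,
    score_distribution: dict[str, np.ndarray] | np.ndarray | None = None,
    seed: int = 0,
    maze_rate: float = 0.3,
    habitual_opener_rate: float = 0.25,
):
    """Generate ``n`` transcripts with targets drawn per element.

    ``score_distribution`` gives categorical weights over scores 0-3, either
    one vector for all elements or a per-element mapping; the default is
    uniform, mirroring a corpus curated to cover the full 0-3 range of every
    element. Story lengths emulate elicited narrative samples: mean ~13
    utterances, SD ~8, clipped to 1-41, never below the feasible minimum.

    Returns ``(fixtures, truth)`` where ``fixtures`` is a list of
    ``(RawTranscript, MISLMicroScores)`` and ``truth`` collects the rows.
    """
    from .agreement import ScoreTable

    if n < 1:
        raise ValueError("n must be >= 1")
    weights = {}
    for el in ELEMENTS:
        if score_distribution is None:
            w = np.ones(4)
        elif isinstance(score_distribution, dict):
            w = np.asarray(score_distribution[el], dtype=float)
        else:
            w = np.asarray(score_distribution, dtype=float)
        if w.shape != (4,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError(f"degenerate score weights for {el}: {w}")
        weights[el] = w / w.sum()

    master = np.random.default_rng(seed)
    fixtures = []
    rows = []
    for i in range(n):
        targets = tuple(
            int(master.choice(4, p=weights[el])) for el in ELEMENTS
        )
        opener = bool(master.random() < habitual_opener_rate)
        length = int(np.clip(round(master.normal(13.2, 7.6)), 1, 41))
        probe = FixtureSpec(
            transcript_id=f"synth_{i:04d}", target_scores=targets,
            habitual_opener=opener, seed=seed + i,
        )
        spec = FixtureSpec(
            transcript_id=probe.transcript_id,
            target_scores=targets,
            n_utterances=max(probe.min_utterances, length),
            maze_rate=maze_rate,
            habitual_opener=opener,
            seed=seed + i,
        )
        raw, truth = generate_transcript(spec)
        fixtures.append((raw, truth))
        rows.append(truth.as_row())
    truth_table = ScoreTable.from_rows("ground_truth", rows)
    return fixtures, truth_table
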