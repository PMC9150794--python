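"""Word banks for the bank-matched literate-language elements.

Four elements are scored by exact surface-form matching against a predefined
bank of common, age-appropriate words: coordinating conjunctions,
subordinating conjunctions, meta-linguistic verbs (verbs of dialogue), and
meta-cognitive verbs (verbs of thought and perspective). Inflected forms are
enumerated in the bank files rather than obtained by lemmatizing tokens, which
keeps matching auditable but means overgeneralized irregular forms ("sayed")
are missed.

Banks ship as editable one-word-per-line text files and can be overridden per
element. The quotative "like" is excluded from the meta-linguistic bank by
default because it is too ambiguous for surface matching; pass
``include_like=True`` to opt in.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "ELEMENTS",
    "BANK_ELEMENTS",
    "WordBank",
    "load_bank",
    "load_default_banks",
    "bank_contains",
]

#: Canonical order of the six microstructure elements.
ELEMENTS = (
    "coordinating_conjunction",
    "subordinating_conjunction",
    "metalinguistic_verb",
    "metacognitive_verb",
    "adverb",
    "elaborated_noun_phrase",
)

#: The four elements scored by word-bank matching.
BANK_ELEMENTS = ELEMENTS[:4]


@dataclass(frozen=True)
class WordBank:
    """A named set of lowercase word forms for one bank-matched element."""

    element: str
    entries: frozenset[str]

    def __post_init__(self) -> None:
        if self.element not in BANK_ELEMENTS:
            raise ValueError(f"not a bank element: {self.element!r}")
        if not self.entries:
            raise ValueError(f"bank for {self.element} is empty")
        for w in self.entries:
            if w != w.lower() or any(c.isspace() for c in w):
                raise ValueError(f"bad bank entry {w!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.entries


def _read_wordlist(fh) -> frozenset[str]:
    words = set()
    for line in fh:
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return frozenset(words)


def load_bank(
    element: str,
    override_path: str | Path | None = None,
    include_like: bool = False,
) -> WordBank:
    """Load the built-in default bank for ``element``, or an override file.

    Override files are plain text, one word per line, ``#`` comments allowed;
    entries are lowercased and deduplicated. An empty override file is a
    configuration error.
    """
    if override_path is not None:
        with open(override_path, encoding="utf-8") as fh:
            entries = _read_wordlist(fh)
        if not entries:
            raise ValueError(f"override bank file {override_path} is empty")
    else:
        ref = resources.files("litlang.data.banks") / f"{element}.txt"
        with ref.open(encoding="utf-8") as fh:
            entries = _read_wordlist(fh)
        if include_like and element == "metalinguistic_verb":
            entries = entries | {"like", "likes", "liked"}
    return WordBank(element=element, entries=frozenset(entries))


def load_default_banks(
    overrides: dict[str, str | Path] | None = None,
    include_like: bool = False,
) -> dict[str, WordBank]:
    """Load all four banks, enforcing pairwise disjointness.

    ``overrides`` maps element name to a replacement bank file; the other
    elements keep their defaults.
    """
    overrides = overrides or {}
    banks = {
        el: load_bank(el, overrides.get(el), include_like=include_like)
        for el in BANK_ELEMENTS
    }
    seen: dict[str, str] = {}
    for el, bank in banks.items():
        for w in bank.entries:
            if w in seen:
                raise ValueError(
                    f"banks must be disjoint: {w!r} in both {seen[w]} and {el}"
                )
            seen[w] = el
    return banks


def bank_contains(bank: WordBank, token: str) -> bool:
    """Exact whole-word membership test; no stemming, case must be lower."""
    return token in bank
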