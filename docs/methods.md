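# Methods

## Scoring model

The package scores the six literate-language elements of the MISL
microstructure rubric from a cleaned transcript. The unit of analysis is the
transcript; the unit of segmentation is the communication unit (C-unit), one
per transcript line, taken as given — no re-segmentation is attempted,
because SALT-convention transcripts arrive already segmented and plain-text
input is defined as one utterance per line.

**Cleaning.** Parenthesized maze spans (repetitions, false starts,
revisions), including nested spans, are deleted whole; square-bracket codes
and annotation sigils are stripped; SALT bound-morpheme markers collapse to
the surface form (`go/ed` → `goed` — grammatical errors are never
corrected, since errorful forms are what the child produced);
unintelligibility marks (`x`/`xx`/`xxx`) are dropped; tokens are lowercased.
Utterances that come out empty are removed and the rest re-indexed. Cleaning
is idempotent and never increases the token count. An unmatched `(` is
recovered by extending the maze to the end of the utterance with a warning
rather than aborting: a progress-monitoring tool must survive a typo. The
maze rule removes the parenthesized *span*, not the whole utterance
containing it; mazes are sub-utterance disfluencies and the fluent remainder
is still the child's language.

**Bank elements.** Coordinating conjunctions, subordinating conjunctions,
meta-linguistic verbs and meta-cognitive verbs are matched by exact surface
form against editable word-bank files. "Unique instances" means distinct
word *types*, not tokens: ten uses of *and* demonstrate one coordinator
type. Inflections are enumerated in the bank rather than recovered by
lemmatization — matching stays auditable, at the cost of missing
overgeneralized irregulars (*sayed*). The four banks must be pairwise
disjoint, enforced at load time. The coordinating bank is exactly the seven
FANBOYS words; *then* is excluded (it is an adverb, and counting it as a
coordinator would double-count across elements — some rubric examples do
list it with *and*, so the bank file documents the choice and users can
override it). The quotative *like* is excluded from the meta-linguistic bank
by default because surface matching cannot distinguish it from the
preposition; `include_like_metalinguistic: true` opts in. The
subordinating/meta-linguistic/meta-cognitive defaults target the child
register at roughly ages 5–10; they are a curated approximation and ship as
data files precisely so users can extend them.

**Habitual openers.** For every maximal run of ≥ 3 consecutive utterances
whose first token is the same coordinating bank word, the utterance-initial
occurrences of that word across the whole run are suppressed (a run of four
suppresses all four). Mid-utterance occurrences inside the run still count:
there the conjunction joins constituents and is doing connective work. The
run threshold of 3 mirrors the rubric's "three consecutive clauses" rule;
"clause" is operationalized as utterance. A stricter variant that suppresses
*every* occurrence of the opener word inside the run's utterances is
available as `opener_exclusion: whole_run` (default `initial`), since the
rule's published phrasing does not settle which reading the original
scorers used.

**Adverbs.** Distinct word types whose tagged class maps to adverb (Penn
RB/RBR/RBS), capped at 3. Uniqueness is by word type alone: *fast* tagged
adjective in one utterance does not block *fast* counting once as an adverb
elsewhere. Wh-adverbs (WRB: *when*, *where*) deliberately map to OTHER so
interrogatives and subordinators are not double-counted as adverbs.

**Elaborated noun phrases.** Admissible modifiers are determiners,
possessive pronouns, numbers, adjectives, and adverbs immediately preceding
an adjective. The slot template, read left-to-right, is

    [DET | POSS]? [NUM]? ([ADV]? ADJ)* NOUN

For each noun, the matcher extends leftward greedily; extension stops at the
first ordering violation, keeping the grammatical sub-span (*silly the
girl*: *the girl* counts one modifier; the stranded adjective never makes it
two). Nouns are processed rightmost-first within an utterance and each token
joins at most one match, which makes overlap resolution deterministic. The
transcript's ENP score is the **maximum** modifier count over all matches
(the longest combination determines the level), capped at 3; 0 means every
noun is bare. "Pronoun" modifiers are restricted to possessives (*my, his,
their*): *his big dog* is elaborated, *he big dog* is not grammatical, so
admitting personal pronouns as modifiers would reward an error.

## Tagging

The scorers consume word classes (NOUN, ADJECTIVE, ADVERB, DETERMINER,
NUMBER, PRONOUN_POSSESSIVE, VERB, OTHER) mapped deterministically from Penn
Treebank tags. Tagging always sees the whole utterance — never isolated
words — because class-ambiguous words (*like*, *fast*, *so*) are exactly the
ones that matter.

The default backend `rule-en-child` (v1.0) is a hand-built deterministic
tagger: a closed-class lexicon, ~500 open-class child-register words, suffix
heuristics for out-of-vocabulary forms (*-ly* → RB, *-ed* → VBD, *-ing* →
VBG, plural/3sg *-s* resolved against the noun/verb lexicons), and a small
set of context rules for the ambiguous words that affect scoring (*fast*
before a noun is JJ, after a verb RB; *so* before an adjective is a degree
adverb, else a coordinator; utterance-initial *there* before *be* is
existential; particles like *down*/*out* are prepositions before a nominal,
adverbs otherwise). Unknown words default to noun — the conservative choice
for ENP, since a spurious adverb or adjective would inflate scores. The
backend is pluggable (`register_tagger`) behind a two-method protocol, and
the backend name+version is written into every score report sidecar so runs
are reproducible; tagging identical input is bit-identical by construction.
A statistical tagger trained on adult newspaper text would behave
differently on child narratives in both directions; tagger-induced error is
the known dominant error source for the adverb and ENP elements, which is
why those two elements carry a tolerance in the round-trip acceptance test
while the bank elements must round-trip exactly.

## Agreement machinery

Quadratic weighted kappa is computed from the observed joint proportion
matrix O, the chance matrix E (outer product of marginals), and weights
W[i,j] = (i−j)²/(k−1)²:  κ_qw = 1 − Σ(W∘O)/Σ(W∘E). Choices:

- **Fixed category domain {0,1,2,3}.** The rubric's scale is 0–3 by
  construction, so k = 4 regardless of which scores a sample happens to
  contain. Note the subtlety: dropping an *unobserved edge* category leaves
  κ_qw unchanged (the (k−1)² normalization cancels in the ratio), so the
  fixed domain is observable only when observed categories are
  non-contiguous — an inferring implementation would relabel {0,1,3}
  contiguously and change the statistic — and in degenerate cases. Both
  facts are asserted in the tests.
- **Degenerate marginals.** If both raters are constant and identical,
  Σ(W∘E) = 0; the result is reported as κ = 1 with a `degenerate` flag
  rather than NaN — constant perfect agreement *is* perfect agreement, and
  the flag preserves honesty.
- **Negative kappa.** The standard definition can go below 0 (worse than
  chance); it is implemented as such and documented rather than clamped,
  although practical rater pairs on this rubric land in [0, 1].
- **Partial id overlap** between two score tables is inner-joined with a
  warning; zero overlap is an error. Clinical workflows have stragglers.

The per-transcript error measure is the total absolute difference across
the six elements (range 0–18); `error_by_group` reports median and IQR per
group label, the robust summary appropriate for small, skewed error
distributions.

## Synthetic corpus generator

The generator emulates the structure of an elicited school-age narrative
corpus: story lengths drawn from a normal(13.2, 7.6) clipped to 1–41
utterances (never below the feasible minimum for the requested elements);
SALT header and speaker codes with an occasional examiner turn; mazes
inserted at a configurable rate (default 0.3 of utterances) containing only
filler words; ~30% of eligible tokens spelled with bound-morpheme markers
(`duck/s`); an optional habitual-opener run (default probability 0.25 per
story) prepended as three `and`-initial utterances. Target scores default to
uniform over 0–3 per element, mirroring a corpus curated to cover every
score level.

Each requested element instance rides one short carrier clause built from a
**tagger-safe vocabulary pool** — bare plural nouns, unambiguous past-tense
verbs, *-ly* adverbs, color/size adjectives — chosen so the pinned tagger's
class assignment is stable and, critically, so that inserting a conjunction
never perturbs the adverb count (the pools avoid *so*, *yet*, *therefore*,
*then*, which tag as adverbs). Bank words are placed non-utterance-initially
so the opener rule cannot touch them. All other clauses use bare plural
subjects, so the ENP carrier's modifier count is the transcript maximum by
construction. Mazes cannot move scores because scoring happens after
cleaning removes them.

Generation is deterministic: one seeded generator per transcript, corpus
per-transcript seeds derived as `seed + index`. What passing round-trip
tests show is that the scorer inverts the generator *on this controlled
vocabulary*; they do not show tagger accuracy on real child speech, where
out-of-vocabulary words, overgeneralized verb forms and genuinely ambiguous
usage will add error, concentrated in the adverb and ENP elements. The
generator also makes no attempt at story grammar, referential coherence, or
age-conditioned vocabulary growth — its realism is structural, not
narrative.

## Problem sizes and numerical choices

The test suite and the acceptance script exercise: the full 4⁴ = 256 grid of
bank-element target combinations (1,024 element comparisons), a 256-story
ENP/adverb grid (512 comparisons, pass threshold 95%), 500 stories for the
cleaning properties at maze rate 0.3, 1,000 random 50-length score pairs for
kappa (brute-force agreement tolerance 1e−12, matching the float64 scale of
the computation), and a 50-story scored corpus — the size of a typical
validation sample for this kind of instrument. All scorer arithmetic is
integer; kappa uses float64 throughout with no iterative steps, so no
initialization or convergence choices arise. Ties in ENP matching are
resolved structurally (rightmost noun, longest extension) rather than by
score, so scoring has no randomness at all.

## Known limitations

- Bank matching is surface-form only: overgeneralized irregulars (*sayed*,
  *thinked*) and the quotative *like* are missed by default.
- The bundled tagger's lexicon targets ages ~5–10 narrative vocabulary;
  unknown words default to noun, so rich adult vocabulary will under-count
  adverbs and adjectives. The backend is pluggable for exactly this reason.
- No macrostructure (story grammar) scoring, no MLU/NDW descriptives, no
  CHAT/CLAN dialect, no audio or ASR front end.
- The ENP score reports the single longest noun phrase; transcripts rich in
  mid-level noun phrases score the same as one with a single long phrase.
  This follows the rubric's level definitions, but is a real compression.
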