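# litlang

Automated scoring of **literate language** in child narrative language
samples, for speech-language pathologists and child-language researchers who
use language sample analysis (LSA) for assessment and progress-monitoring.

A child's fictional narrative is transcribed (SALT conventions or plain
text, one utterance per line) and scored on the six microstructure elements
of the MISL (Monitoring Indicators of Scholarly Language) rubric, each on a
0–3 scale:

| element | what counts | scored by |
|---|---|---|
| coordinating conjunctions | *and, but, or, …* joining clauses | word bank + habitual-opener rule |
| subordinating conjunctions | *because, when, although, …* | word bank |
| meta-linguistic verbs | verbs of dialogue (*said, yelled*) | word bank |
| meta-cognitive verbs | verbs of thought (*wondered, decided*) | word bank |
| adverbs | words POS-tagged as adverbs | rule-based tagger |
| elaborated noun phrases (ENP) | modifiers preceding a noun (*the big green frog*) | tagger + slot grammar |

For the first five elements the score is the number of **distinct word
types** used anywhere in the transcript, capped at 3 (0 = none, 3 = three or
more). ENP is scored by the largest number of admissible modifiers preceding
any noun, using the ordering template

    [determiner | possessive]? [number]? ([adverb]? adjective)* noun

truncated at the first ordering violation (*silly the girl* yields at most
*the girl*, one modifier). Coordinating conjunctions apply the
**habitual-opener rule**: when three or more consecutive utterances open
with the same coordinator ("And then… And then… And…") those
utterance-initial tokens are suppressed — filler, not connective. The total
is out of 18.

To validate an automated (or human) scorer against reference scores, the
package computes the **quadratic weighted kappa** per element over a corpus:

    κ_qw = 1 − Σᵢⱼ wᵢⱼ Oᵢⱼ / Σᵢⱼ wᵢⱼ Eᵢⱼ ,   wᵢⱼ = (i − j)² / (k − 1)²

with O the observed joint score distribution, E = outer product of the
marginals, and the category domain fixed at k = 4 (scores 0–3), so a
three-point disagreement costs nine times a one-point disagreement. A
per-transcript total-absolute-difference (0–18) with grouped median/IQR
summaries supports error profiling (e.g., by age band).

Because scored corpora of child narratives are rarely shareable, the package
includes a synthetic-corpus generator that writes SALT-dialect stories
(1–41 utterances, mazes, morpheme markers, habitual-opener runs) with
ground-truth scores known by construction, built from vocabulary whose
part-of-speech is stable under the bundled tagger.

## Worked example

`python examples/01_score_a_transcript.py` scores a six-utterance story and
prints:

```
cleaned utterances:
  [0] once there was a big purple alien
  [1] the alien landed his spaceship quickly
  ...
scores (0-3 each):
  coordinating_conjunction   3   evidence: ['and', 'but', 'so']
  subordinating_conjunction  2   evidence: ['because', 'if']
  metalinguistic_verb        2   evidence: ['told', 'yelled']
  metacognitive_verb         2   evidence: ['decided', 'wondered']
  adverb                     3   evidence: ['once', 'quickly', 'then', 'there']
  elaborated_noun_phrase     3   evidence: ['a big purple alien']
  total (0-18)               15
```

The maze `(um uh)` and the examiner's turn contribute nothing; `land/ed`
surfaces as *landed*; three distinct coordinators, two subordinators, two
dialogue verbs, two thought verbs, four adverb types (capped at 3), and a
three-modifier noun phrase give 15/18.

Other examples: `02_habitual_openers.py` (the opener-suppression rule),
`03_agreement_analysis.py` (kappa + error profile on a 50-story corpus),
`04_simulate_corpus.py` (fixture generation).

## Command line

```sh
litlang simulate --n 50 --seed 7 --out corpus/ --truth truth.csv
litlang score corpus/ --dialect salt --out scores.csv --evidence audit.jsonl
litlang agree --pred scores.csv --ref truth.csv --out report.csv
```

`score` writes one CSV row per transcript
(`id,coord_conj,subord_conj,metaling_verb,metacog_verb,adverb,enp,total`)
plus a metadata sidecar (tool version, tagger, bank hashes); corrupt files
are skipped with a warning, never abort the batch. Word banks are plain text
files overridable per element via `--config` (see `docs/methods.md`).

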