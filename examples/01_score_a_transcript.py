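"""Score one narrative transcript for the six literate-language elements.

Builds a small SALT-convention story (speaker codes, a maze, a bound-morpheme
marker), cleans it, and prints each element's 0-3 score with its evidence.
"""

from pathlib import Path
import tempfile

from litlang import (
    clean_transcript,
    get_tagger,
    load_default_banks,
    read_transcript,
    score_transcript,
)

STORY = """\
$ Child, Examiner
C once there was a big purple alien .
C (um uh) the alien land/ed his spaceship quickly .
C he saw two little boy/s and wondered if they were friendly .
C but the boy/s yelled because they were scared .
C so the alien decided to fly home .
E what happened next ?
C then he told his mom about the whole thing .
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "alien_story.slt"
    path.write_text(STORY, encoding="utf-8")
    raw = read_transcript(path, dialect="salt")
    clean = clean_transcript(raw)

print("cleaned utterances:")
for utt in clean.utterances:
    print(f"  [{utt.index}] {' '.join(utt.tokens)}")

result = score_transcript(clean, load_default_banks(), get_tagger())
print("\nscores (0-3 each):")
for s in result.scores:
    types = sorted({tok for _, tok in s.evidence})
    print(f"  {s.element:26s} {s.score}   evidence: {types}")
print(f"  {'total (0-18)':26s} {result.total}")

# The maze "(um uh)" and the examiner line contribute nothing; "land/ed"
# surfaces as "landed". Each score is the number of distinct types used
# (for ENP, the longest modifier string before a noun), capped at 3.
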