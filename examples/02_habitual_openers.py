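"""The habitual-opener rule for coordinating conjunctions.

A child who opens three or more consecutive utterances with the same
coordinating conjunction is using it as a filler, not a connective; those
utterance-initial occurrences are suppressed from the count. Mid-utterance
uses still count.
"""

from litlang import load_default_banks, score_coordinating
from litlang.transcript_io import CleanTranscript, Utterance


def ct(*lines):
    return CleanTranscript(
        "demo", tuple(Utterance(i, tuple(l.split())) for i, l in enumerate(lines))
    )


bank = load_default_banks()["coordinating_conjunction"]

passage = ct(
    "i went to the store",
    "and then i bought groceries",
    "and then i went home",
    "and i put the groceries away",
)
print("habitual-opener passage        ->",
      score_coordinating(passage, bank).score)
# -> 0: all three "and" are utterance-initial inside a run of >= 3.

two_openers = ct("and he ran", "and he fell", "then he got up")
print("only two consecutive openers   ->",
      score_coordinating(two_openers, bank).score)
# -> 1: a run of two is below the threshold, so "and" still counts.

mid_use = ct("and he ran", "and he hid", "and he ran and jumped")
print("mid-utterance use inside a run ->",
      score_coordinating(mid_use, bank).score)
# -> 1: the three utterance-initial "and" are suppressed, but the fourth
#    "and" joins two verbs mid-utterance and survives.
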