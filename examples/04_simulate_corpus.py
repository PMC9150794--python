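"""Generate a synthetic SALT corpus with known ground-truth scores.

Equivalent to `litlang simulate --n 4 --seed 11 --out DIR --truth truth.csv`,
showing what the generated files look like.
"""

from litlang import FixtureSpec, generate_corpus, generate_transcript

fixtures, truth = generate_corpus(n=4, seed=11, maze_rate=0.4)
print("ground truth:")
print(truth.frame.to_string(index=False))

raw, scores = fixtures[0]
print(f"\n{raw.transcript_id} ({len(raw.lines)} lines):")
for code, text in raw.lines:
    print(" ", text if code == "$" else f"{code} {text}")

# A fully controlled single story: exactly 2 coordinating types, 1
# subordinator, 3 dialogue verbs, 0 thought verbs, 2 adverbs, and a noun
# phrase with 3 modifiers, plus a habitual-opener run the scorer must ignore.
spec = FixtureSpec(
    "demo", target_scores=(2, 1, 3, 0, 2, 3),
    habitual_opener=True, maze_rate=0.3, seed=5,
)
raw, truth_one = generate_transcript(spec)
print(f"\ncontrolled story (targets {spec.target_scores}):")
for code, text in raw.lines:
    print(" ", text if code == "$" else f"{code} {text}")
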