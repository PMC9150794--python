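"""Validate an automated scorer against reference scores with weighted kappa.

Generates a 50-story synthetic corpus with known ground truth, scores it,
then reports the quadratic weighted kappa per element and the total-absolute-
difference error profile by (synthetic) age band.
"""

import numpy as np

from litlang import (
    clean_transcript,
    error_by_group,
    generate_corpus,
    get_tagger,
    load_default_banks,
    per_element_agreement,
    score_transcript,
)
from litlang.agreement import ScoreTable, table_total_differences

banks, tagger = load_default_banks(), get_tagger()
fixtures, truth = generate_corpus(n=50, seed=7)

rows = [
    score_transcript(clean_transcript(raw), banks, tagger).as_row()
    for raw, _ in fixtures
]
pred = ScoreTable.from_rows("automated", rows)

print("quadratic weighted kappa vs ground truth (k=4 categories):")
for r in per_element_agreement(pred, truth):
    print(f"  {r.element:26s} kappa_qw = {r.kappa_qw:.3f}  (n={r.n})")
# 1.000 everywhere: on the tagger-safe synthetic vocabulary the scorer
# recovers the construction targets exactly. Real transcripts tag noisier.

diffs = table_total_differences(pred, truth)
rng = np.random.default_rng(7)
bands = rng.choice(["5;0-7;11", "8;0-9;11"], size=len(diffs))
profile = error_by_group(list(zip(bands, diffs["total_diff"])))
print("\ntotal |difference| (0-18) by age band:")
print(profile.to_string(index=False))
# median/IQR per band: the shape of an error profile used to ask whether
# scoring error drifts with narrator age.
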