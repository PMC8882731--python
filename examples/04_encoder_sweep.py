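"""Benchmark every encoder x classifier combination by cross-validation.

On synthetic data with positional enrichment, the position-aware
encodings (One-hot1/2) should clearly outrank the density-based (AMNF,
ADNF) and property-based (DPCP, TPCP) ones for every classifier — the
signal is in where nucleotides sit, not in how many there are.

Runs a deliberately small sweep (n=300, 3 folds) so it finishes in about
half a minute.
"""

import methylvote as mv
from methylvote.ensemble import default_specs

data = mv.generate(mv.SyntheticSpec(150, 150, mv.default_profile(0.5), seed=3))
table = mv.sweep(data, list(mv.ENCODER_NAMES), default_specs(3),
                 folds=3, seed=3)
print(table.round(3))
acc = table.xs("ACC", level="metric")
best = acc.idxmax(axis=1)
print("\nbest encoder per classifier (by mean CV accuracy):")
print(best.to_string())
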