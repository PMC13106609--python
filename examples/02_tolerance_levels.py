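"""Cluster the published CI values into four tolerance levels.

Loads the packaged comprehensive-index table for the 48 accessions and
cuts an agglomerative tree (Euclidean distance, average linkage) at four
groups: level I is the extremely tolerant class, level IV the highly
sensitive one. Also shows how sensitive the 1-D partition is to the
linkage choice.
"""

import pandas as pd

import heliotol as ht

df = ht.load_fixture("ci_ranking")
ci = pd.Series(df["ci"].to_numpy(), index=df["name"].to_numpy())

levels = ht.classify_tolerance(ci, k=4)  # default: average linkage
print("tolerance levels (average linkage):")
print(levels.summary.round(3).to_string(index=False))
print("\nlevel I member(s):",
      ", ".join(levels.assignments.query("level == 'I'")["genotype"]))

ward = ht.classify_tolerance(ci, k=4, method="ward")
print("\nsame CI values under Ward linkage:", ward.counts())
print("(the four-group partition of a 1-D score is linkage-sensitive; "
      "average linkage is the package default)")
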