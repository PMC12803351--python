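"""Pairwise mutual information and repertoire groups across genomes.

Builds a binary genome x trait presence matrix (transporter families +
pathway completeness) and reports the trait co-occurrence structure.
"""

import pandas as pd

from sugartrait import (
    TransporterCensus,
    build_presence_matrix,
    pairwise_mi,
    repertoire_groups,
)

censuses = [
    TransporterCensus("ec", 9, 5, 2),   # Pseudomonadota-like: ABC + PTS
    TransporterCensus("ef", 7, 6, 0),
    TransporterCensus("bt", 0, 1, 8),   # Bacteroidota-like: MFS, no ABC
    TransporterCensus("bf", 0, 0, 6),
    TransporterCensus("bl", 12, 0, 3),  # Actinomycetota-like: ABC + MFS
    TransporterCensus("am", 0, 2, 1),
]
pathways = {
    "ec": {"EMP": 1, "ED": 1},
    "ef": {"EMP": 1, "ED": 0},
    "bt": {"EMP": 1, "ED": 0},
    "bf": {"EMP": 1, "ED": 0},
    "bl": {"EMP": 0, "ED": 0},
    "am": {"EMP": 1, "ED": 0},
}

mat = build_presence_matrix(censuses, pathways)
print("presence matrix:")
print(mat.to_string())

mi = pairwise_mi(mat)
print("\npairwise mutual information (bits; diagonal = trait entropy):")
print(mi.round(3).to_string())

groups = repertoire_groups(mat)
print("\ntransporter repertoire groups (combination -> members):")
for combo, members in groups["groups"].items():
    print(f"  {'+'.join(combo) or '(none)'}: {members}")
print()
print("High MI between two traits means knowing one strongly predicts the")
print("other across genomes; 0 bits means they vary independently.")
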