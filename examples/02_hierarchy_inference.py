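"""Infer a monthly hierarchy from dyadic agonistic bouts.

Builds a win-loss matrix from a handful of observed bouts (including one
upset) and finds the ordering that minimizes the number of bout outcomes
falling below the matrix diagonal.
"""

import pandas as pd

from domrank import build_winloss_matrix, count_inconsistencies, order_hierarchy

bouts = pd.DataFrame(
    [
        ("2000-01-03", "G1", "F", "vee", "ash"),
        ("2000-01-05", "G1", "F", "vee", "lou"),
        ("2000-01-09", "G1", "F", "ash", "lou"),
        ("2000-01-12", "G1", "F", "ash", "kit"),
        ("2000-01-15", "G1", "F", "lou", "kit"),
        ("2000-01-21", "G1", "F", "kit", "vee"),  # an upset
    ],
    columns=["date", "group", "sex", "winner", "loser"],
)

matrix = build_winloss_matrix(bouts, period="2000-01", group="G1", sex="F")
print("win-loss matrix (rows = winners):")
print(matrix.to_frame())

ordering = order_hierarchy(matrix)
print("\ninferred order:", " > ".join(ordering.ranked_ids))
print("inconsistencies (bouts won by the lower-ranked):", ordering.inconsistencies)
print("reversed order would give:",
      count_inconsistencies(matrix, ordering.ranked_ids[::-1]))
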