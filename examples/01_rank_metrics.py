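"""Ordinal vs proportional rank when a hierarchy grows.

Five males hold ordinal ranks 1-5; four more then join at the bottom.
Ordinal ranks of the originals are unchanged, but their proportional ranks
(the fraction of others they outrank) all rise except the alpha's.
"""

from domrank import HierarchyOrdering, rank_table

five = HierarchyOrdering("2000-01", "G1", "M", ["A", "B", "C", "D", "E"], 0)
nine = HierarchyOrdering(
    "2000-02", "G1", "M", ["A", "B", "C", "D", "E", "F", "G", "H", "I"], 0
)

table = rank_table([five, nine])
originals = table[table["individual"].isin(list("ABCDE"))]
print(originals.pivot(index="individual", columns="period", values="proportional"))
print()
print("Male E holds ordinal rank 5 in both months, yet his proportional")
print("rank moves from 0.0 to 0.5 — whether that is 'a major rank change'")
print("depends on whether his competition is density-dependent or not.")
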