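"""Align two accented pronunciations of 'Wednesday' with plain and
sensitive segment costs.

The unit-cost alignment counts edit operations; the weighted alignment uses
a hand-specified cost table in which acoustically close segments are cheap.
"""

from ndldist import GAP, SegmentCostTable, align

a = list("wεnzdeI")
b = list("wεnʔsde")  # the second speaker inserts a segment and drops the final one

unit = align(a, b)
print("unit-cost alignment (total = classic edit distance):")
for (x, y), c in zip(unit.pairs, unit.costs):
    print(f"  {x}\t{y}\t{c:g}")
print(f"  total = {unit.total:g} edit operations\n")

costs = SegmentCostTable({("ʔ", GAP): 0.031, ("z", "s"): 0.020, ("I", GAP): 0.030}, default=1.0)
weighted = align(a, b, costs)
print(f"sensitive-cost total = {weighted.total:.3f}")
print("(small numbers: the three edits involve similar or weak segments,")
print(" so the weighted distance is a fraction of the 3 unit operations)")
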