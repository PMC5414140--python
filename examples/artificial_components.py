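"""Outlier detection on artificial 3D principal components.

Reproduces the two small worked examples: two normal groups with one planted
point per group three sigma beyond its group center, and a skewed example
with exponential components where one planted point is visible only in the
third component.  Shows how the 2D bagplot union and the 3D gemplot flag
different samples.
"""

import depthqc as dq

# --- example 1: N(-3,1)^3 vs N(3,1)^3, planted at (-6,-6,-6) and (6,6,6)
data = dq.make_example1(seed=1)
rep2 = dq.detect_2d(data.matrix, data.labels)
rep3 = dq.detect_nd(data.matrix, data.labels, 3)
print("example 1 (well-separated normal groups)")
print(f"  planted    : {sorted(data.truth_ids)}")
for name, rep in (("2D union ", rep2), ("3D gemplot", rep3)):
    for group, flags in rep.flags.items():
        print(f"  {name} {group}: {sorted(flags) or '-'}")

# --- example 2: skewed components; (3,4,25) is extreme only on z3
data = dq.make_example2(seed=1)
rep12 = dq.detect_2d(data.matrix, data.labels, pairs=[(1, 2)])
rep3 = dq.detect_nd(data.matrix, data.labels, 3)
print("\nexample 2 (exponential components)")
print(f"  planted              : {sorted(data.truth_ids)}")
print(f"  PC1xPC2 bagplot only : "
      f"{sorted(rep12.all_flagged() & data.truth_ids) or '-'} "
      f"(misses the point at (3,4,25))")
print(f"  3D gemplot           : {sorted(rep3.all_flagged() & data.truth_ids)}")

# The point planted at (3, 4, 25) is unremarkable in its first two
# coordinates, so the PC1 x PC2 bagplot cannot see it; the gemplot works in
# all three components at once and flags it.
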