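"""Test an observed F2 phenotype ratio against recessive 1:3 segregation.

A cross of a double mutant to the wild type yielded 120 F2 plants of which
29 showed the mutant dwarfism.  If a single recessive locus controls the
phenotype, one quarter of the F2 should be mutant; the chi-square below
measures the departure from 1:3 (with the continuity correction appropriate
for a two-class test).
"""

from mutpool import SegregationCounts, chi_square_segregation

counts = SegregationCounts(observed=(29, 91), expected_ratio=(1, 3),
                           labels=("mutant", "non-mutant"))
res = chi_square_segregation(counts)

print(f"observed 29:91 against 1:3 (Yates correction: {res.yates})")
print(f"chi-square = {res.statistic:.3f}  df = {res.degrees_of_freedom}  "
      f"P = {res.p_value:.3f}")
print("A statistic this small (P near 1) means the ratio is fully consistent")
print("with one recessive causal locus.")
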