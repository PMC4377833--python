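"""Reclassify the packaged published call matrices and score each marker.

Two cohorts ship with the package: 44 colorectal tumours with matched
normals over five markers, and 6 tumour-only cases over BAT25/BAT26. This
script recomputes each sample's overall MSI status from its per-locus
calls, then scores every marker against overall MSI-H status with exact
95% binomial confidence intervals.
"""

from msiamp import (cohort_summary, locus_vs_locus, locus_vs_overall,
                    series1_matrix, series2_matrix)
from msiamp.evaluate import round_half_up as r1

m1, m2 = series1_matrix(), series2_matrix()

for name, m in (("series 1 (paired, 5 markers)", m1),
                ("series 2 (tumour-only, 2 markers)", m2)):
    s = cohort_summary(m)
    counts = ", ".join(f"{k.value}: {v}" for k, v in s.counts.items())
    print(f"{name}: {counts}  "
          f"[{len(m) - len(s.discrepancies)}/{len(m)} rows match the "
          f"recorded status]")

print("\nD5S346 against its own capillary-PCR calls:")
d5 = locus_vs_locus(m1, "D5S346")
print(f"  sensitivity {r1(d5.sensitivity)}%  specificity "
      f"{r1(d5.specificity)}%  (fn={d5.fn}, fp={d5.fp})")

print("\nEach marker against overall MSI-H status "
      "(sens / spec, 95% CI lower bounds):")
for locus, matrices in (("BAT25", [m1, m2]), ("BAT26", [m1, m2]),
                        ("BAT34c4", [m1]), ("D18S55", [m1]),
                        ("D5S346", [m1])):
    cs = locus_vs_overall(matrices, locus)
    print(f"  {locus:<8} {r1(cs.sensitivity):>6}% / "
          f"{r1(cs.specificity):>6}%   "
          f"(CI lo {r1(cs.sens_ci[0])} / {r1(cs.spec_ci[0])}, "
          f"n={cs.n})")
print("\nMononucleotide markers predict MSI-H perfectly; dinucleotide "
      "markers miss roughly half\nof MSI-H tumours but rarely fire in "
      "stable ones.")
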