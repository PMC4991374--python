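"""Printed-parameter replication: the six overlap tests from set sizes alone.

The overlap-enrichment statistics depend only on (m, n, k, N), all of which
are printed numbers, so the tests can be recomputed without any input files:
six comparisons of a 109-gene direct-target list (95 after exclusions in the
DamID case) against independent gene sets, in a 20000-gene universe.
"""

from foxotarget import HypergeomParams, expected_overlap, hypergeom_upper_tail

COMPARISONS = [
    ("microarray-514", 514, 109, 18),
    ("microarray-3396", 3396, 109, 31),
    ("proteomics-86", 86, 109, 12),
    ("DamID-65", 65, 95, 6),
    ("longevity-genes-681", 681, 109, 17),
    ("dietary-restriction-48", 48, 109, 4),
]

print(f"{'comparison':<24}{'m':>6}{'n':>5}{'k':>4}{'expected':>10}{'p':>12}")
for label, m, n, k in COMPARISONS:
    expected = expected_overlap(m, n, 20000)
    p = hypergeom_upper_tail(HypergeomParams(N=20000, m=m, n=n, k=k))
    print(f"{label:<24}{m:>6}{n:>5}{k:>4}{expected:>10.2f}{p:>12.2E}")

print()
print("Every observed overlap k far exceeds its random-chance baseline")
print("m*n/N; the largest p-value is 1.9E-3 and four comparisons fall")
print("below 1E-6 (printed as 0 at reporting precision).")
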