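"""Audic-Claverie differential test between two sequencing libraries.

Shows the p-value for a tag observed x times in a library of n1 reads and
y times in a library of n2 reads, and how the test sharpens with depth.
"""

from evmir import audic_claverie_pvalue

n1, n2 = 12_771_308, 15_367_876  # miRNA-assigned reads of two libraries

print("x (lib1)  y (lib2)  two-sided p")
for x, y in [(10, 10), (10, 25), (100, 250), (1000, 2500)]:
    p = audic_claverie_pvalue(x, y, n1, n2)
    print(f"{x:8d}  {y:8d}  {p:.3e}")

print("\nsame 2.5-fold ratio, increasing counts: p shrinks with depth")
for scale in (1, 10, 100):
    p = audic_claverie_pvalue(10 * scale, 25 * scale, n1, n2)
    print(f"  x={10 * scale:5d} y={25 * scale:5d}  p={p:.3e}")
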