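"""Numerator relationship matrix A and its Henderson inverse.

A small pedigree with a full-sib mating illustrates the textbook values:
parent-offspring relationship 0.5 and an inbred animal with F = 0.25.
"""

import numpy as np

from funcblup import Pedigree, build_a_inverse, build_a_matrix, inbreeding

ped = Pedigree([
    ("p1", "0", "0"),
    ("p2", "0", "0"),
    ("c1", "p1", "p2"),
    ("c2", "p1", "p2"),
    ("x", "c1", "c2"),   # offspring of a full-sib mating
])

a = build_a_matrix(ped)
ainv = build_a_inverse(ped)

print("A =")
print(np.round(a.dense(), 3))
print("relationship(p1, c1) =", a.dense()[0, 2], " (parent-offspring: 0.5)")
print("inbreeding of x      =", inbreeding(ped)[4], " (full-sib mating: 0.25)")
err = np.abs(a.dense() @ ainv.dense() - np.eye(len(ped))).max()
print(f"max |A A^-1 - I| = {err:.2e}  (Henderson's rules agree with the dense inverse)")
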