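"""Build the additive relationship matrix A from a pedigree.

A_ij is twice the coancestry of i and j: 0.5 for parent-offspring and
full sibs, 0.25 for half sibs, 1 + F on the diagonal.  A is the
covariance structure of the polygenic effect in the animal model.
"""

import mmra

ped = mmra.Pedigree(
    ids=["sire", "dam1", "dam2", "fullsib1", "fullsib2", "halfsib"],
    sire=["0", "0", "0", "sire", "sire", "sire"],
    dam=["0", "0", "0", "dam1", "dam1", "dam2"])
A = mmra.build_A(ped)

pairs = [("sire", "fullsib1"), ("fullsib1", "fullsib2"),
         ("fullsib1", "halfsib"), ("dam1", "dam2")]
idx = {name: i for i, name in enumerate(ped.ids)}
for a, b in pairs:
    print(f"A[{a}, {b}] = {A[idx[a], idx[b]]:.2f}")
print(f"inbreeding coefficients: {mmra.inbreeding(ped)}")
# Expected: parent-offspring 0.50, full sibs 0.50, half sibs 0.25,
# unrelated founders 0.00, and F = 0 everywhere in a two-generation design.
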