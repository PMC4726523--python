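"""Enumerate the second-order social norms and their mirror classes.

A second-order norm maps (recipient reputation, donor action) to the donor's
new reputation, so there are 2^4 = 16 pure norms; swapping the Good/Bad
labels (which carry no intrinsic meaning) pairs them into 10 equivalence
classes.  Four norms have standard names: stern judging (SJ), simple
standing (SS), shunning (SH) and image scoring (IS).
"""

from irdyn import enumerate_pure_norms, equivalence_classes, mirror, named_norm

norms = enumerate_pure_norms()
classes = equivalence_classes()
print(f"{len(norms)} pure second-order norms, {len(classes)} mirror classes\n")

for name in ("SJ", "SS", "SH", "IS"):
    n = named_norm(name)
    partner = mirror(n)
    rel = "self-mirror" if partner == n else f"mirror partner {partner.as_tuple()}"
    print(f"{name}: d = {n.as_tuple()}  ({rel})")

print("\nClass representatives (lexicographic minimum of each class):")
for i, cls in enumerate(classes, 1):
    rep = min(cls)
    print(f"  {i:2d}. {rep.as_tuple()}  (class size {len(cls)})")
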