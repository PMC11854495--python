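"""Classify connection-weight patterns as Boolean or quantum logic.

Thresholding a weight matrix gives a binary relation; the fixed points
of its rough-set closure form a lattice.  A diagonal weight pattern
thresholds to the identity relation, whose lattice is the full powerset
(Boolean algebra).  The quantum condition thresholds to diagonal
sub-blocks surrounded by related cells, whose lattice is a horizontal
sum of Boolean blocks sharing only top and bottom — a non-distributive
orthomodular lattice, i.e. quantum logic.
"""

import rrscope as rr

for name, n, theta in [("diagonal", 5, 0.7), ("quantum", 5, 0.2),
                       ("quantum", 7, 0.2), ("blocky", 5, 0.7)]:
    w = rr.sample_weights(rr.condition(name, "linear", n), seed=2)
    rel = rr.relation_from_weights(w, theta)
    lat = rr.enumerate_fixed_points(rel)
    logic = rr.classify(lat)
    sizes = sorted(len(b) for b in logic.blocks)
    print(f"{name:8s} n={n} theta={theta}: {len(lat.elements):3d} lattice "
          f"elements -> {logic.kind:7s} (atoms per block: {sizes})")

# The closure operator behind the lattice, on the canonical 3+2 block
# relation: {A} and {B,C} are fixed, but {C,D} mixes the blocks and
# closes to the whole universe.
rel = rr.fixture("block_relation_3_2")
for X in [{"A"}, {"B", "C"}, {"C", "D"}]:
    print(f"Cl({sorted(X)}) = {sorted(rr.closure(X, rel))}")
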