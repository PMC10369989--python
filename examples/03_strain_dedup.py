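"""De-duplicate closely related genomes by protein-set Jaccard distance.

Three genomes where B is nearly identical to A: the greedy pass keeps a
subset in which every retained pair differs by at least 1% of their
protein identifiers.
"""

from tisdiv import ProteinSet, jaccard_distance, select_strains

A = ProteinSet("A", frozenset(f"WP_{i:06d}" for i in range(1000)))
B = ProteinSet("B", frozenset(f"WP_{i:06d}" for i in range(995)))       # 99.5% of A
C = ProteinSet("C", frozenset(f"WP_{i:06d}" for i in range(980)))       # 98% of A

for x, y in [(A, B), (A, C), (B, C)]:
    print(f"d_J({x.genome_id}, {y.genome_id}) = {jaccard_distance(x, y):.4f}")

kept = select_strains([A, B, C], min_dist=0.01)
print(f"retained at threshold 0.01: {kept}")
print("(B is within 1% of A and is dropped; C differs enough from A to stay)")
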