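"""Associate per-gene rearrangement calls with a binary clinical outcome.

The outlier-sample set of a scored gene (cancer samples beyond the Tukey fence
of its transformed profile) becomes a 0/1 vector over the cancer group. Its
normalized Hamming distance to a clinical 0/1 vector (here a synthetic death
outcome deliberately overlapping the spiked samples) measures association; the
conditional rate P(outcome = 1 | rearranged) is reported alongside, since a
small distance only implies concordance when the supports match.
"""

import numpy as np

from eigfusion import SimulationSpec, hamming_association, rearrangement_vector, simulate_dataset
from eigfusion.clinical import BinaryVector

dataset = simulate_dataset(
    SimulationSpec(cancer_size=50, test_ks=(10,), seed=7)
)
affected = set(dataset.truth.entries[0].affected_samples)

# synthetic outcome: death in 8 of the 10 affected samples + 4 others
rng = np.random.default_rng(7)
others = [s for s in dataset.labels.s1 if s not in affected]
deaths = set(list(affected)[:8]) | set(rng.choice(others, 4, replace=False))
clinical = BinaryVector(
    list(dataset.labels.s1),
    np.array([1 if s in deaths else 0 for s in dataset.labels.s1]),
)

v = rearrangement_vector(dataset.matrix, dataset.labels, "test_10")
distance, rate = hamming_association(v, clinical)
called = [s for s, b in zip(v.sample_ids, v.bits) if b]

print(f"samples called rearranged for test_10 : {len(called)} of 50")
print(f"truly affected samples                : {sorted(affected)}")
print(f"hamming distance to death vector      : {distance:.3f}")
print(f"P(death | rearranged)                 : {rate:.3f}")
print()
print("A distance near 0 with a high conditional rate means the gene's")
print("rearranged samples are largely the ones with the adverse outcome.")
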