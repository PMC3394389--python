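"""Attach permutation p-values to the spectral ranking.

Labels are shuffled (here 100 times) preserving the cancer-group size and all
genes are rescored; the null scores of all genes and permutations form one
pooled null, so 100 permutations of a 300-gene matrix resolve p-values down to
1/(1 + 300*100) ≈ 3.3e-5 — fine enough for a 0.001 significance cut.
"""

from eigfusion import RunConfig, SimulationSpec, permutation_pvalues, simulate_dataset

dataset = simulate_dataset(
    SimulationSpec(n_genes=300, n_samples=100, cancer_size=50,
                   test_ks=(2, 5, 10), seed=4)
)
config = RunConfig(n_permutations=100, p_threshold=0.001, seed=4)
table = permutation_pvalues(dataset.matrix, dataset.labels, config)

print(table.head(8)[["gene", "score", "rank", "p_value", "significant"]]
      .to_string(index=False))
print()
n_sig = int(table["significant"].sum())
print(f"{n_sig} genes pass p < {config.p_threshold} "
      f"(attainable minimum p = {1.0 / (1 + 300 * 100):.2e})")
print("The spiked test genes head the list with the smallest p-values;")
print("background genes spread roughly uniformly over (0, 1].")
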