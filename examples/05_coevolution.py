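"""MSA coevolution: weighted mutual information and randomization z-scores.

Generates a receptor-family-like alignment (500 sequences x 100 columns)
with one planted fully covarying column pair, weights redundant sequences,
scores all column pairs, and standardizes them against column-shuffled
null alignments; pairs at z >= 6.5 are called coupled.
"""

import numpy as np

from vibronet import coevolution as co, synthetic as syn

spec = syn.SyntheticSpec(n_sequences=500, n_columns=100, seed=0)
msa, truth = syn.generate_msa(
    spec, planted_pairs=[(10, 60, 1.0)], redundancy=[(0, 9, 0.02)]
)
weights = co.sequence_weights(msa, identity_threshold=0.62)
print(f"alignment: {msa.n_sequences} sequences x {msa.n_columns} columns")
print(f"redundant cluster of sequence 0: total weight {weights[:1].sum() + weights[500:].sum():.2f}")

result = co.z_scores(msa, weights, n_randomizations=100, seed=0)
i, j, c = truth.coupled_pairs[0]
print(f"\nplanted pair ({i}, {j}), coupling {c}: MI = {result.mi[i, j]:.3f}, z = {result.z[i, j]:.1f}")
print(f"analytic MI of the planted joint table: {truth.extras['pair_tables']['10,60']['analytic_mi']:.3f}")
print(f"pairs with z >= {result.threshold}: {len(result.significant)}")
print(result.significant.head(3).to_string(index=False))

ranking = co.connectivity_ranking(result, top_k=1)
print(f"\nnodes of the single strongest link:\n{ranking.to_string(index=False)}")

cons = co.conservation(msa, weights)
print(f"\nmean per-column conservation (KL from uniform): {np.nanmean(cons):.3f} nats")
print(
    "\nOnly the planted pair clears the z >= 6.5 threshold, and restricting"
    "\nthe network to its strongest link recovers exactly its two columns."
)
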