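"""Elastic-network force distribution: where does mechanical stress go?

Defines harmonic springs on a two-domain reference structure, computes
signed pairwise forces along each spring for a relaxed state and for a
state whose second domain is inflated (pre-stretched springs), condenses
them into per-residue punctual stress, and ranks the residues whose stress
changes most between the states.
"""

import numpy as np

from vibronet import forces as fd, synthetic as syn
from vibronet.trajectory import Trajectory

structure, _ = syn.generate_two_domain_elastic(15, 2, seed=0)
ref = structure.coords[0]
network = fd.build_elastic_network(ref, cutoff=10.0, spring_constant=1.0)
print(f"elastic network: {len(network.pairs)} springs at cutoff {network.cutoff} A")

rng = np.random.default_rng(0)
state_a = Trajectory.from_arrays(
    coords=ref[None] + rng.normal(0.0, 0.05, (20, *ref.shape)), dt=1.0
)
inflated = ref.copy()
dom_b = slice(17, None)
centroid = inflated[dom_b].mean(axis=0)
inflated[dom_b] = centroid + (inflated[dom_b] - centroid) * 1.08
state_b = Trajectory.from_arrays(
    coords=inflated[None] + rng.normal(0.0, 0.05, (20, *inflated.shape)), dt=1.0
)

forces_a = fd.pairwise_forces(state_a, network)
forces_b = fd.pairwise_forces(state_b, network)
profile_a = fd.punctual_stress(forces_a, "relaxed")
profile_b = fd.punctual_stress(forces_b, "inflated")
diff = fd.stress_difference(profile_a, profile_b)
print("\ntop 5 residues by stress change (inflated - relaxed):")
print(diff.head(5).to_string(index=False))
print(f"(perturbed domain spans residues 17-31)")

model = fd.force_pca(forces_b)
print(f"\nforce-PCA eigenvalues: {np.round(model.eigenvalues[:4], 3).tolist()}")
print(
    "\nStress accumulates exactly in the residues whose springs were"
    "\npre-stretched; force PCA shows which spring combinations co-fluctuate."
)
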