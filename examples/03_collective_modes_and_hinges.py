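"""Essential-dynamics PCA and Gaussian-network hinge detection.

A synthetic Cα chain carries a planted slow collective motion; PCA of the
fitted coordinates should recover it as PC1.  A separate two-domain
structure with a planted linker feeds the GNM hinge finder.
"""

import numpy as np

from vibronet import modes as md, synthetic as syn

spec = syn.SyntheticSpec(n_frames=5000, dt=100.0, n_residues=40, seed=0)
traj, truth = syn.generate_fragment_switch_trajectory(spec)

model = md.pca(traj)
overlap = abs(model.eigenvectors[:, 0] @ truth.mode_vectors[0])
print(f"eigenvalue spectrum (A^2): {np.round(model.eigenvalues[:5], 2).tolist()}")
print(f"|cos| between PC1 and the planted collective mode: {overlap:.4f}")
print(f"cosine content of PC1: {md.cosine_content(model, 0):.2e} "
      "(values near 1 would flag random-walk-like, unconverged sampling)")

filtered = md.filter_along_mode(traj, model, 0)
flat = filtered.coords.reshape(filtered.n_frames, -1)
var = ((flat - flat.mean(axis=0)) ** 2).sum(axis=1).mean()
print(f"variance of the PC1-filtered trajectory: {var:.2f} (lambda_1 = {model.eigenvalues[0]:.2f})")

structure, hinge_truth = syn.generate_two_domain_elastic(20, 3, seed=0)
hinges = md.gnm_hinges(structure, cutoff=10.0, n_modes=1)
print(f"\nplanted linker residues: {hinge_truth.hinge_residues}")
print(f"GNM slowest-mode sign crossover at residues: {hinges[0]}")
print(
    "The crossover of the slowest connectivity mode marks the hinge between"
    "\nthe two rigid domains, matching the planted linker."
)
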