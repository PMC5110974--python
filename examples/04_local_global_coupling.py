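"""Structural-alphabet encoding and local-global (LSF-GSF) coupling.

Four-residue fragments of a Cα trajectory are encoded into a 25-state
structural alphabet; the mutual information between a fragment's state
series and the discretized top-two-PC collective state quantifies how
strongly that local fluctuation couples to the global motion.
"""

import numpy as np

from vibronet import coupling as cp, modes as md, synthetic as syn

spec = syn.SyntheticSpec(n_frames=10_000, dt=100.0, n_residues=40, seed=0)
traj, truth = syn.generate_fragment_switch_trajectory(spec)

enc = cp.encode_fragments(traj, fragment_starts=truth.extras["fragment_starts"])
print("fragment state sequences (first 40 frames):")
for fi in range(enc.n_fragments):
    print(f"  fragment {enc.fragment_starts[fi]:2d}: {enc.state_letters(fi)[:40]}")

model = md.pca(traj)
states = cp.discretize_global(model, n_bins=10)
profile = cp.lsf_gsf_coupling(enc, states, n_shuffles=20, rng=np.random.default_rng(0))
print("\nfragment  planted coupling  nMI      shuffled-null nMI")
for start, c, nmi, bias in zip(
    profile.fragment_starts, truth.extras["couplings"], profile.nmi, profile.bias
):
    print(f"{start:8d}  {c:16.1f}  {nmi:.4f}  {bias:.4f}")

M = cp.lsf_mi_matrix(enc)
g = cp.lsf_network(M, top_k=3, node_names=[int(s) for s in profile.fragment_starts])
print("\nLSF network edges (top 3 MI pairs):")
for u, v, w in g.edges(data="weight"):
    print(f"  {u} -- {v}: MI {w:.4f}")
print(
    "\nnMI falls with the planted coupling strength, and the zero-coupling"
    "\nfragment is indistinguishable from the shuffled null."
)
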