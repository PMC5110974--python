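"""Hydrogen-bond existence kinetics from a telegraph-switching bond.

Generates a donor/hydrogen/acceptor triple that forms and breaks as a
two-state Markov process, detects the bond frame by frame with the
3.5 Å / 2.6 Å / 30° geometric criterion, and compares the intermittent
existence autocorrelation with the closed-form telegraph prediction.
"""

import numpy as np

from vibronet import hbonds as hb, synthetic as syn

k_on = k_off = 1e-3  # 1/fs
spec = syn.SyntheticSpec(n_frames=50_000, dt=100.0, seed=1)
traj, truth = syn.generate_hbond_telegraph(spec, k_on, k_off)

mat = hb.existence_matrix(traj, truth.extras["donors"], truth.extras["acceptors"])
print(f"bond universe: {mat.bonds}")
print(f"occupancy: {mat.matrix.mean():.3f} (stationary truth {truth.extras['stationary_occupancy']:.3f})")

corr = hb.hbond_autocorrelation(mat, max_lag_fs=3000.0)
analytic = 0.5 + 0.5 * np.exp(-(k_on + k_off) * corr.lags)
print("lag (fs)   c(tau)   telegraph closed form")
for lag, c, a in list(zip(corr.lags, corr.values, analytic))[::6]:
    print(f"{lag:8.0f}   {c:.4f}   {a:.4f}")

tau, amp, base = hb.fit_relaxation_time(hb.hbond_autocorrelation(mat, max_lag_fs=5000.0))
print(f"\nfitted relaxation time: {tau:.0f} fs (truth 1/(k_on+k_off) = {1/(k_on+k_off):.0f} fs)")
print(
    "The fitted decay recovers the planted switching kinetics; the plateau"
    f" near {base:.2f} is the stationary occupancy."
)
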