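"""Recover planted vibrational modes from a velocity autocorrelation spectrum.

Builds an exact harmonic trajectory with three low-frequency modes (40, 65
and 85 cm⁻¹ — the far-infrared range where collective protein and ligand
torsions absorb), computes the VACF and its Fourier power spectrum, picks
peaks, and pairs the "simulated" peaks with a mock experimental peak list
under the usual 10–15 cm⁻¹ classical blue shift.
"""

import numpy as np

from vibronet import synthetic as syn, vibrational as vib

spec = syn.SyntheticSpec(n_frames=2048, dt=100.0, seed=0)
masses = np.full(3, 12.0)
stiffness = syn.stiffness_for_frequencies([40.0, 65.0, 85.0], masses)
traj, truth = syn.generate_harmonic_trajectory(
    spec, stiffness, masses, free_mode_velocity_scale=0.0
)
print(f"planted modes (cm^-1): {[round(float(f), 1) for f in truth.mode_frequencies]}")

corr = vib.vacf(traj)
spectrum = vib.power_spectrum(corr, window="hann", grid_resolution_cm=4.0)
peaks = vib.find_peaks(spectrum, min_prominence_fraction=0.05)
print(f"recovered peaks (cm^-1): {np.round(peaks.positions, 2).tolist()}")
print(f"spectral resolution: {spectrum.resolution:.3f} cm^-1")

assignment = vib.blue_shift_match(peaks, np.array([55.0, 75.0]), (10.0, 15.0))
for sim, exp, shift in assignment.matches:
    print(f"simulated {sim:.1f} cm^-1 -> measured {exp:.1f} cm^-1 (blue shift {shift:.1f})")
print(f"unmatched simulated peaks: {[round(float(p), 1) for p in assignment.unmatched_sim]}")
print(
    "\nEach recovered peak sits within one resolution bin of its planted mode;"
    "\nthe lowest mode has no measured partner, as expected when a minor"
    "\nconformation's fluctuation is absent from the equilibrium spectrum."
)
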