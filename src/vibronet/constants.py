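"""Physical constants and unit conversions.

Internal units: lengths in Å, times in fs, velocities in Å/fs, masses in amu.
Wavenumbers are reported in cm⁻¹.
"""

# speed of light, cm per fs
C_CM_PER_FS = 2.99792458e-5

# 1 THz expressed in cm⁻¹ (1e-3 cycles/fs divided by c)
THZ_IN_INV_CM = 1e-3 / C_CM_PER_FS


def omega_to_wavenumber(omega_rad_per_fs: float) -> float:
    """Angular frequency (rad/fs) → wavenumber (cm⁻¹), ν̃ = ω / (2π c)."""
    import math

    return omega_rad_per_fs / (2.0 * math.pi * C_CM_PER_FS)


def wavenumber_to_omega(nu_cm: float) -> float:
    """Wavenumber (cm⁻¹) → angular frequency (rad/fs)."""
    import math

    return 2.0 * math.pi * C_CM_PER_FS * nu_cm


# light-element masses (amu); fallback for unknown elements is carbon-like
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "CA": 40.078,
    "FE": 55.845,
}
DEFAULT_MASS = 12.011
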