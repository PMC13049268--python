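"""Physical constants and unit conventions used across the package.

Units are fixed package-wide: RF in volts, gradients in mT/m, positions in
mm, frequencies in Hz, times in seconds unless a name says otherwise.
Channel sensitivities carry Hz/V, i.e. gamma*B1/(2*pi) = sum_c s_c(r)*V_c(t),
so the Bloch model never needs an explicit volts->tesla conversion.
"""

# gamma/2pi for 1H. With G in mT/m and r in mm, G*r is in microtesla, so the
# off-resonance contribution of a gradient is GAMMA_BAR * G * r in Hz.
GAMMA_BAR_HZ_PER_UT = 42.577

#: Combined CP-mode reference sensitivity (Hz/V). A head array driven in CP
#: mode with all-channel voltage V(t) produces gamma*B1/2pi = REF * V(t) at a
#: reference (center) voxel. Chosen so that a 90 deg, 3 ms Hann-sinc pulse
#: respects a 1 W per-channel average-power limit with ~2x margin.
REF_SENS_HZ_PER_V = 47.0

#: Transmit-chain impedance convention for energy/power accounting (ohm).
DEFAULT_IMPEDANCE_OHM = 50.0
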