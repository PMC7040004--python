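"""Physical constants and unit-conversion factors used across the package.

All public interfaces use Å⁻¹ for momentum transfer Q, K for temperature,
Å² for mean square displacements and N/m for force constants.
"""

#: Boltzmann constant (J/K), CODATA exact value.
K_B = 1.380649e-23

#: 2·k_B expressed in Å²·(N/m)/K, i.e. the factor such that a proteome with
#: effective force constant k' (N/m) has an MSD temperature slope of
#: TWO_KB_A2_PER_K / k' in Å²/K (and conversely k' = TWO_KB_A2_PER_K / slope).
#: 2 · 1.380649e-23 J/K = 2.761298e-23 m²·(N/m)/K = 2.761298e-3 Å²·(N/m)/K.
TWO_KB_A2_PER_K = 2.0 * K_B * 1e20  # = 0.0027612980...

#: Reference monitor count: synthetic amplitudes are calibrated so that a run
#: recorded at this monitor value has counts equal to the model amplitude.
REFERENCE_MONITOR = 1.0e6
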