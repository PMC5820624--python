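"""Unit conventions and conversion constants.

The package works in a single consistent unit system throughout:
stress in MPa, length in mm, force in N (1 MPa x 1 mm^2 = 1 N).
Intra-abdominal and intravesical pressures are quoted clinically in
cm H2O and converted with the exact conventional water-column constant.
"""

#: Pascals per centimetre of water column (conventional value).
PA_PER_CMH2O = 98.0665

#: MPa per centimetre of water column.
MPA_PER_CMH2O = PA_PER_CMH2O * 1e-6


def cmh2o_to_mpa(pressure_cmh2o: float) -> float:
    """Convert a water-column pressure reading to MPa."""
    return pressure_cmh2o * MPA_PER_CMH2O
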