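"""Unit conventions and atomic constants.

All coordinates are stored internally in angstrom (the PDB native unit);
report-facing geometry is converted to nanometre. Times are nanoseconds,
diffusion coefficients nm^2/ns.
"""

import numpy as np

ANG_PER_NM = 10.0
NM_PER_ANG = 0.1

#: 1 nm^2/ns expressed in the conventional 1e-5 cm^2/s unit of lipid diffusion.
NM2_PER_NS_TO_1E5_CM2_PER_S = 1.0

# Standard atomic masses (u) for the elements the generator and analyzers use.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
}


def masses_for(elements) -> np.ndarray:
    """Per-atom mass array; unknown elements fall back to carbon mass."""
    return np.array(
        [ATOMIC_MASSES.get(str(e).upper(), ATOMIC_MASSES["C"]) for e in elements],
        dtype=float,
    )
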