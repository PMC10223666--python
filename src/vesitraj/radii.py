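"""Van der Waals radius table for solvent-accessible surface area."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

# Bondi-style van der Waals radii (angstrom).
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "NA": 2.27,
    "CL": 1.75,
}

#: Conventional water-probe radius (angstrom).
DEFAULT_PROBE_RADIUS = 1.4


@dataclass
class AtomRadiusTable:
    """Element -> vdW radius (angstrom) plus the rolling-probe radius."""

    radii: dict = field(default_factory=lambda: dict(BONDI_RADII))
    probe_radius: float = DEFAULT_PROBE_RADIUS

    def __post_init__(self):
        bad = [e for e, r in self.radii.items() if r <= 0]
        if bad or self.probe_radius < 0:
            raise ConfigurationError([f"non-positive radius for {e}" for e in bad] or ["negative probe radius"])

    def radii_for(self, elements) -> np.ndarray:
        """Per-atom radius array; raises listing every element missing a radius."""
        missing = sorted({str(e).upper() for e in elements} - set(self.radii))
        if missing:
            raise ConfigurationError([f"no van der Waals radius defined for element {e!r}" for e in missing])
        return np.array([self.radii[str(e).upper()] for e in elements], dtype=float)
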