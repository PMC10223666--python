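"""Exception hierarchy used across the package."""


class VesitrajError(Exception):
    """Base class for all package errors."""


class MalformedTrajectoryError(VesitrajError):
    """Trajectory file violates the declared dialect (e.g. frame atom-count mismatch)."""


class UnsupportedFormatError(VesitrajError):
    """Requested coordinate format is not one of the supported dialects."""


class TopologyError(VesitrajError):
    """Topology declaration does not partition the atoms (unclaimed or doubly claimed)."""


class PackingError(VesitrajError):
    """Requested monomer count cannot be placed on the shell at minimum spacing."""


class SpecError(VesitrajError):
    """Generator spec is internally inconsistent (bad radii, unknown molecule, ...)."""


class GeometryError(VesitrajError):
    """Vesicle geometry is undefined (e.g. an empty leaflet)."""


class FitError(VesitrajError):
    """Diffusion fit cannot proceed (degenerate MSD values in the window)."""


class ConfigurationError(VesitrajError):
    """Invalid run configuration or missing per-element parameters.

    Carries ``errors``, the full list of individual problems, so callers see
    every violation at once rather than one per run.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
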