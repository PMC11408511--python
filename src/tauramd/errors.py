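"""Exception hierarchy.

All package errors derive from :class:`TauRAMDError` so callers can catch
one base class; subclasses distinguish configuration mistakes (bad user
input that a config change fixes) from invalid data and from numerical
failures.
"""


class TauRAMDError(Exception):
    """Base class for all tauramd errors."""


class ConfigurationError(TauRAMDError):
    """A user-supplied parameter or specification is invalid."""


class InvalidInputError(TauRAMDError):
    """An input file or data structure violates its contract."""


class InvalidLayoutError(InvalidInputError):
    """A campaign layout is inconsistent (e.g. duplicate trajectory)."""


class EmptyInterfaceError(InvalidInputError):
    """No residue pair of the two partners lies within the contact cutoff."""


class InsufficientDataError(InvalidInputError):
    """Too few observations for the requested estimator."""


class InconsistentInputError(InvalidInputError):
    """Inputs that must agree (e.g. pair lists across replicas) do not."""


class EmptySelectionError(InvalidInputError):
    """A frame selection matched nothing (e.g. no dissociating trajectory)."""


class UnassignedResidueError(ConfigurationError):
    """Residues without an interaction-group table entry or override."""

    def __init__(self, residue_names):
        self.residue_names = sorted(set(residue_names))
        super().__init__(
            "no interaction-group assignment for residue name(s): "
            + ", ".join(self.residue_names)
        )


class SelectionError(ConfigurationError):
    """An atom/residue selection did not resolve."""


class IntegrationFailureError(TauRAMDError):
    """The Langevin integrator produced non-finite coordinates."""


class FixtureError(TauRAMDError):
    """A synthetic fixture specification is infeasible."""
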