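"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PhytonetError` so callers (and the
CLI) can distinguish bad inputs from internal failures.
"""


class PhytonetError(Exception):
    """Base class for all package errors."""


class StructureParseError(PhytonetError):
    """A SMILES string could not be parsed into a molecule."""


class RegistryError(PhytonetError):
    """Ligand registry construction failed (e.g. duplicate identifiers)."""


class DialectError(PhytonetError):
    """An input table is missing expected columns for its dialect."""


class InputError(PhytonetError):
    """Semantically invalid input (empty gene sets, bad ranges, ...)."""


class AssemblyError(PhytonetError):
    """Network assembly referenced an unknown entity."""


class AnnotationError(PhytonetError):
    """A node could not be annotated (e.g. ligand with no targets)."""


class CalibrationError(PhytonetError):
    """Confidence calibration lacks the records it needs."""


class StyleError(PhytonetError):
    """A visual channel has no defined value for an attribute."""


class LayoutError(PhytonetError):
    """A node's compartment has no rectangle in the cell template."""


class FixtureSpecError(PhytonetError):
    """A synthetic fixture specification is infeasible."""


class ConfigError(PhytonetError):
    """Pipeline configuration is missing or inconsistent."""


class StageError(PhytonetError):
    """A pipeline stage failed after configuration was accepted."""
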