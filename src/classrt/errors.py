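"""Exception hierarchy.

Every error raised by this package derives from :class:`ClassRTError`, so
callers (and the CLI) can catch one type and report a machine-parsable class
name.
"""


class ClassRTError(Exception):
    """Base class for all classrt errors."""


class InvalidMoleculeError(ClassRTError):
    """A SMILES string could not be parsed into a molecular graph."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ConfigurationError(ClassRTError):
    """Bad configuration: missing columns, invalid ratios, bad thresholds."""


class EmptyInputError(ClassRTError):
    """An input file yielded zero usable records."""


class DatasetTooSmallError(ClassRTError):
    """Not enough records for the requested operation."""


class RuleError(ClassRTError):
    """A taxonomy rule file is malformed (bad SMARTS, duplicate id, ...)."""


class ModelPersistenceError(ClassRTError):
    """A model directory is missing, corrupt, or schema-incompatible."""


class MetricError(ClassRTError):
    """Metric computation is undefined for the given inputs."""
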