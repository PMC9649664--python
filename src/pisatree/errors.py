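"""Exception hierarchy for pisatree.

All user-facing failures derive from :class:`PisaError` so the CLI can map
them to exit code 2 uniformly.
"""


class PisaError(Exception):
    """Base class for all pisatree errors."""


class NotInTreeError(PisaError):
    """A path has no ``_p_`` project ancestor."""


class MissingKeyError(PisaError, KeyError):
    """A requested metadata key is absent from a record."""

    def __init__(self, key: str, source: str | None = None):
        self.key = key
        self.source = source
        where = f" in {source}" if source else ""
        super().__init__(f"metadata key {key!r} not found{where}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return self.args[0]


class ValidationError(PisaError):
    """Input data violates a structural rule (duplicate IDs, bad key...)."""


class InvalidNameError(ValidationError):
    """A level name is empty or unusable after sanitisation."""


class InvalidChoiceError(ValidationError):
    """A prompt answer is not among the menu choices and no 'other' escape."""


class TemplateError(PisaError):
    """A template file is malformed."""


class ConfigurationError(PisaError):
    """The template repository, mapping file or sync config is inconsistent."""


class HierarchyError(PisaError):
    """A level-creation request violates the project>I>S>A nesting order."""


class AlreadyExistsError(PisaError):
    """The target directory of a creation request already exists."""


class ExportError(PisaError):
    """An ISA-Tab export precondition is not met."""


class SeekSyncError(PisaError):
    """A remote operation failed; carries the transcript of completed steps."""

    def __init__(self, message: str, transcript=None):
        super().__init__(message)
        self.transcript = transcript or []
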