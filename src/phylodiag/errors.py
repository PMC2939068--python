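"""Exception hierarchy shared across the package."""


class PhylodiagError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhylodiagError):
    """A file could not be parsed in the expected format."""


class ValidationError(PhylodiagError):
    """An in-memory object violates one of its invariants."""


class AlignmentShapeError(ValidationError):
    """Sequences in an alignment do not all share one length."""


class UnrootedTreeError(ValidationError):
    """An operation requiring a rooted tree received an unrooted one."""


class ConfigError(PhylodiagError):
    """A simulation or analysis configuration is inconsistent."""
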