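"""Exception hierarchy shared across the package."""


class MDNetsError(Exception):
    """Base class for all package errors."""


class ParseError(MDNetsError):
    """A file could not be parsed (malformed records)."""


class StructureError(MDNetsError):
    """Inconsistent molecular structure (e.g. models with different atoms)."""


class SelectionError(MDNetsError):
    """An atom selection resolved to nothing or to missing atoms."""


class CapabilityError(MDNetsError):
    """A requested file format or feature is not supported."""


class ConfigurationError(MDNetsError):
    """Invalid configuration or generator specification."""


class ContractError(MDNetsError):
    """An operation was called outside its documented preconditions."""


class DegenerateProfileError(MDNetsError):
    """A network profile could not be computed (e.g. isolated source node)."""
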