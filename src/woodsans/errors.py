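"""Exception hierarchy."""


class WoodSansError(Exception):
    """Base class for package errors."""


class DomainError(WoodSansError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DataError(WoodSansError, ValueError):
    """Input data are structurally valid but unusable (empty sector, no overlap...)."""


class FormatError(WoodSansError, ValueError):
    """Structurally inconsistent input (shape mismatch, bad file layout)."""


class ConfigurationError(WoodSansError, ValueError):
    """An invalid combination of configuration options."""


class ContractError(WoodSansError, ValueError):
    """An operation was called in a way its contract forbids."""
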