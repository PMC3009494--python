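"""Exception hierarchy shared across the package."""


class OntoPrimeError(Exception):
    """Base class for all package errors."""


class OntologyValidationError(OntoPrimeError):
    """The ontology violates a structural invariant (cycle, dangling parent,
    closure edge into an obsolete term)."""


class UnknownTermError(OntoPrimeError, KeyError):
    """A term id is absent from the ontology, obsolete, or not prime-assigned."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class UnknownProteinError(OntoPrimeError, KeyError):
    """A protein id is absent from the interaction store."""

    def __str__(self) -> str:
        return Exception.__str__(self)


class LoadError(OntoPrimeError):
    """A tabular input file is malformed or references unknown entities in
    strict mode."""


class ExportError(OntoPrimeError):
    """An output document cannot be produced (e.g. unresolvable endpoint)."""


class ConfigurationError(OntoPrimeError):
    """An operation was invoked without the inputs it requires."""
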