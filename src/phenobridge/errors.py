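"""Exception hierarchy shared across the package."""


class PhenobridgeError(Exception):
    """Base class for all package errors."""


class ParseError(PhenobridgeError):
    """A document could not be parsed (malformed stanza, bad line format)."""


class ValidationError(PhenobridgeError):
    """Parsed content violates a structural contract (cycles, dangling IDs)."""


class ConceptLookupError(PhenobridgeError, KeyError):
    """A concept ID does not resolve in the ontology it was looked up in."""


class UsageError(PhenobridgeError):
    """Arguments are inconsistent with each other (prefix/direction mismatch)."""


class EvaluationError(PhenobridgeError):
    """An evaluation cannot be carried out (e.g. ROC without positives)."""


class ConfigError(PhenobridgeError):
    """A generator configuration is infeasible or self-contradictory."""
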