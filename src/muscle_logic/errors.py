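"""Exception hierarchy for muscle-logic."""


class MuscleLogicError(Exception):
    """Base class for all errors raised by this package."""


class OboParseError(MuscleLogicError):
    """Malformed OBO-dialect input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DanglingReferenceError(MuscleLogicError):
    """An axiom or tag references a CURIE that is not declared."""


class OntologyValidationError(MuscleLogicError):
    """An ontology container invariant is violated (e.g. duplicate labels)."""


class UnknownTermError(MuscleLogicError):
    """A label, synonym or CURIE string did not resolve to any class."""


class AmbiguousTermError(MuscleLogicError):
    """A synonym resolves to more than one class."""

    def __init__(self, text: str, candidates):
        self.candidates = list(candidates)
        names = ", ".join(str(c) for c in self.candidates)
        super().__init__(f"ambiguous term {text!r}: candidates {names}")


class QuerySyntaxError(MuscleLogicError):
    """A class-expression / DL-query string failed to parse; carries position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"at position {position}: {message}"
        super().__init__(message)


class NoEntailmentError(MuscleLogicError):
    """An explanation was requested for a subsumption that is not entailed."""


class ConfigurationError(MuscleLogicError):
    """An operation was invoked with an unsupported configuration."""


class CorpusSpecError(MuscleLogicError):
    """A synthetic-corpus specification cannot be satisfied."""


class LexiconBuildError(MuscleLogicError):
    """A lexicon phrase would map to more than one class."""
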