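"""Exception hierarchy shared across the package."""


class TuslabError(Exception):
    """Base class for all package errors."""


class ValidationError(TuslabError, ValueError):
    """An input object violates one of its declared invariants.

    The message names the violated invariant so callers (and the CLI,
    which maps this to exit code 2) can report it directly.
    """


class DependencyError(TuslabError, RuntimeError):
    """A pipeline stage was requested without its upstream artefact."""
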