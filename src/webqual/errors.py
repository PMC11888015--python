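"""Exception hierarchy for webqual.

Every contract violation raises a named subclass of :class:`WebqualError`
so that callers (and the CLI) can distinguish malformed input from bugs.
"""


class WebqualError(Exception):
    """Base class for all webqual errors."""


class FormatError(WebqualError):
    """A file is structurally malformed (e.g. a required column is missing)."""


class ValidationError(WebqualError):
    """A value violates a type invariant (range, arity, enum membership)."""


class ReferentialError(WebqualError):
    """A rating references a website id that does not exist in the corpus."""


class OrderingError(WebqualError):
    """A date pair is in the wrong temporal order."""


class UndefinedStatisticError(WebqualError):
    """A readability formula was evaluated on degenerate counts."""


class RangeError(WebqualError):
    """A score lies outside its instrument's allowed range."""


class DegenerateRangeError(WebqualError):
    """Min-max normalisation was attempted over a zero-width range."""


class AdjudicationRequiredError(WebqualError):
    """Two raters differ by >= 5 DISCERN points and no third rating exists."""


class UnresolvedDisagreementError(WebqualError):
    """Item-level disagreement with no third rater to break it."""


class InsufficientGroupsError(WebqualError):
    """A between-group test needs at least two groups."""


class EmptyCorpusError(WebqualError):
    """An operation that needs at least one record got an empty corpus."""


class GenerationError(WebqualError):
    """The synthetic generator cannot satisfy the requested parameters."""
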