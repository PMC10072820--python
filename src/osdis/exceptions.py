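"""Exception hierarchy for the osdis package.

Every error raised by the library derives from :class:`OsdisError`, so CLI
entry points can catch one type and exit with a categorized message.
"""


class OsdisError(Exception):
    """Base class for all osdis errors."""


class ParameterError(OsdisError, ValueError):
    """Invalid parameter value (generator recipe, diffusion config, ...)."""


class EdgeListFormatError(OsdisError, ValueError):
    """Malformed edge-list file: bad tokens, self-loop, duplicate edge,
    or a missing delay column that was declared present."""


class UnreachableError(OsdisError):
    """A shortest-path query between nodes in different components."""


class IncompleteObservationError(OsdisError):
    """An observer was never infected in the diffusion outcome."""


class InconsistentRecordError(OsdisError):
    """An observer record whose direction neighbor is not adjacent to it."""


class ScoringError(OsdisError, ValueError):
    """Invalid input to a similarity measure (empty or mismatched vectors)."""


class LocatorError(OsdisError):
    """Locator contract violation (no records) or no feasible candidate."""


class SummaryError(OsdisError, ValueError):
    """Empty input to the experiment summarizer."""
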