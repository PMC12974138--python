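"""Named error conditions shared across the package."""


class MicrostabError(Exception):
    """Base class for package-specific errors."""


class DuplicateIDError(MicrostabError, ValueError):
    """A sample or taxon identifier appears more than once."""


class NonIntegerCountError(MicrostabError, ValueError):
    """A feature-table cell is not a non-negative integer."""


class MissingColumnError(MicrostabError, ValueError):
    """A mandatory metadata column is absent."""


class UnknownRankError(MicrostabError, ValueError):
    """A taxonomic rank label is not one of kingdom..species."""


class ZeroSumSampleError(MicrostabError, ValueError):
    """An operation requiring positive sample totals met an all-zero sample."""


class DegenerateGroupError(MicrostabError, ValueError):
    """A group-comparison input is degenerate (zero variance / too few samples)."""


class SingularSystemError(MicrostabError, ValueError):
    """The SparCC basis-variance linear system is singular."""


class CliqueLimitError(MicrostabError, RuntimeError):
    """Maximal-clique enumeration exceeded the configured cap."""
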