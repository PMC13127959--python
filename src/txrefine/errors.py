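"""Exception hierarchy for the refinement toolkit."""


class RefineError(Exception):
    """Base class for all toolkit errors."""


class GtfParseError(RefineError):
    """Malformed GTF input; message names the offending line number."""


class CoordinateError(RefineError):
    """A genomic coordinate violates its invariants (end < start, out of bounds...)."""


class DuplicateIdError(RefineError):
    """A transcript or gene identifier occurs more than once in one annotation."""


class ContractError(RefineError):
    """An operation received input violating its stated preconditions."""


class ConsistencyError(RefineError):
    """Cross-stage inputs disagree (e.g. a survivor references a consumed gene)."""


class MappingError(RefineError):
    """A required id -> id mapping is missing an entry."""


class ConfigError(RefineError):
    """Invalid or infeasible configuration."""
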