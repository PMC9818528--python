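"""Exception hierarchy for mammobalance.

All library errors derive from :class:`MammoBalanceError` so callers can
catch toolkit failures with a single except clause.  The subclasses mirror
the failure modes of the pipeline: bad configuration, degenerate inputs
(empty histograms, single-class splits), impossible lesion placement, and
contract violations (e.g. artifacting an already-malignant image).
"""


class MammoBalanceError(Exception):
    """Base class for all mammobalance errors."""


class ConfigurationError(MammoBalanceError, ValueError):
    """Invalid parameter values (dimensions, batch sizes, spacings...)."""


class DegenerateInputError(MammoBalanceError, ValueError):
    """Structurally valid input on which the operation is undefined."""


class PlacementError(MammoBalanceError):
    """No valid insertion site exists for a lesion."""


class ContractError(MammoBalanceError):
    """A documented precondition was violated by the caller."""
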