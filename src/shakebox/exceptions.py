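"""Exception hierarchy for shakebox.

All errors derive from :class:`ShakeboxError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
bad numeric inputs, bad configuration files, malformed data tables, and
designs too degenerate to fit.
"""


class ShakeboxError(Exception):
    """Base class for all shakebox errors."""


class InvalidParameterError(ShakeboxError, ValueError):
    """A numeric argument violates its precondition (e.g. sigma <= 0)."""


class ConfigurationError(ShakeboxError, ValueError):
    """A config file or model/estimator name is malformed or unknown."""


class DataError(ShakeboxError, ValueError):
    """A data table violates the schema or contains impossible values."""


class DegenerateDesignError(DataError):
    """The design has no variation to fit (constant predictor, zero variance)."""


class PipelineOrderError(ShakeboxError, RuntimeError):
    """A pipeline stage was run before the stages it depends on."""
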