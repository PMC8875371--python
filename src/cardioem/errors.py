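"""Package-wide exception types.

``ValidationError`` covers bad configuration or malformed inputs (CLI exit
code 2); ``SimulationError`` covers runtime failures of an otherwise valid
model (CLI exit code 3).
"""


class CardioemError(Exception):
    """Base class for package errors."""


class ValidationError(CardioemError):
    """Invalid configuration, parameters, or input data."""


class SimulationError(CardioemError):
    """Runtime failure during simulation or analysis."""
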