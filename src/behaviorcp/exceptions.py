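"""Exception hierarchy for behaviorcp."""


class BehaviorCPError(Exception):
    """Base class for all behaviorcp errors."""


class ConfigurationError(BehaviorCPError, ValueError):
    """Invalid task, tracker, or run configuration."""


class ParameterError(BehaviorCPError, ValueError):
    """Invalid generative or model parameters (non-finite, out of range)."""


class InputError(BehaviorCPError, ValueError):
    """Invalid data input (shape mismatch, empty sample, misaligned labels)."""


class DegenerateDesignError(BehaviorCPError, ValueError):
    """A model fit was requested on a design with no usable variation."""


class MissingDetectionError(BehaviorCPError, RuntimeError):
    """No animal blob could be detected in a frame."""


class SummaryError(BehaviorCPError, ValueError):
    """A summary was requested over an empty or all-failed collection of fits."""
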