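class ConfigError(ValueError):
    """A configuration value violates its documented constraints."""


class InvalidSpanError(ValueError):
    """A lactation span is structurally impossible (e.g. end before start)."""


class SimulationError(RuntimeError):
    """A simulated timeline reached a structurally impossible state."""
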