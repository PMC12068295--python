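"""Exception types shared across the pipeline."""


class BH3KitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BH3KitError):
    """A layout, gate or truth configuration is invalid or incomplete."""


class ValidationError(ConfigurationError):
    """Structured input (layout YAML, event CSV, reference table) failed validation."""


class AcquisitionError(BH3KitError):
    """An event file is unusable (zero beads, empty well, corrupt header)."""
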