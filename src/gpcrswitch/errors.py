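"""Exception hierarchy for the package."""


class GpcrSwitchError(Exception):
    """Base class for all package errors."""


class NumberingError(GpcrSwitchError):
    """Invalid or inconsistent Ballesteros–Weinstein numbering."""


class TopologyError(GpcrSwitchError):
    """Topology parsing or atom-selection failure."""


class TrajectoryError(GpcrSwitchError):
    """Trajectory reading/validation failure."""


class HillsParseError(GpcrSwitchError):
    """Malformed metadynamics hills record."""


class ConfigError(GpcrSwitchError):
    """Invalid run configuration."""
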