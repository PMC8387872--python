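"""Exception hierarchy used across the package."""


class ScpMechError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ScpMechError, ValueError):
    """A physical quantity is outside its mathematical domain (e.g. stretch <= 0)."""


class InputError(ScpMechError, ValueError):
    """Structurally invalid input (lengths, ordering, ranges, missing columns)."""


class SegmentationError(ScpMechError, RuntimeError):
    """A trajectory could not be split into loading / rebound / unloading phases."""


class SimulationError(ScpMechError, RuntimeError):
    """A time integration left its validity envelope (e.g. full compression)."""
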