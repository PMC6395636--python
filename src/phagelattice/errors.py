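"""Exception types shared across the package."""


class PhageLatticeError(Exception):
    """Base class for all package errors."""


class ValidationError(PhageLatticeError, ValueError):
    """A configuration value is outside its permitted range or inconsistent."""


class CoordinateError(PhageLatticeError, ValueError):
    """A grid coordinate lies outside the lattice."""


class CapacityError(PhageLatticeError, ValueError):
    """An operation would exceed lattice or per-location capacity."""


class RegistryError(PhageLatticeError, KeyError):
    """A species or attachment-phenotype label is unknown to the registry."""


class ConsistencyError(PhageLatticeError, RuntimeError):
    """An internal state invariant (occupancy, capacity) was violated."""
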