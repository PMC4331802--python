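"""Exception hierarchy for evogrid."""


class EvogridError(Exception):
    """Base class for all evogrid errors."""


class DomainError(EvogridError, ValueError):
    """A value lies outside its admissible domain (e.g. allele outside gene bounds)."""


class ParameterError(EvogridError, ValueError):
    """A parameter violates its contract (non-positive shape, zero cell transfer, ...)."""


class StructureError(EvogridError, ValueError):
    """An operation would produce an invalid gene-network structure."""


class InsufficientCellsError(EvogridError, ValueError):
    """A cell-moving operation requested more cells than the source holds."""


class ConfigError(EvogridError, ValueError):
    """A scenario configuration is malformed; message carries the key path."""
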