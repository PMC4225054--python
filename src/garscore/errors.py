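"""Exception hierarchy for the GARS engine.

Everything user-facing derives from :class:`GarsError` so the CLI can map
any expected failure to exit status 1 with a one-line diagnostic.
"""


class GarsError(Exception):
    """Base class for all expected, user-facing failures."""


class PanelError(GarsError):
    """Malformed or inconsistent panel definition."""


class GenotypeValidationError(GarsError):
    """A genotype call violates the panel (bad allele label, ploidy, sex)."""


class UnscorableError(GarsError):
    """A subject has no countable alleles (all panel markers missing)."""


class AssociationError(GarsError):
    """A contingency table does not support the requested statistic."""


class SimulationError(GarsError):
    """Invalid simulation configuration."""
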