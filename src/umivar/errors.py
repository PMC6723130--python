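"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3.
"""


class UmivarError(Exception):
    """Base class for all package errors."""


class ConfigError(UmivarError):
    """Invalid configuration or parameters."""


class DataError(UmivarError):
    """Invalid or inconsistent input data."""


class PanelError(DataError):
    """Malformed probe panel (duplicate ids, overlaps, bad sequence...)."""


class EdgeContextError(DataError):
    """Trinucleotide context requested at a probe-region edge."""


class SimSpecError(ConfigError):
    """Simulated variant specification inconsistent with the panel."""


class InsufficientControlsError(DataError):
    """Too few control samples to fit a background distribution."""


class PhasingError(DataError):
    """Requested SNP site is not heterozygous in the sample."""


class FilterError(DataError):
    """Variant filtering requested outside the probed regions."""
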