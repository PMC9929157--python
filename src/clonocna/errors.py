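"""Exception hierarchy for the clonocna pipeline."""


class ClonocnaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ClonocnaError):
    """A file did not conform to the expected format (e.g. missing column)."""


class InputError(ClonocnaError):
    """Inputs violated an operation's precondition (e.g. mixed sample ids)."""


class StatisticError(ClonocnaError):
    """A statistic is undefined for the given input (e.g. <2 clonotypes)."""


class CoordinateError(ClonocnaError):
    """A variant refers to positions outside its coding sequence."""


class ContractError(ClonocnaError):
    """A pluggable component returned a value outside its contract."""


class ConfigError(ClonocnaError):
    """A simulation or pipeline configuration is invalid."""
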