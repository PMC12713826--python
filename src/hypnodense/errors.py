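"""Exception hierarchy.

Every validation failure raised by this package derives from
:class:`HypnodensityError`, so callers (and the CLI, which maps it to exit
code 2) can distinguish bad input from genuine bugs.
"""


class HypnodensityError(ValueError):
    """Base class for all validation and domain errors."""


class VocabularyError(HypnodensityError):
    """Unknown stage code, or an operation applied to the wrong vocabulary."""


class AlignmentError(HypnodensityError):
    """Hypnograms / hypnodensities that should be epoch-aligned are not."""


class DegenerateScorerError(HypnodensityError):
    """A scorer's labels make an agreement statistic undefined."""


class UndefinedStatisticError(HypnodensityError):
    """A statistic's defining ratio is 0/0 (e.g. kappa with p_e = 1)."""


class FileFormatError(HypnodensityError):
    """A file does not conform to the documented text formats."""
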