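"""Exception hierarchy. All package errors derive from TwoStepMRError."""


class TwoStepMRError(Exception):
    """Base class for all errors raised by this package."""


class SumStatsFormatError(TwoStepMRError):
    """A summary-statistics file is malformed (e.g. a mandatory column is absent)."""


class EmptyTableError(TwoStepMRError):
    """No parsable variant rows were found."""


class EmptyInstrumentError(TwoStepMRError):
    """No SNP survives instrument selection; MR cannot proceed."""


class EmptyHarmonizationError(TwoStepMRError):
    """Every instrument was dropped during harmonization or outcome filtering."""


class InsufficientInstrumentsError(TwoStepMRError):
    """An estimator needs more instruments than are available."""


class UnderdeterminedError(TwoStepMRError):
    """Multivariable regression with J <= number of regressors."""


class CollinearityError(TwoStepMRError):
    """The exposure-beta matrix is rank deficient."""


class ScaleMismatchError(TwoStepMRError):
    """Arithmetic attempted across incompatible effect scales (sd vs log-odds)."""


class UndefinedProportionError(TwoStepMRError):
    """Proportion mediated requested with a zero total effect."""


class ConfigError(TwoStepMRError):
    """An analysis or simulation configuration field is invalid."""
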