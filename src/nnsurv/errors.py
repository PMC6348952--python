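"""Exception hierarchy shared across the package."""


class NnsurvError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(NnsurvError, ValueError):
    """A tabular input file is malformed (missing column, bad event codes...)."""


class ExtrapolationError(NnsurvError, ValueError):
    """A survival probability was requested past the end of the time grid.

    The discrete-time model carries no information beyond the last interval
    boundary, so no extrapolation rule is defined.
    """


class MetricUndefinedError(NnsurvError, ValueError):
    """A metric has no defined value on this input.

    Raised e.g. when the concordance index has no comparable pairs, or when
    the censoring survival function used for Brier weighting reaches zero.
    """


class TrainingDivergedError(NnsurvError, RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int, loss: float):
        self.epoch = epoch
        self.loss = loss
        super().__init__(
            f"training loss became non-finite ({loss}) at epoch {epoch}; "
            "reduce the learning rate or check the input data"
        )
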