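"""Exception hierarchy for the screening funnel."""


class CholScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CholScreenError):
    """A file is structurally malformed (bad header, unparseable cell)."""


class ValidationError(CholScreenError):
    """Parsed content violates a domain invariant."""


class MissingGroupError(CholScreenError):
    """A required treatment group has no observations."""


class DegenerateDenominatorError(CholScreenError):
    """Ethanol-only and control means coincide: no ethanol-induced cell
    death to normalise against."""


class InsufficientDataError(CholScreenError):
    """Fewer values than the statistic requires."""


class DegenerateMeanError(CholScreenError):
    """Mean of zero: coefficient of variation undefined."""


class DegenerateVarianceError(CholScreenError):
    """A variable has zero variance: Pearson correlation undefined."""


class InsufficientStrainsError(CholScreenError):
    """Fewer than three strains share protein and phenotype values."""


class UncategorizedError(CholScreenError):
    """A phenotype label matched no rule and no fallthrough is set."""


class PipelineStageError(CholScreenError):
    """A funnel stage failed; carries the stage name and the partial report.

    Attributes
    ----------
    stage : str
        Name of the stage that raised.
    partial_report : FunnelReport
        Stages completed before the failure.
    """

    def __init__(self, stage, cause, partial_report):
        super().__init__(f"funnel aborted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial_report = partial_report
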