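"""Exception hierarchy for surveyscreen."""


class SurveyScreenError(Exception):
    """Base class for all surveyscreen errors."""


class ConfigurationError(SurveyScreenError):
    """A configuration file or field mapping is invalid."""


class ProtocolError(SurveyScreenError):
    """A protocol run cannot proceed (e.g. a record falls outside every era)."""


class EvaluationError(SurveyScreenError):
    """An evaluation operation received inconsistent inputs."""


class ScenarioError(SurveyScreenError):
    """A synthetic-cohort scenario is internally impossible."""
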