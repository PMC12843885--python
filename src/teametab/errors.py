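"""Exception types shared across the pipeline."""


class TeametabError(Exception):
    """Base class for all pipeline errors."""


class InvalidDesignError(TeametabError):
    """The experimental design (stages/replicates/weights) is unusable."""


class EmptyInputError(TeametabError):
    """An operation received no data where at least one record is required."""


class FilterParameterError(TeametabError):
    """A filtering threshold is outside its valid range."""


class FormulaError(TeametabError):
    """A molecular formula could not be parsed or is chemically invalid."""


class InapplicableRuleError(TeametabError):
    """An ionisation rule was applied to a formula it cannot act on."""


class EnumerationLimitError(TeametabError):
    """Formula enumeration would exceed the candidate budget."""


class DegenerateTestError(TeametabError):
    """A statistical test was handed data it cannot meaningfully assess."""


class GraphError(TeametabError):
    """Knowledge-graph nodes referenced by an operation are absent."""


class PipelineError(TeametabError):
    """An orchestration step failed; the message names the step."""
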