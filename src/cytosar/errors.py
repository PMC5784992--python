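"""Exception hierarchy shared across the package."""


class CytosarError(Exception):
    """Base class for all package errors."""


class StructureParseError(CytosarError):
    """Input text could not be parsed as a molecular structure."""


class StructureError(CytosarError):
    """Structure parsed but is chemically inconsistent (e.g. valence)."""


class InvalidStructureError(CytosarError):
    """Operation refused because the molecule fails admissibility criteria."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "structure fails admissibility criteria: "
            + ", ".join(report.failures)
        )


class UnknownUnitError(CytosarError):
    """Concentration unit outside the supported molar family."""


class SchemaError(CytosarError):
    """Tabular input is missing mandatory columns."""


class EmptyTrainingSetError(CytosarError):
    """No cell line survived the eligibility filters."""


class OutOfDomainError(CytosarError):
    """Query shares no descriptor with the training vocabulary."""


class ModelError(CytosarError):
    """Model fitting or loading failed (degenerate class, bad file)."""
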