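"""Exception hierarchy shared across the pipeline."""


class DDIScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DDIScreenError):
    """Invalid user-supplied configuration (columns, ranges, file schema)."""


class StructureError(DDIScreenError):
    """A molecule could not be parsed or fingerprinted.

    Carries ``drug_id`` so callers can report which record failed.
    """

    def __init__(self, message: str, drug_id: str | None = None):
        super().__init__(message)
        self.drug_id = drug_id


class ComparabilityError(DDIScreenError):
    """Two objects with incompatible parameters (bit length, radius, dimension)."""


class CatalogError(DDIScreenError):
    """Invalid or unknown DDI-type catalogue content."""


class DataError(DDIScreenError):
    """Inconsistent tabular data (unresolvable ids, bad labels)."""


class ProvenanceError(DDIScreenError):
    """Model and featurization provenance (reference digest) do not match."""
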