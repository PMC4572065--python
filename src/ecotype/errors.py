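"""Exception hierarchy used across the package."""


class EcotypeError(Exception):
    """Base class for all package errors."""


class FormatError(EcotypeError):
    """Input table or file does not match the documented schema."""


class DataIntegrityError(EcotypeError):
    """Inputs parse but contradict each other (e.g. allele/contig mismatch)."""


class ConfigError(EcotypeError):
    """Invalid configuration, unknown sample/marker ids, bad thresholds."""


class DegenerateDataError(EcotypeError):
    """A statistic is undefined on the given data (all missing, zero variance)."""


class MonomorphicMarkerError(DegenerateDataError):
    """Exact heterozygosity test requested for a marker with one observed allele."""
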