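"""Exception hierarchy for the transferome package."""


class TransferomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TransferomeError):
    """Invalid run configuration or parameter value."""


class FormatError(TransferomeError):
    """Malformed input file (FASTA/FASTQ/TSV)."""
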