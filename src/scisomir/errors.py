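"""Exception hierarchy.

The CLI maps these onto distinct exit codes so shell pipelines can tell
usage problems, malformed input files and mid-run processing failures apart.
"""


class ScisomirError(Exception):
    """Base class for all package errors."""


class ConfigError(ScisomirError):
    """Invalid configuration or invalid combination of options."""


class FormatError(ScisomirError):
    """Malformed input file (FASTA/GFF3/FASTQ/TSV)."""


class ProcessingError(ScisomirError):
    """A record-level failure while running a pipeline stage."""
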