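"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`LdFingerprintError` so the CLI can map failures to a single
exit code.
"""


class LdFingerprintError(Exception):
    """Base class for all errors raised by ldfingerprint."""


class MapFormatError(LdFingerprintError):
    """A haplotype-map file line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class MapStructureError(LdFingerprintError):
    """The parsed map violates a structural invariant (bad anchor refs,
    duplicate positions, ...)."""


class MapValidationError(LdFingerprintError):
    """A field value is outside its legal domain (e.g. MAF > 0.5)."""


class ChecksumMismatchError(LdFingerprintError):
    """Fingerprints bound to different haplotype maps were combined."""


class ContigMismatchError(LdFingerprintError):
    """The alignment input lacks contigs required by the haplotype map."""

    def __init__(self, missing: list[str]):
        super().__init__(
            "alignment input is missing map contigs: " + ", ".join(sorted(missing))
        )
        self.missing = sorted(missing)


class MonomorphicSnpError(LdFingerprintError):
    """r^2 is undefined for a monomorphic column."""


class DuplicateSourceError(LdFingerprintError):
    """Two observations from the same read-pair reached one block."""


class InsufficientReadsError(LdFingerprintError):
    """A contamination mixture requested more reads than are available."""


class ConfigurationError(LdFingerprintError):
    """Invalid or inconsistent configuration."""
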