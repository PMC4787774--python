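"""Exception hierarchy.

CLI exit-code mapping: InputError -> 1, ConfigurationError -> 2.
"""


class BgcforgeError(Exception):
    """Base class for all package errors."""


class InputError(BgcforgeError):
    """Unreadable, empty, or oversized input file."""


class FormatError(InputError):
    """Input file is not recognizable FASTA or GenBank."""


class ConfigurationError(BgcforgeError):
    """Missing or inconsistent reference data / backend configuration."""


class MonomerLibraryError(ConfigurationError):
    """A predicted substrate has no structure in the monomer library."""
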