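"""Exception hierarchy shared across the suite."""


class VcbenchError(Exception):
    """Base class for all suite errors."""


class VcfParseError(VcbenchError, ValueError):
    """Malformed VCF input; message names the offending record."""


class BedParseError(VcbenchError, ValueError):
    """Malformed BED input."""


class ReferenceLookupError(VcbenchError, KeyError):
    """Contig absent or coordinates out of range in the reference."""


class ReferenceMismatchError(VcbenchError, ValueError):
    """A record's REF string disagrees with the reference sequence."""


class NullVariantError(VcbenchError, ValueError):
    """ref == alt after parsimony trimming; the record encodes no edit."""


class ConfigError(VcbenchError, ValueError):
    """Invalid user configuration (unknown threshold parameter, bad rates...)."""


class DataError(VcbenchError, ValueError):
    """Input data violates a precondition (e.g. single-class ROC input)."""
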