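"""Exception types shared across the package."""


class EpitopeScanError(Exception):
    """Base class for all package-specific errors."""


class DatasetError(EpitopeScanError, ValueError):
    """Malformed or inconsistent labeled-peptide dataset."""


class ParseError(EpitopeScanError, ValueError):
    """Structurally invalid annotation file."""


class ConsistencyError(EpitopeScanError, ValueError):
    """Annotation or coordinate content disagrees with the expected sequence."""


class MissingParentError(EpitopeScanError, ValueError):
    """An operation needed the parent protein sequence but none was attached."""


class AlphabetError(EpitopeScanError, ValueError):
    """A sequence contains characters outside the 20 standard residues."""


class ModelFormatError(EpitopeScanError, ValueError):
    """A serialized model file is corrupt or has an unsupported version."""
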