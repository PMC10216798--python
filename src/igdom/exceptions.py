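"""Exception hierarchy. Every error raised by igdom derives from IgdomError."""


class IgdomError(Exception):
    """Base class for igdom errors."""


class FormatError(IgdomError):
    """Malformed input file (ragged alignment, bad CSV, unparseable PDB)."""


class AlphabetError(IgdomError):
    """Symbol outside the 24-symbol alignment alphabet."""


class MetadataError(IgdomError):
    """Sequence id without a metadata record, or malformed metadata table."""


class InputError(IgdomError):
    """Semantically invalid input (empty alignment, all-gap row, bad vector)."""


class ParameterError(IgdomError):
    """Out-of-range analysis parameter (window too large, too many components)."""


class SelectionError(IgdomError):
    """Requested chain or residue absent from a structure."""


class SyntheticSpecError(IgdomError):
    """Inconsistent synthetic-data specification."""


class ConstructionError(IgdomError):
    """Toy-dimer geometry could not satisfy its contact plan."""
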