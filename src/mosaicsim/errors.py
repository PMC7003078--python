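"""Exception hierarchy used across the package."""


class MosaicSimError(Exception):
    """Base class for all package errors."""


class ParameterError(MosaicSimError, ValueError):
    """A configuration or argument value violates its contract."""


class ConfigurationError(MosaicSimError, ValueError):
    """A scenario/schedule combination is internally inconsistent."""


class EmptyPanelError(MosaicSimError):
    """Founder simulation produced zero segregating sites."""


class EmptyDatasetError(MosaicSimError):
    """All SNP columns were removed by filtering."""


class FormatError(MosaicSimError, ValueError):
    """An external file does not conform to the documented layout."""
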