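"""Exception hierarchy shared across the package."""


class PathscreenError(Exception):
    """Base class for all package-specific errors."""


class ManifestError(PathscreenError):
    """Problems with a library manifest."""


class ManifestParseError(ManifestError):
    """A manifest file could not be parsed (names the offending line)."""


class ManifestValidationError(ManifestError):
    """A manifest violates a structural invariant."""


class CapacityError(ManifestError):
    """More barcodes requested than a code at the given distance can hold."""


class LayoutError(PathscreenError):
    """A read, index, or linker is inconsistent with the read layout."""


class SchemaError(PathscreenError):
    """Two tables that must share a construct/sample schema do not."""


class ConfigurationError(PathscreenError):
    """A pipeline step was configured inconsistently with its inputs."""


class DemuxError(PathscreenError):
    """A FASTQ file could not be read (names the file and record)."""
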