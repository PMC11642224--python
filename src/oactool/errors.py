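"""Exception hierarchy for the oactool pipeline."""


class OactoolError(Exception):
    """Base class for all oactool errors."""


class ConfigurationError(OactoolError):
    """Missing or inconsistent configuration (sidecar fields, pipeline config)."""


class DataError(OactoolError):
    """Input data violates a contract (negative intensities, out-of-range indices)."""


class SegmentationFailure(OactoolError):
    """Automated boundary detection failed on too many columns.

    Mirrors the clinical situation where the ellipsoid-zone band is so
    disrupted that slab definition is not meaningful; callers may fall back
    to an externally supplied boundary surface.
    """


class PhantomSpecError(OactoolError):
    """Invalid synthetic phantom specification (e.g. overlapping layers)."""
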