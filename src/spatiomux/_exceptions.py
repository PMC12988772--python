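"""Exception hierarchy shared across the package."""


class SpatiomuxError(Exception):
    """Base class for all package-specific errors."""


class InvalidPolygonError(SpatiomuxError, ValueError):
    """Polygon has fewer than three distinct vertices or zero area where area is required."""


class NoExtentError(SpatiomuxError, ValueError):
    """Sample carries no image and no cells, so no spatial extent can be derived."""


class UidCollisionError(SpatiomuxError, ValueError):
    """Two samples with the same UID were combined in one experiment."""


class ConfigError(SpatiomuxError, ValueError):
    """Assembly configuration file is malformed."""


class ProjectError(SpatiomuxError, RuntimeError):
    """On-disk project is missing, corrupted, or does not match the object being saved."""


class RegistrationError(SpatiomuxError, RuntimeError):
    """Image registration failed; carries the failing stage and QC counts.

    Parameters
    ----------
    stage : name of the pipeline stage that failed.
    counts : mapping of QC counters (keypoints, matches, ...) observed up to
        the failure; kept so callers can log the failure as a QC record.
    """

    def __init__(self, message: str, stage: str = "", counts: dict | None = None):
        super().__init__(message)
        self.stage = stage
        self.counts = dict(counts or {})


class FeatureMismatchError(SpatiomuxError, ValueError):
    """Two expression matrices share no features."""
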