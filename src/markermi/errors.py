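"""Exception hierarchy shared across the package."""


class MarkerMIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MarkerMIError):
    """A named column, marker, method tag or option does not exist / is invalid."""


class EmptyInputError(MarkerMIError):
    """No usable rows (cells or subjects) remain after loading or filtering."""


class DegenerateMarkerError(MarkerMIError):
    """A marker is constant over its normalization or estimation stratum."""


class DegenerateInputError(MarkerMIError):
    """Input lacks the variation a statistical procedure needs (e.g. one-class outcome)."""


class CollinearityError(MarkerMIError):
    """Design matrix is rank deficient; the message names the offending columns."""


class ClusterCountError(MarkerMIError):
    """Requested number of clusters cannot be formed from the given profiles."""


class ScenarioError(MarkerMIError):
    """A simulation scenario is misconfigured or repeatedly fails its validity checks."""
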