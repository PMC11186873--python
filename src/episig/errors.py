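"""Exception hierarchy.

Each error family carries a distinct process exit code so that shell
pipelines can distinguish configuration mistakes from data problems.
"""


class EpisigError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(EpisigError):
    """Invalid configuration or parameter combination."""

    exit_code = 2


class ValidationError(EpisigError):
    """Malformed input data (values out of range, duplicate ids, ...)."""

    exit_code = 3


class MatchingError(EpisigError):
    """Control matching is infeasible for at least one case."""

    exit_code = 4


class FixtureCorruptionError(EpisigError):
    """A packaged fixture table failed its checksum."""

    exit_code = 5


class EmptyCohortError(EpisigError):
    """Every sample was removed by quality control."""

    exit_code = 6
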