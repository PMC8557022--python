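"""Exception hierarchy for methnet.

Every anticipated failure mode raises a subclass of :class:`MethnetError`
so callers (and the CLI) can distinguish bad input from bugs.
"""


class MethnetError(Exception):
    """Base class for all methnet errors."""


class InvalidArgumentError(MethnetError, ValueError):
    """An argument is outside its documented domain."""


class InconsistentInputError(MethnetError, ValueError):
    """Two inputs that must align (e.g. shared probe ids) do not."""


class InvalidDesignError(MethnetError, ValueError):
    """Design matrix is rank deficient or otherwise unusable."""


class InsufficientSamplesError(MethnetError, ValueError):
    """Too few samples for the requested statistic."""


class MissingProbesError(MethnetError, KeyError):
    """Clock (or other) probes absent from a beta matrix."""

    def __init__(self, probe_ids):
        self.probe_ids = list(probe_ids)
        super().__init__(
            f"{len(self.probe_ids)} required probe(s) missing from beta matrix: "
            f"{self.probe_ids[:10]}{'...' if len(self.probe_ids) > 10 else ''}"
        )


class NamingMismatchError(MethnetError, ValueError):
    """Chromosome naming conventions disagree between inputs."""


class EmptyNetworkError(MethnetError, ValueError):
    """Network construction retained no edges."""


class NoOverlapError(MethnetError, ValueError):
    """Two gene universes that must intersect are disjoint."""


class DegenerateVarianceError(MethnetError, ValueError):
    """Both groups have zero variance but different means."""
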