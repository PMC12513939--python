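"""Exception hierarchy for the benchmarking cycle pipeline."""


class BenchcycleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BenchcycleError):
    """A config file, column set, or parameter combination is invalid."""


class EmptyCohortError(BenchcycleError):
    """An operation that requires patients received none."""


class DataIntegrityError(BenchcycleError):
    """Input values violate a structural constraint (e.g. events > n)."""


class RegistryKeyError(BenchcycleError, KeyError):
    """No benchmark entry exists for a (procedure, outcome, stratum) key."""

    def __init__(self, procedure: str, outcome: str, stratum: str):
        self.key = (procedure, outcome, stratum)
        super().__init__(
            f"no benchmark entry for procedure={procedure!r}, "
            f"outcome={outcome!r}, stratum={stratum!r}"
        )

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]
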