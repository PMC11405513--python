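"""Exception types used across the package."""


class ArocmError(Exception):
    """Base class for all package errors."""


class ValidationError(ArocmError):
    """Raised when an input table violates the data contract.

    ``problems`` lists every violation found (offending ids / cells), so a
    caller can report them all at once instead of fixing one at a time.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class DegenerateStratumError(ArocmError):
    """Raised when a stratum cannot support an estimate.

    ``reason`` is a machine-readable code (e.g. ``"constant_ages"``,
    ``"constant_methyl"``, ``"too_few_samples"``) so that filtering code can
    log why a stratum was dropped rather than propagating NaN.
    """

    def __init__(self, reason: str, stratum_id: str | None = None):
        self.reason = reason
        self.stratum_id = stratum_id
        where = f" in stratum {stratum_id!r}" if stratum_id else ""
        super().__init__(f"degenerate stratum{where}: {reason}")
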