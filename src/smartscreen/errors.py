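"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 1, CohortValidationError -> 2,
I/O problems (OSError) -> 3.
"""


class SmartScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(SmartScreenError):
    """A ruleset, threshold file, message catalog or run configuration is invalid."""


class FormatError(SmartScreenError):
    """An input file could not be parsed in the named dialect."""

    def __init__(self, message: str, *, path: str | None = None, record: str | int | None = None):
        self.path = path
        self.record = record
        loc = []
        if path is not None:
            loc.append(str(path))
        if record is not None:
            loc.append(f"record {record}")
        suffix = f" [{', '.join(loc)}]" if loc else ""
        super().__init__(message + suffix)


class CohortValidationError(SmartScreenError):
    """One or more person records violate a data invariant.

    Carries the individual findings so callers can report field and person_id.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in self.findings[:10])
        more = f" (+{len(self.findings) - 10} more)" if len(self.findings) > 10 else ""
        super().__init__(f"{len(self.findings)} validation finding(s): {lines}{more}")


class InfeasibleSpecError(SmartScreenError):
    """A synthetic-cohort specification cannot be satisfied."""
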