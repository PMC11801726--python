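"""Exception hierarchy mapped to CLI exit codes."""


class MethylPredictError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(MethylPredictError):
    """I/O problem: missing file, unreadable format. Exit code 2."""

    exit_code = 2


class ValidationError(MethylPredictError):
    """Data violates a contract (bounds, duplicates, alignment). Exit code 3."""

    exit_code = 3


class NumericError(MethylPredictError):
    """Numerical failure (degenerate target, rank deficiency, no variance). Exit code 4."""

    exit_code = 4
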