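"""Exception hierarchy with distinct CLI exit codes per failure class."""


class EpicrossError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(EpicrossError):
    """A file or stream could not be parsed."""

    exit_code = 3


class ValidationError(EpicrossError):
    """Inputs parsed but violate a contract (bad spec, inconsistent grids...)."""

    exit_code = 4


class ComputationError(EpicrossError):
    """A stage failed during computation despite valid inputs."""

    exit_code = 5
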