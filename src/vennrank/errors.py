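"""Error hierarchy shared by all pipeline stages.

Each class carries the process exit code the CLI maps it to, so library
callers and the command-line wrapper agree on failure semantics.
"""


class VennRankError(Exception):
    """Base class for all vennrank failures."""

    exit_code = 1


class UsageError(VennRankError):
    """The caller asked for something invalid (bad expression, too few files)."""

    exit_code = 2


class InputError(VennRankError):
    """An input file is malformed (empty, short row, conflicting annotation)."""

    exit_code = 3


class AnalysisError(VennRankError):
    """The analysis cannot proceed on these inputs (e.g. no seeds in network)."""

    exit_code = 4
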