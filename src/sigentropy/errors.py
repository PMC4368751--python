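"""Exception hierarchy.

All package-specific failures derive from :class:`SigentropyError` so callers
(and the CLI) can distinguish bad input from numerical breakdown.
"""


class SigentropyError(Exception):
    """Base class for all errors raised by sigentropy."""


class ParseError(SigentropyError):
    """A data file could not be parsed; the message names the offending line."""


class NetworkValidationError(SigentropyError):
    """The interaction network violates a structural precondition."""


class BipartiteNetworkError(NetworkValidationError):
    """The network is bipartite, so the expression-weighted walk is periodic.

    Carries the two-colouring witness in :attr:`partition`.
    """

    def __init__(self, message, partition=None):
        super().__init__(message)
        self.partition = partition


class DegenerateNetworkError(NetworkValidationError):
    """The usable component is too small to carry a random walk."""


class PositivityError(SigentropyError):
    """An expression value is nonpositive or non-finite; names the gene."""


class AlignmentError(SigentropyError):
    """Two objects that must share an index (genes, samples) do not."""


class InternalConsistencyError(SigentropyError):
    """Two redundant computations of the same quantity disagree.

    Signals a broken precondition (e.g. a disconnected or bipartite graph
    slipping past validation), not a user-input problem.
    """


class NumericalError(SigentropyError):
    """An iterative numerical routine failed (non-convergence etc.)."""


class ConvergenceError(NumericalError):
    """A model fit diverged, e.g. monotone partial likelihood / separation."""


class SignatureCoverageError(SigentropyError):
    """Too few signature genes remain in the matrix to define the score."""


class EmptySignatureError(SigentropyError):
    """Signature derivation produced no genes."""


class StratificationError(SigentropyError):
    """Scores cannot be split into the requested groups."""


class UndefinedTestError(SigentropyError):
    """A statistical test is undefined on the given input (e.g. all-zero
    differences for the signed-rank test, no comparable pairs for the
    concordance index)."""
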