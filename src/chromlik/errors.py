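"""Exception hierarchy shared across the package."""


class ChromlikError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ChromlikError, ValueError):
    """A caller supplied an argument outside the documented domain."""


class ModelDefinitionError(ChromlikError, ValueError):
    """A rate-matrix builder produced an invalid infinitesimal generator."""


class DataError(ChromlikError, ValueError):
    """Tip observations are inconsistent with the tree or the state space."""


class NewickParseError(ChromlikError, ValueError):
    """A Newick string could not be parsed."""


class NestingError(ChromlikError, ValueError):
    """Two fits submitted to a likelihood-ratio test are not properly nested."""
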