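"""Exception hierarchy shared across the package."""


class NetstabError(Exception):
    """Base class for all package-specific errors."""


class GraphFormatError(NetstabError):
    """A graph file could not be parsed in the requested dialect."""


class DomainError(NetstabError, ValueError):
    """An argument is outside its documented domain."""


class GraphTooDenseError(NetstabError):
    """Rewiring could not place the requested number of new edges."""


class CatalogueError(NetstabError, KeyError):
    """Unknown community-detection method name."""


class ValidationError(NetstabError, ValueError):
    """Invalid parameter value or inconsistent input objects."""
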