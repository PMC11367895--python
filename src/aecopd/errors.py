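"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed input data (bad CSV cells, unknown
codes, broken invariants); ``ConfigError`` covers bad run configuration
(missing paths, invalid rule tables / simulator settings). The CLI maps
these onto exit codes 1 and 2 respectively.
"""


class AecopdError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AecopdError, ValueError):
    """Input data violates a schema or domain invariant."""


class ConfigError(AecopdError):
    """Run or simulator configuration is invalid or unreadable."""


class DegenerateTableError(AecopdError):
    """Agreement statistic undefined for this contingency table."""
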