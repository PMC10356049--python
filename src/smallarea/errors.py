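"""Exception hierarchy for the small-area analysis pipeline.

Validation is total: files or configs violating a stated invariant raise one
of these with a located message; nothing is silently repaired.
"""


class SmallAreaError(Exception):
    """Base class for all package errors."""


class SchemaError(SmallAreaError):
    """A table or geometry layer violates the data contract."""


class ConnectivityError(SmallAreaError):
    """The township adjacency graph is disconnected (ICAR prior undefined).

    Carries the connected components so the user can locate the islands.
    """

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        preview = "; ".join(
            f"component {k}: {c[:5]}{'...' if len(c) > 5 else ''}"
            for k, c in enumerate(self.components)
        )
        super().__init__(
            f"adjacency graph has {len(self.components)} connected components "
            f"(must be 1 for the ICAR prior): {preview}"
        )


class ConfigError(SmallAreaError):
    """An invalid configuration value."""


class ContractError(SmallAreaError):
    """Two pipeline stages were combined with inconsistent settings."""
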