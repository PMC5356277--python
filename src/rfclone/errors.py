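"""Exception hierarchy for the cloning toolkit.

Every failure mode a caller may want to catch programmatically has its own
class; all inherit from :class:`CloningError` so the CLI can surface any
toolkit failure with a single handler.
"""

from __future__ import annotations


class CloningError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(CloningError, ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class CoordinateError(CloningError, ValueError):
    """A 1-based coordinate is out of range for the sequence."""


class AnchorNotFoundError(CloningError, ValueError):
    """An anchor subsequence does not occur in the search sequence."""

    def __init__(self, anchor: str, seq_id: str):
        self.anchor = anchor
        self.seq_id = seq_id
        super().__init__(f"anchor {anchor!r} not found in sequence {seq_id!r}")


class AnchorAmbiguityError(CloningError, ValueError):
    """An anchor required to be unique occurs more than once."""

    def __init__(self, anchor: str, seq_id: str, positions: list[int]):
        self.anchor = anchor
        self.seq_id = seq_id
        self.positions = positions
        super().__init__(
            f"anchor {anchor!r} occurs {len(positions)} times in sequence "
            f"{seq_id!r} at 1-based positions {positions}"
        )


class GeometryError(CloningError, ValueError):
    """Overhang regions, stuffer and backbone do not tile the vector."""


class PrimingError(CloningError, ValueError):
    """Base class for primer-binding failures during simulated PCR."""


class NoBindingError(PrimingError):
    """A primer body has no exact match on the template."""

    def __init__(self, primer_name: str, template_id: str):
        self.primer_name = primer_name
        self.template_id = template_id
        super().__init__(
            f"primer {primer_name!r} has no exact binding site on template "
            f"{template_id!r}"
        )


class AmbiguousPrimingError(PrimingError):
    """A primer body matches the template at more than one site."""

    def __init__(self, primer_name: str, template_id: str, positions: list[int]):
        self.primer_name = primer_name
        self.template_id = template_id
        self.positions = positions
        super().__init__(
            f"primer {primer_name!r} binds template {template_id!r} at "
            f"{len(positions)} sites (1-based positions {positions})"
        )


class AnnealingError(CloningError, ValueError):
    """Two strands share no perfect complementary core of sufficient length."""


class AnnealingMismatchError(AnnealingError):
    """The best strand pairing contains internal mismatches."""

    def __init__(self, positions: list[int]):
        self.positions = positions
        super().__init__(
            f"annealed core contains mismatches at top-strand positions {positions}"
        )


class LigationError(CloningError, ValueError):
    """Two fragment ends are not cohesive-compatible."""


class FixtureError(CloningError, RuntimeError):
    """The synthetic fixture generator exhausted its retry budget."""
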