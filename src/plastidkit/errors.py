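"""Exception hierarchy.

Domain errors (bad sequences, bad images, bad tables) derive from
:class:`PlastidkitError` so the CLI can map them to exit code 1, distinct
from usage errors (exit 2).
"""


class PlastidkitError(ValueError):
    """Base class for all domain errors raised by plastidkit."""


class FrameError(PlastidkitError):
    """Sequence length is not a positive multiple of three."""


class AlphabetError(PlastidkitError):
    """Sequence contains characters outside {A, C, G, T}."""


class NonSynonymousError(PlastidkitError):
    """Two coding sequences differ at the amino-acid level."""

    def __init__(self, positions):
        self.positions = list(positions)
        super().__init__(
            "sequences are not synonymous recodings; amino acids differ at "
            f"codon positions (1-based): {self.positions}"
        )
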