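"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2 (bad input / bad parameters);
``PanelScanError`` maps to exit code 3 (the window scan hit a position with
fewer complete samples than the requested panel size and must terminate).
"""


class ChimpanelError(Exception):
    """Base class for all package errors."""


class ValidationError(ChimpanelError):
    """Invalid input data or parameters."""


class PanelScanError(ChimpanelError):
    """The window scan cannot satisfy the panel size at some position.

    Raised when shrinking reaches a single site whose complete-sample count is
    below the requested minimum; carries the offending 1-based position.
    """

    def __init__(self, chrom: str, position: int, n_complete: int, required: int):
        self.chrom = chrom
        self.position = position
        self.n_complete = n_complete
        self.required = required
        super().__init__(
            f"cannot assemble panel: position {chrom}:{position} has only "
            f"{n_complete} samples with complete genotypes but {required} are "
            f"required; filter the input more stringently or lower the panel size"
        )


class InfeasibleMaskError(ValidationError):
    """The requested masked-cell count cannot fit under the per-site cap."""
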