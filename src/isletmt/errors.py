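"""Exception types shared across the package."""


class IsletMTError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IsletMTError):
    """A configuration value is missing, malformed, or inconsistent."""


class PackingError(IsletMTError):
    """Nucleus packing could not place the requested number of cells."""

    def __init__(self, requested: int, achieved: int, message: str | None = None):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            message
            or f"could not pack {requested} nuclei: placed {achieved} "
            f"before exhausting rejection attempts"
        )


class DegenerateHistogramError(IsletMTError):
    """The intensity histogram has a single occupied bin (constant image)."""


class NoSpheroidError(IsletMTError):
    """No foreground object of sufficient volume was found in the stack."""


class StackBoundsError(IsletMTError):
    """One or more cells fall outside the requested stack extent."""

    def __init__(self, offending_ids: list[int]):
        self.offending_ids = list(offending_ids)
        super().__init__(
            f"{len(self.offending_ids)} cell(s) outside stack bounds: "
            f"{self.offending_ids}"
        )
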