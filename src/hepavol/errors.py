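"""Exception hierarchy.

``ValidationError`` covers bad user input (files, tables, configs, edits);
``ContractError`` covers programming-contract breaches (misaligned grids,
dimension mismatches); everything else derives from ``HepavolError`` so a
caller can catch the whole family.
"""


class HepavolError(Exception):
    """Base class for all package errors."""


class ValidationError(HepavolError):
    """Invalid user-supplied input (file, table, config, edit list)."""


class ContractError(HepavolError):
    """A call-site contract was violated (shapes, alignment, ordering)."""


class DegenerateDataError(HepavolError):
    """Input data cannot support the requested estimate (e.g. zero variance)."""


class EmptySegmentationError(HepavolError):
    """A segmentation step selected no voxels."""


class PlacementError(HepavolError):
    """Phantom lesions could not be placed without overlap."""


class StageError(HepavolError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
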