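"""Stage-labeled pipeline failures."""

from __future__ import annotations

__all__ = ["StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
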