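"""Failure semantics for the measurement pipeline.

Every stage of the automated index computation can fail on real data
(motion artefacts, missing landmarks, degenerate registration).  A failed
stage must never produce a fabricated number: it raises
:class:`StageFailure`, which the subject-level driver converts into an
``IndexResult`` with ``status="failed"`` and the offending stage recorded.
"""

from __future__ import annotations

# Closed set of pipeline stages, in execution order.
STAGES = (
    "registration",
    "intensity",
    "landmarks",
    "midsagittal",
    "slab",
    "brainstem",
    "ventricles",
)


class StageFailure(Exception):
    """A pipeline stage could not produce a valid measurement.

    Parameters
    ----------
    stage : str
        One of :data:`STAGES`.
    message : str
        Human-readable reason (e.g. the name of the missing landmark).
    """

    def __init__(self, stage: str, message: str):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class ConstructionError(ValueError):
    """Phantom geometry is invalid (collision or out-of-bounds structure)."""


class VolumeIOError(IOError):
    """A volume file could not be read or written (distinct from pipeline failure)."""
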