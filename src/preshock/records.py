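"""Core record container and package-wide error types."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Outcome labels: return / no return of organized electrical activity
#: after the defibrillation shock.
LABEL_ROEA = "ROEA"
LABEL_NOROEA = "NoROEA"
LABEL_UNKNOWN = "unknown"
VALID_LABELS = (LABEL_ROEA, LABEL_NOROEA, LABEL_UNKNOWN)

#: Integer class codes used by the classifier: 1 = NoROEA, 2 = ROEA.
LABEL_TO_CODE = {LABEL_NOROEA: 1, LABEL_ROEA: 2}
CODE_TO_LABEL = {1: LABEL_NOROEA, 2: LABEL_ROEA}


class InsufficientBeatsError(ValueError):
    """Raised when a record has too few detected beats for a feature."""


class DegenerateGroupsError(ValueError):
    """Raised when group data cannot support a one-way F statistic."""


@dataclass(frozen=True)
class ECGRecord:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples:
        Voltage samples in millivolts.
    fs:
        Sampling frequency in Hz.
    record_id:
        Identifier used in manifests and reports.
    label:
        Shock outcome: ``"ROEA"``, ``"NoROEA"`` or ``"unknown"``.
    """

    samples: np.ndarray
    fs: float
    record_id: str = "record"
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a nonempty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"record {self.record_id!r}: non-finite samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "ECGRecord":
        """Copy of this record with new samples (and optionally a new rate)."""
        return replace(self, samples=samples, fs=self.fs if fs is None else fs)
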