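"""Head-motion censoring and quality control on framewise-displacement traces.

A volume is censored when its framewise displacement (FD, mm) exceeds a hard
limit (default 3 mm, strict) or exceeds the session mean by more than a given
number of sample standard deviations (default 2, strict).  A session passes QC
when its censored fraction does not exceed the QC threshold (default 20%,
boundary inclusive: a fraction exactly equal to the threshold passes).

The mean FD (mFD) covariate is computed on the full, uncensored trace: it is a
session-level motion characteristic, not a post-censoring quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, ValidationError

FD_LIMIT_MM = 3.0
OUTLIER_SIGMA = 2.0
QC_THRESHOLD = 0.20


@dataclass
class FdTrace:
    """Per-volume framewise displacement (mm) for one session."""

    values: np.ndarray
    participant_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size == 0:
            raise DegenerateInputError("empty FD trace")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("FD trace contains non-finite values")
        if np.any(vals < 0):
            raise ValidationError("FD values must be >= 0")
        self.values = vals

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CensorResult:
    keep: np.ndarray
    censored_fraction: float
    qc_pass: bool


def censor_frames(
    trace: FdTrace,
    fd_limit_mm: float = FD_LIMIT_MM,
    outlier_sigma: float = OUTLIER_SIGMA,
    qc_threshold: float = QC_THRESHOLD,
) -> CensorResult:
    """Apply the FD-limit and motion-outlier censoring rules to one trace.

    A volume is censored iff FD > ``fd_limit_mm`` or
    FD > mean(FD) + ``outlier_sigma`` * sd(FD), with sd the sample standard
    deviation (ddof=1) of the session's own trace.  Both inequalities are
    strict, so FD exactly at the limit is kept.
    """
    fd = trace.values
    if fd.size < 3:
        raise DegenerateInputError(f"need at least 3 volumes, got {fd.size}")
    sd = float(np.std(fd, ddof=1))
    outlier_cut = float(np.mean(fd)) + outlier_sigma * sd
    censored = (fd > fd_limit_mm) | (fd > outlier_cut)
    keep = ~censored
    frac = float(1.0 - keep.mean())
    return CensorResult(keep=keep, censored_fraction=frac, qc_pass=frac <= qc_threshold)


def mean_fd(trace: FdTrace) -> float:
    """Arithmetic mean of the full (uncensored) FD trace, in mm."""
    return float(np.mean(trace.values))


def read_fd_trace(path: str | Path, participant_id: str = "", condition: str = "") -> FdTrace:
    """Read a one-column plain-text FD file; a non-numeric first line is a header."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise DegenerateInputError(f"empty FD file: {path}")
    try:
        float(lines[0])
    except ValueError:
        lines = lines[1:]
    values = np.array([float(ln) for ln in lines])
    return FdTrace(values, participant_id=participant_id, condition=condition)


def write_fd_trace(path: str | Path, trace: FdTrace) -> None:
    Path(path).write_text("\n".join(f"{v:.6f}" for v in trace.values) + "\n")
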