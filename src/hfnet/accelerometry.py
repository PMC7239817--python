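"""Accelerometer epoch processing.

Converts per-minute counts-per-minute (cpm) traces into daily-activity
variables: wear time, percent of wear time active/inactive at the 100-cpm
threshold, and the skewness of the wear-time cpm distribution.  Non-wear is
detected with the 60-minute zero-count rule allowing up to two interruption
minutes of 1-99 cpm per run (Troiano convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "EpochTrace",
    "ActivitySummary",
    "integrate_epochs",
    "detect_nonwear",
    "summarize_activity",
    "read_trace_csv",
]

EPOCH_SECONDS = 60
MIN_WEAR_DAYS = 3.0
ACTIVE_THRESHOLD = 100
NONWEAR_RUN_MIN = 60
MAX_INTERRUPT_MIN = 2
INTERRUPT_CPM_MAX = 99


@dataclass(frozen=True)
class EpochTrace:
    """A 60-s-epoch cpm series with strictly increasing epoch-start times."""

    timestamps: np.ndarray  # seconds, 60 s spacing
    cpm: np.ndarray         # non-negative integer counts per minute

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps)
        cpm = np.asarray(self.cpm)
        if ts.shape != cpm.shape or ts.ndim != 1:
            raise ValueError("timestamps and cpm must be 1-D and equal length")
        if len(ts) > 1 and not np.all(np.diff(ts) == EPOCH_SECONDS):
            raise ValueError("timestamps must increase in exact 60-s steps")
        if np.any(cpm < 0):
            raise ValueError("cpm must be non-negative")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "cpm", cpm)

    def __len__(self) -> int:
        return len(self.cpm)


@dataclass(frozen=True)
class ActivitySummary:
    """Per-subject activity variables over wear time.

    ``pct_active + pct_inactive == 100`` of wear time; ``valid`` is False for
    subjects with under 3 wear days (excluded downstream) or with undefined
    moments (no wear, or zero cpm variance for the skewness).
    """

    wear_days: float
    pct_active: float
    pct_inactive: float
    skewness: float
    active_minutes: float
    valid: bool


def integrate_epochs(
    raw_counts: np.ndarray, sample_s: float, epoch_s: int = EPOCH_SECONDS
) -> EpochTrace:
    """Sum uniformly sampled raw counts into fixed-length epochs.

    A partial trailing epoch is discarded.  ``sample_s`` must divide the
    epoch length exactly.
    """
    raw = np.asarray(raw_counts)
    per = epoch_s / sample_s
    if abs(per - round(per)) > 1e-9:
        raise ValueError(
            f"sample spacing {sample_s}s does not divide the {epoch_s}s epoch"
        )
    per = int(round(per))
    n_epochs = len(raw) // per
    sums = raw[: n_epochs * per].reshape(n_epochs, per).sum(axis=1)
    ts = np.arange(n_epochs, dtype=np.int64) * epoch_s
    return EpochTrace(timestamps=ts, cpm=sums)


def detect_nonwear(
    trace: EpochTrace,
    run_min: int = NONWEAR_RUN_MIN,
    max_interrupt: int = MAX_INTERRUPT_MIN,
    interrupt_cpm_max: int = INTERRUPT_CPM_MAX,
) -> np.ndarray:
    """Per-epoch wear mask (True = worn).

    A non-wear interval is a maximal run of >= ``run_min`` minutes of 0 cpm,
    tolerating up to ``max_interrupt`` interior minutes of 1-99 cpm (which
    count toward the run length).  Any epoch >= 100 cpm, or a third
    interruption minute, terminates the candidate run.
    """
    cpm = np.asarray(trace.cpm)
    n = len(cpm)
    wear = np.ones(n, dtype=bool)
    i = 0
    while i < n:
        if cpm[i] != 0:
            i += 1
            continue
        # grow a candidate run of zeros with tolerated low-cpm interruptions
        j = i
        interrupts: list[int] = []
        last_zero = i
        while j < n:
            v = cpm[j]
            if v == 0:
                last_zero = j
                j += 1
            elif v <= interrupt_cpm_max and len(interrupts) < max_interrupt:
                interrupts.append(j)
                j += 1
            else:
                break
        # trailing interruptions do not belong to the run
        end = last_zero + 1
        if end - i >= run_min:
            wear[i:end] = False
        i = max(end, i + 1)
    return wear


def summarize_activity(
    trace: EpochTrace,
    wear_mask: np.ndarray | None = None,
    active_threshold: int = ACTIVE_THRESHOLD,
    min_wear_days: float = MIN_WEAR_DAYS,
) -> ActivitySummary:
    """Compute wear days, % active/inactive and cpm skewness over wear time.

    Skewness is the bias-corrected (adjusted Fisher-Pearson) sample third
    standardized moment of wear-epoch cpm; it is flagged NaN (and the
    summary can still be valid=True if wear time suffices) when the wear
    cpm variance is zero.
    """
    if wear_mask is None:
        wear_mask = detect_nonwear(trace)
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if wear_mask.shape != np.asarray(trace.cpm).shape:
        raise ValueError("wear mask must align with the trace")
    wear_cpm = np.asarray(trace.cpm)[wear_mask]
    wear_days = float(len(wear_cpm)) / 1440.0
    if len(wear_cpm) == 0:
        return ActivitySummary(
            wear_days=0.0, pct_active=float("nan"), pct_inactive=float("nan"),
            skewness=float("nan"), active_minutes=0.0, valid=False,
        )
    active = wear_cpm > active_threshold
    pct_active = 100.0 * active.mean()
    if len(wear_cpm) >= 3 and np.ptp(wear_cpm) > 0:
        skew = float(sps.skew(wear_cpm, bias=False))
    else:
        skew = float("nan")
    return ActivitySummary(
        wear_days=wear_days,
        pct_active=float(pct_active),
        pct_inactive=float(100.0 - pct_active),
        skewness=skew,
        active_minutes=float(active.sum()),
        valid=wear_days >= min_wear_days,
    )


def read_trace_csv(path) -> EpochTrace:
    """Read a per-subject epoch CSV with ``timestamp`` and ``cpm`` columns."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"timestamp", "cpm"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'timestamp' and 'cpm'")
    return EpochTrace(
        timestamps=df["timestamp"].to_numpy(), cpm=df["cpm"].to_numpy()
    )
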