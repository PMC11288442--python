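"""Stride segmentation and per-stride vertical asymmetry parameters.

In trot the head and the pelvis each describe two vertical oscillations per
stride, one per diagonal step.  The four asymmetry parameters HDmin, HDmax,
PDmin and PDmax are, per stride, the signed difference between the two
minimum (resp. maximum) vertical positions of the head (HD) or pelvis (PD).

Sign convention used throughout this package: a stride starts at the
right-forelimb reference event (the pastern sensor's cycle start), so the
first extremum of a kind inside a stride belongs to the right diagonal step
and the second to the left.  Each parameter is defined as

    value(left-step extremum) - value(right-step extremum)

so a *lower* right-step minimum (greater head/pelvic drop during right
stance) gives a positive minimum-difference.  Positive values are therefore
associated with the right fore/hind limb, negative values with the left.
Classification downstream uses absolute values only, so the subtraction
order cannot affect prevalence results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt


class SegmentationError(ValueError):
    """Raised when a reference trace cannot be cut into strides."""


class TraceError(ValueError):
    """Raised for malformed displacement traces."""


@dataclass(frozen=True)
class DisplacementTrace:
    """Uniformly sampled vertical-position time series for one sensor.

    Parameters
    ----------
    location : str
        One of ``"head"``, ``"pelvis"``, ``"pastern"``.
    time : numpy.ndarray
        Sample times in seconds, strictly increasing, uniform grid.
    z : numpy.ndarray
        Vertical position in millimetres.
    """

    location: str
    time: np.ndarray
    z: np.ndarray

    _LOCATIONS = ("head", "pelvis", "pastern")

    def __post_init__(self) -> None:
        if self.location not in self._LOCATIONS:
            raise TraceError(f"unknown sensor location {self.location!r}")
        t = np.asarray(self.time, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if t.ndim != 1 or t.shape != z.shape or t.size < 2:
            raise TraceError("time and z must be 1-D arrays of equal length >= 2")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(z))):
            raise TraceError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TraceError("time must be strictly increasing")
        if np.max(dt) - np.min(dt) > 1e-6 * np.median(dt):
            raise TraceError("sampling interval is not uniform")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "z", z)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class StrideInterval:
    """Half-open time interval [start, end) covering one stride."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StrideRecord:
    """One stride's four asymmetry differences and its duration (mm, s)."""

    index: int
    duration: float
    hd_min: float = np.nan
    hd_max: float = np.nan
    pd_min: float = np.nan
    pd_max: float = np.nan
    flagged: bool = False
    flag_reason: str = ""


def segment_strides(
    reference: DisplacementTrace,
    hysteresis_frac: float = 0.2,
    max_duration_cv: float = 0.5,
) -> list[StrideInterval]:
    """Cut a periodic reference trace into strides at upward zero crossings.

    The reference (right pastern sensor, one cycle per stride) is mean
    centred; a stride boundary is placed at each upward crossing of zero.
    Hysteresis at ``hysteresis_frac`` of the signal amplitude suppresses
    noise-induced crossings: a new crossing is armed only after the signal
    has dropped below minus that fraction of the amplitude.

    Returns a list of contiguous :class:`StrideInterval`, one per cycle.

    Raises
    ------
    SegmentationError
        If fewer than two full cycles are present or the detected cycle
        durations are too irregular (coefficient of variation above
        ``max_duration_cv``), with a diagnostic message.
    """
    z = reference.z - np.mean(reference.z)
    amp = (np.percentile(z, 95) - np.percentile(z, 5)) / 2.0
    if amp <= 0:
        raise SegmentationError("reference trace is constant; no cycles found")
    arm_level = -hysteresis_frac * amp

    t = reference.time
    crossings: list[float] = []
    armed = False
    for i in range(z.size):
        if armed and z[i] >= 0.0:
            if z[i] == 0.0 or i == 0:
                crossings.append(t[i])
            else:
                # linear interpolation between the bracketing samples
                frac = -z[i - 1] / (z[i] - z[i - 1])
                crossings.append(t[i - 1] + frac * (t[i] - t[i - 1]))
            armed = False
        elif not armed and z[i] < arm_level:
            armed = True

    if len(crossings) < 3:
        raise SegmentationError(
            f"need at least 2 full reference cycles, found {max(len(crossings) - 1, 0)}"
        )
    durations = np.diff(crossings)
    cv = np.std(durations) / np.mean(durations)
    if cv > max_duration_cv:
        raise SegmentationError(
            f"reference appears aperiodic: stride-duration CV {cv:.2f} "
            f"exceeds {max_duration_cv:.2f}"
        )
    return [StrideInterval(a, b) for a, b in zip(crossings[:-1], crossings[1:])]


def _local_extrema(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima/minima by 3-point comparison.

    Plateaus are credited to their earliest sample: a maximum requires a
    strict rise from the previous sample and a non-rise to the next.
    """
    if z.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    left = z[1:-1] - z[:-2]
    right = z[2:] - z[1:-1]
    maxima = np.where((left > 0) & (right <= 0))[0] + 1
    minima = np.where((left < 0) & (right >= 0))[0] + 1
    return maxima, minima


def _prune_extrema(
    z: np.ndarray,
    maxima: np.ndarray,
    minima: np.ndarray,
    min_prominence: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop small max/min turning-point pairs until all swings are deep.

    Repeatedly removes the adjacent (max, min) pair with the smallest
    vertical swing while that swing is below ``min_prominence``.  The
    surviving extrema alternate and every swing between neighbours is at
    least the threshold.  Deterministic: ties resolve to the earliest pair.
    """
    if min_prominence <= 0:
        return maxima, minima
    idx = sorted(
        [(i, +1) for i in maxima] + [(i, -1) for i in minima]
    )
    changed = True
    while changed and len(idx) > 1:
        changed = False
        swings = [
            abs(z[idx[k + 1][0]] - z[idx[k][0]]) for k in range(len(idx) - 1)
        ]
        k_min = int(np.argmin(swings))
        if swings[k_min] < min_prominence:
            del idx[k_min : k_min + 2]
            changed = True
    maxima = np.array([i for i, s in idx if s == +1], dtype=int)
    minima = np.array([i for i, s in idx if s == -1], dtype=int)
    return maxima, minima


def _lowpass(z: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return z
    b, a = butter(4, cutoff_hz / nyq)
    return filtfilt(b, a, z)


def compute_stride_asymmetries(
    head: DisplacementTrace,
    pelvis: DisplacementTrace,
    strides: list[StrideInterval],
    smooth_cutoff_hz: float | None = None,
    min_prominence: float | str = 0.0,
) -> list[StrideRecord]:
    """Compute per-stride HDmin/HDmax/PDmin/PDmax differences.

    Per stride and per trace the two local minima and two local maxima are
    located on the sampled grid; each parameter is the second (left-step)
    extremum value minus the first (right-step) one.  Strides in which a
    trace does not show exactly two extrema of each kind are flagged, never
    silently dropped.

    Parameters
    ----------
    smooth_cutoff_hz : float, optional
        Zero-phase Butterworth low-pass cutoff applied before the extrema
        scan; ``None`` disables smoothing (appropriate for noiseless data).
    min_prominence : float or "auto"
        Minimum vertical swing (mm) between neighbouring extrema; smaller
        wiggles (sensor noise) are pruned before counting.  ``"auto"`` uses
        a quarter of the per-trace amplitude estimate.

    Raises
    ------
    TraceError
        If either trace does not cover all stride intervals.
    """
    if not strides:
        return []
    t0, t1 = strides[0].start, strides[-1].end
    for trace in (head, pelvis):
        if trace.time[0] > t0 + 1e-9 or trace.time[-1] < t1 - 1e-9:
            raise TraceError(
                f"{trace.location} trace [{trace.time[0]:.3f}, {trace.time[-1]:.3f}] s "
                f"does not cover strides [{t0:.3f}, {t1:.3f}] s"
            )

    prepared = {}
    for trace in (head, pelvis):
        z = trace.z
        if smooth_cutoff_hz is not None:
            z = _lowpass(z, trace.sample_rate, smooth_cutoff_hz)
        if min_prominence == "auto":
            prom = 0.25 * (np.percentile(z, 95) - np.percentile(z, 5)) / 2.0
        else:
            prom = float(min_prominence)
        prepared[trace.location] = (trace.time, z, prom)

    records: list[StrideRecord] = []
    for k, iv in enumerate(strides):
        rec = StrideRecord(index=k, duration=iv.duration)
        reasons = []
        for loc, (mn_attr, mx_attr) in (
            ("head", ("hd_min", "hd_max")),
            ("pelvis", ("pd_min", "pd_max")),
        ):
            t, z, prom = prepared[loc]
            sel = (t >= iv.start - 1e-9) & (t < iv.end - 1e-9)
            zs = z[sel]
            maxima, minima = _local_extrema(zs)
            maxima, minima = _prune_extrema(zs, maxima, minima, prom)
            if len(minima) == 2 and len(maxima) == 2:
                setattr(rec, mn_attr, float(zs[minima[1]] - zs[minima[0]]))
                setattr(rec, mx_attr, float(zs[maxima[1]] - zs[maxima[0]]))
            else:
                reasons.append(
                    f"{loc}: {len(minima)} minima / {len(maxima)} maxima (need 2/2)"
                )
        if reasons:
            rec.flagged = True
            rec.flag_reason = "; ".join(reasons)
        records.append(rec)
    return records


def records_to_frame(records: list[StrideRecord], **meta) -> pd.DataFrame:
    """Tabulate stride records; extra keyword columns (horse_id, ...) prepended."""
    df = pd.DataFrame(
        {
            "stride_index": [r.index for r in records],
            "duration_s": [r.duration for r in records],
            "hd_min_mm": [r.hd_min for r in records],
            "hd_max_mm": [r.hd_max for r in records],
            "pd_min_mm": [r.pd_min for r in records],
            "pd_max_mm": [r.pd_max for r in records],
            "flagged": [r.flagged for r in records],
        }
    )
    for name, value in reversed(meta.items()):
        df.insert(0, name, value)
    return df
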