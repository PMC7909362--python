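"""Fiducial point detection on the vector magnitude of the median beat.

QRS onset/offset are threshold crossings of the origin-referenced vector
magnitude relative to the baseline noise floor; T-wave offset uses the
tangent method (steepest descending tangent after the T peak intersected
with the baseline).  All detections accept explicit manual overrides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vcg_core import MedianBeatXYZ


class FiducialError(ValueError):
    """Raised when a fiducial point cannot be located."""


@dataclass
class FiducialSet:
    """QRS onset/offset and T offset (sample indices into the median beat)."""

    qrs_on: int
    qrs_off: int
    t_off: int
    fs: float
    rr_ms: float = float("nan")
    override: bool = False

    def __post_init__(self) -> None:
        if not self.qrs_on < self.qrs_off < self.t_off:
            raise FiducialError(
                f"fiducials out of order: on={self.qrs_on} off={self.qrs_off} "
                f"t_off={self.t_off}"
            )

    @property
    def qt_ms(self) -> float:
        return (self.t_off - self.qrs_on) / self.fs * 1000.0

    @property
    def qrs_duration_ms(self) -> float:
        return (self.qrs_off - self.qrs_on) / self.fs * 1000.0


def vector_magnitude(mb: MedianBeatXYZ) -> np.ndarray:
    """VM(t) = sqrt(X²+Y²+Z²) of the origin-referenced median beat."""
    return np.linalg.norm(mb.referenced(), axis=0)


def rr_from_annotations(beat_samples: np.ndarray, fs: float) -> float:
    """Median inter-beat distance of R-peak samples, in ms."""
    beat_samples = np.asarray(beat_samples)
    if beat_samples.size < 2:
        return float("nan")
    return float(np.median(np.diff(np.sort(beat_samples))) / fs * 1000.0)


def _first_quiet_run(below: np.ndarray, start: int, step: int, min_run: int) -> int | None:
    """Index adjacent to the first run of >=min_run below-threshold samples
    scanning from ``start`` in direction ``step`` (+1 right, -1 left)."""
    run = 0
    i = start
    while 0 <= i < below.size:
        if below[i]:
            run += 1
            if run >= min_run:
                return i - step * (min_run - 1)
        else:
            run = 0
        i += step
    return None


def detect_fiducials(
    mb: MedianBeatXYZ,
    rr_ms: float = float("nan"),
    qrs_threshold_uv: float = 5.0,
    min_below_ms: float = 8.0,
    t_search_gap_ms: float = 20.0,
    rel_threshold: float = 0.02,
    overrides: dict[str, int] | None = None,
) -> FiducialSet:
    """Detect QRS onset, QRS offset and T offset on the VM signal.

    The threshold is ``max(qrs_threshold_uv, 2 x baseline spread,
    rel_threshold x peak VM)``; the baseline spread is taken over the
    20 ms around the origin point and the relative floor keeps the
    isoelectric ST segment below threshold in the presence of residual
    noise.  QRS bounds are placed where a lightly smoothed VM stays below
    threshold for at least ``min_below_ms``.  T offset is the
    intersection of the steepest descending tangent after the T peak with
    the baseline.  ``overrides`` maps any of {"qrs_on","qrs_off","t_off"}
    to manual sample indices.
    """
    vm = vector_magnitude(mb)
    fs = mb.fs
    origin = mb.origin_index
    w = max(1, int(round(0.010 * fs)))
    base = vm[max(0, origin - w) : origin + w + 1]
    thr = max(qrs_threshold_uv, 2.0 * float(base.max() - base.min()),
              rel_threshold * float(vm.max()))
    min_run = max(1, int(round(min_below_ms / 1000 * fs)))
    smooth = max(1, int(round(0.006 * fs)))
    kernel = np.ones(smooth) / smooth
    below = np.convolve(vm, kernel, mode="same") < thr

    # R peak anchored near the alignment instant; the global VM maximum
    # can belong to a large T wave in paced beats.
    half = int(round(0.120 * fs))
    lo_r = max(0, mb.alignment_point - half)
    hi_r = min(vm.size, mb.alignment_point + half)
    r_peak = lo_r + int(np.argmax(vm[lo_r:hi_r]))
    qrs_on = _first_quiet_run(below, r_peak, -1, min_run)
    if qrs_on is None:
        qrs_on = 0
    qrs_off = _first_quiet_run(below, r_peak, +1, min_run)
    if qrs_off is None:
        raise FiducialError("QRS offset not found before window end")

    # T peak: maximum VM after the QRS offset plus a small guard gap; the
    # search is bounded physiologically (QT below ~600 ms and 90% of RR)
    # so a neighbouring beat at the window edge cannot capture it.
    gap = int(round(t_search_gap_ms / 1000 * fs))
    t_lo = qrs_off + gap
    qt_cap_ms = 600.0 if not np.isfinite(rr_ms) else min(600.0, 0.9 * rr_ms)
    t_hi = min(vm.size, qrs_on + int(round(qt_cap_ms / 1000 * fs)))
    if t_lo >= t_hi - 2:
        raise FiducialError("no room for a T wave after QRS offset")
    t_peak = t_lo + int(np.argmax(vm[t_lo:t_hi]))
    if vm[t_peak] < thr:
        raise FiducialError("T wave not found above noise floor")

    # Tangent method: steepest negative slope on the descending limb,
    # intersected with the baseline; the offset is then carried forward to
    # the actual return of VM below the noise floor when that comes later
    # (the tangent alone clips the shallow terminal tail of the T wave).
    dvm = np.diff(vm)
    desc = dvm[t_peak : vm.size - 1]
    if desc.size == 0 or np.min(desc) >= 0:
        raise FiducialError("no descending limb after the T peak")
    s_idx = t_peak + int(np.argmin(desc))
    slope = dvm[s_idx]
    t_off = s_idx + (-vm[s_idx] / slope)
    ret = _first_quiet_run(below, t_peak, +1, min_run)
    if ret is not None:
        t_off = max(t_off, ret)
    t_off = int(round(min(max(t_off, t_peak + 1), vm.size - 1)))

    if overrides:
        qrs_on = overrides.get("qrs_on", qrs_on)
        qrs_off = overrides.get("qrs_off", qrs_off)
        t_off = overrides.get("t_off", t_off)
    return FiducialSet(
        qrs_on=int(qrs_on),
        qrs_off=int(qrs_off),
        t_off=int(t_off),
        fs=fs,
        rr_ms=rr_ms,
        override=bool(overrides),
    )
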