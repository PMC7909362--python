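"""Kors transformation and time-coherent global XYZ median beat.

Pipeline: 12-lead ECG -> orthogonal XYZ (Kors regression matrix) -> beat
selection (manual labels or template correlation) -> alignment on the
maximum absolute first derivative of the X lead -> sample-wise median
across aligned beats -> electrically quiet origin point on the vector
magnitude signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .ecg_io import LEAD_NAMES, Ecg12Lead

#: Kors regression matrix (rows X, Y, Z; columns I, II, V1..V6), the
#: standard published coefficients for deriving orthogonal leads from the
#: 8 independent leads of the 12-lead ECG.
KORS_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
KORS_MATRIX = np.array(
    [
        [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],   # X (leftward)
        [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],  # Y (inferior)
        [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],  # Z (posterior)
    ]
)


class BeatSelectionError(ValueError):
    """Raised when no analyzable beat remains after exclusion."""


class AlignmentError(ValueError):
    """Raised when beats cannot be aligned (e.g. flat X lead)."""


class OriginError(ValueError):
    """Raised when no pre-QRS segment is available for origin search."""


@dataclass
class EcgXYZ:
    """Orthogonal XYZ ECG, microvolts, shape ``(3, n_samples)``."""

    samples: np.ndarray
    fs: float
    provenance: str = ""

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class MedianBeatXYZ:
    """Time-coherent global XYZ median beat.

    ``beat`` is ``(3, M)`` in microvolts; ``origin_value`` is the XYZ
    sample at the electrically quiet origin point, the reference from
    which every heart vector is measured.
    """

    beat: np.ndarray
    fs: float
    alignment_point: int  # sample index of the alignment (max |dX/dt|) instant
    n_beats_used: int
    alignment_indices: list[int] = field(default_factory=list)
    origin_index: int | None = None
    origin_value: np.ndarray | None = None
    origin_override: bool = False

    @property
    def n_samples(self) -> int:
        return self.beat.shape[1]

    def referenced(self) -> np.ndarray:
        """Beat with the origin value subtracted (requires origin)."""
        if self.origin_value is None:
            raise OriginError("origin point has not been detected yet")
        return self.beat - self.origin_value[:, None]


def kors_transform(ecg: Ecg12Lead) -> EcgXYZ:
    """Transform a 12-lead ECG into the orthogonal XYZ ECG.

    Uses the 8 independent leads (I, II, V1–V6); the operation is linear
    and sample-wise.
    """
    if not np.all(np.isfinite(ecg.samples)):
        raise ValueError("non-finite samples in ECG input")
    rows = [LEAD_NAMES.index(l) for l in KORS_LEADS]
    xyz = KORS_MATRIX @ ecg.samples[rows]
    return EcgXYZ(samples=xyz, fs=ecg.fs, provenance=ecg.patient_id)


def detect_r_peaks(xyz: EcgXYZ, min_rr_s: float = 0.3) -> np.ndarray:
    """Crude R-peak detection on the vector magnitude (for unlabeled input)."""
    vm = np.linalg.norm(xyz.samples - np.median(xyz.samples, axis=1, keepdims=True), axis=0)
    height = 0.5 * np.max(vm)
    peaks, _ = sps.find_peaks(vm, height=height, distance=int(min_rr_s * xyz.fs))
    return peaks


def classify_beats(
    xyz: EcgXYZ,
    annotations: list[tuple[int, str]] | None = None,
    corr_threshold: float = 0.8,
    window_ms: float = 120.0,
) -> np.ndarray:
    """Select beats entering the median beat.

    With annotations, beats labeled ``normal`` are retained (ectopic,
    fusion and artifact beats excluded).  Without annotations, R peaks are
    detected and beats whose X-lead cross-correlation with the dominant
    (median) template falls below ``corr_threshold`` are excluded.

    Returns the retained R-peak sample indices.
    """
    if annotations:
        keep = np.array([i for i, c in annotations if c == "normal"], dtype=int)
        if keep.size == 0:
            raise BeatSelectionError("no normal beat retained after exclusions")
        return keep
    peaks = detect_r_peaks(xyz)
    if peaks.size == 0:
        raise BeatSelectionError("no beat detected and no annotations provided")
    half = int(window_ms / 1000 * xyz.fs)
    x = xyz.samples[0]
    segs = []
    ok_peaks = []
    for p in peaks:
        if p - half < 0 or p + half >= xyz.n_samples:
            continue
        segs.append(x[p - half : p + half])
        ok_peaks.append(p)
    if not segs:
        raise BeatSelectionError("no complete beat window inside the record")
    segs = np.array(segs)
    template = np.median(segs, axis=0)
    tc = template - template.mean()
    keep = []
    for p, s in zip(ok_peaks, segs):
        sc = s - s.mean()
        denom = np.linalg.norm(sc) * np.linalg.norm(tc)
        r = float(sc @ tc / denom) if denom > 0 else 0.0
        if r >= corr_threshold:
            keep.append(p)
    if not keep:
        raise BeatSelectionError("all beats rejected by template correlation")
    return np.array(keep, dtype=int)


def align_beats(
    xyz: EcgXYZ, beats: np.ndarray, search_ms: float = 80.0
) -> np.ndarray:
    """Alignment instants: sample of maximum |dV/dt| of the X lead per beat.

    Only the X lead is used; the search is limited to ±``search_ms``
    around each retained R-peak index.  Ties break to the earliest sample.
    """
    beats = np.asarray(beats, dtype=int)
    if beats.size == 0:
        raise AlignmentError("no beats to align")
    x = xyz.samples[0]
    dx = np.abs(np.diff(x))
    half = int(search_ms / 1000 * xyz.fs)
    out = []
    for p in beats:
        lo = max(0, p - half)
        hi = min(dx.size, p + half)
        win = dx[lo:hi]
        if win.size == 0 or np.max(win) == 0:
            raise AlignmentError(f"flat X lead around beat at sample {p}")
        out.append(lo + int(np.argmax(win)))  # argmax returns earliest max
    return np.array(out, dtype=int)


def build_median_beat(
    xyz: EcgXYZ,
    offsets: np.ndarray,
    pre_ms: float = 280.0,
    post_ms: float = 520.0,
) -> MedianBeatXYZ:
    """Sample-wise median across aligned beats.

    The Y and Z leads use the X-derived alignment (time-coherent global
    median beat).  The window spans ``pre_ms`` before to ``post_ms`` after
    the alignment instant (the default 800 ms covers the full PQRST of a
    paced beat, whose QT runs near 500 ms); beats whose window exceeds the record are
    dropped, and if none remains an error is raised.
    """
    offsets = np.asarray(offsets, dtype=int)
    if offsets.size >= 2:
        # keep the window inside one cycle so neighbours don't leak in
        rr_est = float(np.median(np.diff(np.sort(offsets))))
        pre_ms = min(pre_ms, 0.35 * rr_est / xyz.fs * 1000)
        post_ms = min(post_ms, 0.80 * rr_est / xyz.fs * 1000)
    pre = int(round(pre_ms / 1000 * xyz.fs))
    post = int(round(post_ms / 1000 * xyz.fs))
    used = []
    stacks = []
    for o in offsets:
        if o - pre < 0 or o + post > xyz.n_samples:
            continue
        stacks.append(xyz.samples[:, o - pre : o + post])
        used.append(int(o))
    if not stacks:
        raise AlignmentError("no beat window fits inside the record bounds")
    beat = np.median(np.stack(stacks, axis=0), axis=0)
    return MedianBeatXYZ(
        beat=beat,
        fs=xyz.fs,
        alignment_point=pre,
        n_beats_used=len(used),
        alignment_indices=used,
    )


def detect_origin(
    mb: MedianBeatXYZ,
    window_ms: float = 20.0,
    search_ms: float = 150.0,
    override_index: int | None = None,
) -> MedianBeatXYZ:
    """Locate the electrically quiet origin point of the heart vector.

    A sliding window (width ``window_ms``) runs over the ``search_ms``
    preceding the R peak of the vector magnitude signal; flatness score is
    mean |ΔVM| + 0.5·(max−min) over the window, minimized.  The origin
    value is the XYZ sample at the winning window's center, and all heart
    vectors are subsequently referenced to it.

    ``override_index`` records a manual correction; it bypasses the search
    and is flagged in the output.
    """
    if override_index is not None:
        if not 0 <= override_index < mb.n_samples:
            raise OriginError(f"override index {override_index} out of range")
        mb.origin_index = int(override_index)
        mb.origin_value = mb.beat[:, override_index].copy()
        mb.origin_override = True
        return mb
    vm = np.linalg.norm(mb.beat, axis=0)
    # R peak near the alignment instant (the global VM maximum can be a
    # large T wave, particularly in paced beats)
    half = int(round(0.120 * mb.fs))
    lo_r = max(0, mb.alignment_point - half)
    hi_r = min(vm.size, mb.alignment_point + half)
    r_peak = lo_r + int(np.argmax(vm[lo_r:hi_r]))
    w = max(2, int(round(window_ms / 1000 * mb.fs)))
    search = int(round(search_ms / 1000 * mb.fs))
    lo = max(0, r_peak - search)
    hi = r_peak - w
    if hi <= lo:
        raise OriginError("median beat has no pre-QRS segment for origin search")
    best, best_score = None, np.inf
    dvm = np.abs(np.diff(vm))
    floor = float(np.min(vm[lo : hi + w]))
    for s in range(lo, hi):
        seg = vm[s : s + w]
        # flatness plus elevation above the quietest level in the search
        # region: the P-wave top is flat but not electrically quiet
        score = float(
            np.mean(dvm[s : s + w - 1])
            + 0.5 * (seg.max() - seg.min())
            + 0.3 * (float(seg.mean()) - floor)
        )
        if score < best_score:
            best_score, best = score, s
    idx = best + w // 2
    mb.origin_index = idx
    mb.origin_value = mb.beat[:, idx].copy()
    mb.origin_override = False
    return mb
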