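"""Global electrical heterogeneity metrics and cardiac-memory angles.

Spatial peak and area QRS, T and spatial ventricular gradient (SVG)
vectors with direction (azimuth, elevation) and magnitude; scalar SVG
measures SAI QRST and iVMQT; spatial QRS–T angle; and the set of
cardiac-memory and comparison angles between the four recordings
(AAI-1, DDD-1, AAI-7, DDD-7) of one patient.

Axis convention: X leftward, Y inferior, Z posterior.  Azimuth is the
angle of the (X, Z) projection in the transverse plane, 0° at +X and
positive toward +Z, range (−180°, 180°]; elevation is the angle from the
+Y axis, range [0°, 180°].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiducials import FiducialSet, vector_magnitude
from .vcg_core import MedianBeatXYZ


class ZeroVectorError(ValueError):
    """Direction requested for a zero-magnitude heart vector."""


@dataclass(frozen=True)
class HeartVector:
    """A 3-D heart vector in mV (peak basis) or mV·ms (area basis)."""

    x: float
    y: float
    z: float
    basis: str = "peak"      # {"peak", "area"}
    interval: str = "QRS"    # {"QRS", "T", "QRST"}
    flip_z: bool = False     # anterior-positive dialect switch

    @property
    def magnitude(self) -> float:
        return float(np.sqrt(self.x**2 + self.y**2 + self.z**2))

    def _z(self) -> float:
        return -self.z if self.flip_z else self.z

    @property
    def azimuth(self) -> float:
        """Transverse-plane angle, degrees in (−180, 180]; 0 with a
        degenerate-flag of 0 magnitude is signaled by :attr:`degenerate`."""
        if self.magnitude == 0 or (self.x == 0 and self.z == 0):
            return 0.0
        az = float(np.degrees(np.arctan2(self._z(), self.x)))
        return 180.0 if az == -180.0 else az

    @property
    def elevation(self) -> float:
        """Angle from the +Y (inferior) axis, degrees in [0, 180]."""
        if self.magnitude == 0:
            return 0.0
        return float(np.degrees(np.arccos(np.clip(self.y / self.magnitude, -1, 1))))

    @property
    def degenerate(self) -> bool:
        """True when magnitude is zero (direction undefined, sentinel 0)."""
        return self.magnitude == 0 or (self.x == 0 and self.z == 0)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _window(fid: FiducialSet, interval: str) -> tuple[int, int]:
    if interval == "QRS":
        return fid.qrs_on, fid.qrs_off
    if interval == "T":
        return fid.qrs_off, fid.t_off  # J point = QRS offset
    if interval == "QRST":
        return fid.qrs_on, fid.t_off
    raise ValueError(f"unknown interval {interval!r}")


def peak_vector(mb: MedianBeatXYZ, fid: FiducialSet, interval: str) -> HeartVector:
    """Heart vector at the sample of maximal VM within the interval, mV."""
    lo, hi = _window(fid, interval)
    if hi <= lo:
        raise ValueError(f"empty {interval} window [{lo}, {hi})")
    vm = vector_magnitude(mb)[lo:hi]
    i = lo + int(np.argmax(vm))
    x, y, z = mb.referenced()[:, i] / 1000.0
    return HeartVector(float(x), float(y), float(z), basis="peak", interval=interval)


def area_vector(mb: MedianBeatXYZ, fid: FiducialSet, interval: str) -> HeartVector:
    """Per-axis trapezoidal integral over the interval, mV·ms."""
    lo, hi = _window(fid, interval)
    if hi <= lo:
        raise ValueError(f"inverted {interval} window [{lo}, {hi})")
    seg = mb.referenced()[:, lo : hi + 1]
    # µV integrated over samples -> mV·ms: (1/1000 mV/µV) * (1000/fs ms/sample)
    vals = np.trapezoid(seg, dx=1.0, axis=1) / mb.fs
    return HeartVector(*map(float, vals), basis="area", interval=interval)


def svg_vectors(mb: MedianBeatXYZ, fid: FiducialSet) -> tuple[HeartVector, HeartVector]:
    """Spatial ventricular gradient: (peak SVG, area SVG).

    Area SVG is Wilson's gradient, the QRST-interval area vector; peak
    SVG is the heart vector at maximal VM over the full QRST interval.
    """
    peak = peak_vector(mb, fid, "QRST")
    area = area_vector(mb, fid, "QRST")
    return peak, area


def sai_qrst(mb: MedianBeatXYZ, fid: FiducialSet) -> float:
    """Sum of absolute QRST integrals: ∫|X| + ∫|Y| + ∫|Z|, mV·ms."""
    lo, hi = _window(fid, "QRST")
    seg = np.abs(mb.referenced()[:, lo : hi + 1])
    return float(np.sum(np.trapezoid(seg, dx=1.0, axis=1)) / mb.fs)


def ivmqt(mb: MedianBeatXYZ, fid: FiducialSet) -> float:
    """QT integral of the vector magnitude signal, mV·ms (≤ SAI QRST)."""
    lo, hi = _window(fid, "QRST")
    vm = vector_magnitude(mb)[lo : hi + 1]
    return float(np.trapezoid(vm, dx=1.0) / mb.fs)


def spatial_angle(v1: HeartVector | np.ndarray, v2: HeartVector | np.ndarray) -> float:
    """Angle between two heart vectors in degrees, range [0, 180]."""
    a = v1.as_array() if isinstance(v1, HeartVector) else np.asarray(v1, float)
    b = v2.as_array() if isinstance(v2, HeartVector) else np.asarray(v2, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroVectorError("spatial angle undefined for a zero vector")
    return float(np.degrees(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0))))


@dataclass
class GehRecord:
    """Full metric set for one recording (one row of the study's metric table)."""

    patient_id: str
    mode_label: str  # AAI-1 / DDD-1 / AAI-7 / DDD-7
    rr_ms: float
    qt_ms: float
    qrs_duration_ms: float
    qrs_peak: HeartVector
    qrs_area: HeartVector
    t_peak: HeartVector
    t_area: HeartVector
    svg_peak: HeartVector
    svg_area: HeartVector
    sai_qrst: float
    ivmqt: float
    qrst_angle_peak: float
    qrst_angle_area: float
    overrides: dict = field(default_factory=dict)

    @property
    def mode(self) -> str:
        return self.mode_label.split("-")[0]

    @property
    def day(self) -> int:
        return int(self.mode_label.split("-")[1])

    def to_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "mode_label": self.mode_label,
            "mode": self.mode,
            "day": self.day,
            "rr_ms": self.rr_ms,
            "qt_ms": self.qt_ms,
            "qrs_duration_ms": self.qrs_duration_ms,
            "sai_qrst": self.sai_qrst,
            "ivmqt": self.ivmqt,
            "qrst_angle_peak": self.qrst_angle_peak,
            "qrst_angle_area": self.qrst_angle_area,
        }
        for name, v in (
            ("qrs_peak", self.qrs_peak), ("qrs_area", self.qrs_area),
            ("t_peak", self.t_peak), ("t_area", self.t_area),
            ("svg_peak", self.svg_peak), ("svg_area", self.svg_area),
        ):
            row[f"{name}_x"] = v.x
            row[f"{name}_y"] = v.y
            row[f"{name}_z"] = v.z
            row[f"{name}_mag"] = v.magnitude
            row[f"{name}_azimuth"] = v.azimuth
            row[f"{name}_elevation"] = v.elevation
        return row


def compute_geh(
    mb: MedianBeatXYZ,
    fid: FiducialSet,
    patient_id: str = "",
    mode_label: str = "",
) -> GehRecord:
    """Assemble the complete metric set for one median beat."""
    qrs_p = peak_vector(mb, fid, "QRS")
    qrs_a = area_vector(mb, fid, "QRS")
    t_p = peak_vector(mb, fid, "T")
    t_a = area_vector(mb, fid, "T")
    svg_p, svg_a = svg_vectors(mb, fid)
    return GehRecord(
        patient_id=patient_id,
        mode_label=mode_label,
        rr_ms=fid.rr_ms,
        qt_ms=fid.qt_ms,
        qrs_duration_ms=fid.qrs_duration_ms,
        qrs_peak=qrs_p,
        qrs_area=qrs_a,
        t_peak=t_p,
        t_area=t_a,
        svg_peak=svg_p,
        svg_area=svg_a,
        sai_qrst=sai_qrst(mb, fid),
        ivmqt=ivmqt(mb, fid),
        qrst_angle_peak=spatial_angle(qrs_p, t_p),
        qrst_angle_area=spatial_angle(qrs_a, t_a),
    )


#: The nine named angles of the cardiac-memory analysis.
CM_ANGLE_NAMES = (
    "cm_angle",          # QRS_DDD-7 vs T_AAI-7 (the memory angle)
    "t_aai1_aai7", "t_ddd1_ddd7", "t_aai1_ddd1", "t_aai7_ddd7",
    "qrs_aai7_ddd7", "qrs_aai1_ddd1", "qrs_aai1_aai7", "qrs_ddd1_ddd7",
)


def cm_angles(records: dict[str, GehRecord], basis: str = "peak") -> dict[str, float]:
    """Cardiac-memory and comparison angles for one patient.

    ``records`` maps mode labels to :class:`GehRecord`; ``basis`` selects
    peak or area vectors (both bases carry a memory signal; peak vectors
    are the default headline).  Missing recordings yield NaN for the
    angles that need them.
    """
    if basis not in ("peak", "area"):
        raise ValueError(f"basis must be 'peak' or 'area', got {basis!r}")

    def vec(label: str, which: str) -> HeartVector | None:
        rec = records.get(label)
        if rec is None:
            return None
        return getattr(rec, f"{which}_{basis}")

    pairs = {
        "cm_angle": (vec("DDD-7", "qrs"), vec("AAI-7", "t")),
        "t_aai1_aai7": (vec("AAI-1", "t"), vec("AAI-7", "t")),
        "t_ddd1_ddd7": (vec("DDD-1", "t"), vec("DDD-7", "t")),
        "t_aai1_ddd1": (vec("AAI-1", "t"), vec("DDD-1", "t")),
        "t_aai7_ddd7": (vec("AAI-7", "t"), vec("DDD-7", "t")),
        "qrs_aai7_ddd7": (vec("AAI-7", "qrs"), vec("DDD-7", "qrs")),
        "qrs_aai1_ddd1": (vec("AAI-1", "qrs"), vec("DDD-1", "qrs")),
        "qrs_aai1_aai7": (vec("AAI-1", "qrs"), vec("AAI-7", "qrs")),
        "qrs_ddd1_ddd7": (vec("DDD-1", "qrs"), vec("DDD-7", "qrs")),
    }
    out: dict[str, float] = {}
    for name, (a, b) in pairs.items():
        out[name] = float("nan") if a is None or b is None else spatial_angle(a, b)
    return out
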