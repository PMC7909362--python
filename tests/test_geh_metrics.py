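"""Spatial vectors, scalar SVG measures, and cardiac-memory angles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vcgmem.fiducials import FiducialSet
from vcgmem.geh_metrics import (
    HeartVector, ZeroVectorError, area_vector, cm_angles, compute_geh,
    ivmqt, peak_vector, sai_qrst, spatial_angle, svg_vectors,
)
from vcgmem.vcg_core import MedianBeatXYZ

FS = 500.0


def _mb(beat):
    mb = MedianBeatXYZ(beat=np.asarray(beat, float), fs=FS,
                       alignment_point=0, n_beats_used=1)
    mb.origin_index = 0
    mb.origin_value = np.zeros(3)
    return mb


def _fid(qrs_on, qrs_off, t_off):
    return FiducialSet(qrs_on=qrs_on, qrs_off=qrs_off, t_off=t_off, fs=FS)


def test_rectangular_pulse_closed_forms():
    # 1 mV on X during the whole QRS window of 100 ms (50 samples at 500 Hz)
    beat = np.zeros((3, 300))
    beat[0, 50:101] = 1000.0
    mb, fid = _mb(beat), _fid(50, 100, 250)
    pv = peak_vector(mb, fid, "QRS")
    assert (pv.x, pv.y, pv.z) == (1.0, 0.0, 0.0)
    av = area_vector(mb, fid, "QRS")
    assert av.x == pytest.approx(100.0)  # 1 mV * 100 ms
    assert av.y == av.z == 0.0
    # zero T window (signal support strictly inside the QRS interval)
    beat2 = np.zeros((3, 300))
    beat2[0, 60:95] = 1000.0
    mb2 = _mb(beat2)
    tv = area_vector(mb2, fid, "T")
    assert tv.magnitude == 0.0
    assert peak_vector(mb2, fid, "T").degenerate


def test_sine_half_wave_area_analytic():
    # A * sin(pi t / d) integrates to 2 A d / pi
    A_uv, d_ms = 800.0, 200.0
    n = int(d_ms / 1000 * FS) + 1
    t = np.arange(n) / FS * 1000
    beat = np.zeros((3, 400))
    beat[0, 100 : 100 + n] = A_uv * np.sin(np.pi * t / d_ms)
    av = area_vector(_mb(beat), _fid(100, 100 + n - 1, 399), "QRS")
    expect = 2 * (A_uv / 1000) * d_ms / np.pi
    assert av.x == pytest.approx(expect, rel=1e-3)


def test_peak_vector_equals_argmax_scan(rng):
    beat = rng.normal(0, 300, (3, 400))
    mb, fid = _mb(beat), _fid(60, 140, 350)
    pv = peak_vector(mb, fid, "QRS")
    vm = np.linalg.norm(beat, axis=0)
    i = 60 + int(np.argmax(vm[60:140]))
    np.testing.assert_allclose(pv.as_array() * 1000, beat[:, i])


def test_area_vectors_additive_over_adjacent_intervals(rng):
    beat = rng.normal(0, 300, (3, 400))
    mb, fid = _mb(beat), _fid(60, 140, 350)
    qrs = area_vector(mb, fid, "QRS").as_array()
    jt = area_vector(mb, fid, "T").as_array()
    qrst = area_vector(mb, fid, "QRST").as_array()
    np.testing.assert_allclose(qrs + jt, qrst, rtol=1e-12)


def test_svg_area_is_wilsons_gradient(rng):
    beat = rng.normal(0, 300, (3, 400))
    mb, fid = _mb(beat), _fid(60, 140, 350)
    _, svg_a = svg_vectors(mb, fid)
    np.testing.assert_allclose(
        svg_a.as_array(), area_vector(mb, fid, "QRST").as_array())


def test_sai_qrst_rectification_and_single_axis_identity():
    beat = np.zeros((3, 400))
    beat[0, 50:201] = 1000.0
    beat[0, 201:351] = -1000.0  # sign flip leaves SAI unchanged
    mb, fid = _mb(beat), _fid(50, 150, 350)
    assert sai_qrst(mb, fid) == pytest.approx(ivmqt(mb, fid))
    flipped = beat.copy()
    flipped[0] = np.abs(flipped[0])
    assert sai_qrst(_mb(flipped), fid) == pytest.approx(sai_qrst(mb, fid))


def test_ivmqt_never_exceeds_sai_qrst(rng):
    for _ in range(10):
        beat = rng.normal(0, 300, (3, 400))
        mb, fid = _mb(beat), _fid(60, 140, 350)
        assert ivmqt(mb, fid) <= sai_qrst(mb, fid) + 1e-12


@pytest.mark.parametrize("vec,az,el", [
    ((1, 0, 0), 0.0, 90.0),     # leftward: convention anchor
    ((1, 0, 1), 45.0, 90.0),    # toward posterior
    ((0, 1, 0), 0.0, 0.0),      # inferior axis: azimuth undefined -> 0
    ((0, -1, 0), 0.0, 180.0),
])
def test_azimuth_elevation_conventions(vec, az, el):
    v = HeartVector(*map(float, vec))
    assert v.azimuth == pytest.approx(az)
    assert v.elevation == pytest.approx(el)


def test_degenerate_vectors_flagged_not_silent():
    assert HeartVector(0.0, 1.0, 0.0).degenerate  # azimuth undefined
    assert HeartVector(0.0, 0.0, 0.0).degenerate
    assert not HeartVector(1.0, 1.0, 0.0).degenerate


def test_flip_z_switches_azimuth_sign():
    assert HeartVector(1.0, 0.0, 1.0, flip_z=True).azimuth == pytest.approx(-45.0)


@pytest.mark.parametrize("a,b,expect", [
    ((1, 0, 0), (1, 0, 0), 0.0),
    ((1, 0, 0), (0, 1, 0), 90.0),
    ((1, 1, 0), (1, 0, 0), 45.0),
    ((1, 0, 0), (-1, 0, 0), 180.0),
])
def test_spatial_angle_examples(a, b, expect):
    assert spatial_angle(np.array(a, float), np.array(b, float)) == pytest.approx(expect)


@given(st.integers(0, 1000), st.floats(0.1, 50.0), st.floats(0.1, 50.0))
@settings(max_examples=30, deadline=None)
def test_spatial_angle_symmetric_and_scale_invariant(seed, s1, s2):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=3), rng.normal(size=3)
    ang = spatial_angle(a, b)
    assert 0.0 <= ang <= 180.0
    assert spatial_angle(b, a) == pytest.approx(ang)
    assert spatial_angle(s1 * a, s2 * b) == pytest.approx(ang, abs=1e-9)


def test_spatial_angle_zero_vector_raises():
    with pytest.raises(ZeroVectorError):
        spatial_angle(np.zeros(3), np.ones(3))


# ---------------------------------------------------------------------------
# Cardiac-memory angle set
# ---------------------------------------------------------------------------

def _geh_with(qrs, t):
    beat = np.zeros((3, 400))
    beat[:, 80:130] = np.outer(np.asarray(qrs, float) * 1000, np.hanning(50))
    beat[:, 200:300] = np.outer(np.asarray(t, float) * 1000, np.hanning(100))
    return compute_geh(_mb(beat), _fid(78, 132, 302))


def test_identical_recordings_collapse_comparison_angles():
    rec = _geh_with([1, 0.2, -0.3], [0.3, 0.1, 0.2])
    recs = {m: rec for m in ("AAI-1", "DDD-1", "AAI-7", "DDD-7")}
    angles = cm_angles(recs)
    for name, v in angles.items():
        if name == "cm_angle":  # QRS vs T of the same beat: the QRS-T angle
            assert v == pytest.approx(rec.qrst_angle_peak)
        else:
            assert v == pytest.approx(0.0, abs=1e-9)


def test_perfect_memory_gives_zero_cm_angle():
    """T of the day-7 sensed beat aligned with the day-7 paced QRS."""
    direction = np.array([0.5, -0.4, 0.8])
    recs = {
        "AAI-1": _geh_with([1, 0, 0], [0, 1, 0]),
        "DDD-1": _geh_with(direction, [0, 1, 0]),
        "DDD-7": _geh_with(direction, [0, 1, 0]),
        "AAI-7": _geh_with([1, 0, 0], direction * 0.3),
    }
    angles = cm_angles(recs, basis="peak")
    assert angles["cm_angle"] == pytest.approx(0.0, abs=1.0)


def test_missing_recording_flags_nan():
    rec = _geh_with([1, 0, 0], [0, 1, 0])
    angles = cm_angles({"AAI-1": rec, "AAI-7": rec})
    assert np.isnan(angles["cm_angle"])
    assert angles["qrs_aai1_aai7"] == pytest.approx(0.0, abs=1e-9)


def test_cm_angles_match_generated_rotations(clean_cohort):
    """Noise-free cohort: the pipeline-measured day-1 to day-7 sensed-T
    angle reproduces each patient's generated memory rotation within 2°."""
    from vcgmem.pipeline import process_cohort
    recs = {p.patient_id: p.recordings for p in clean_cohort.patients}
    _, angles = process_cohort(recs)
    truth = {p.patient_id: p.truth_scalars["cm_rotation_applied_deg"]
             for p in clean_cohort.patients}
    meas = angles.set_index("patient_id")["t_aai1_aai7_peak"]
    for pid, gamma in truth.items():
        assert meas[pid] == pytest.approx(gamma, abs=2.0)
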