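"""LUT construction, correction identities, and baselines."""

import numpy as np
import pytest

from fluolut.lut import (
    CorrectionLUT,
    TrainingSet,
    build_lut,
    correct,
    estimate_concentration,
    fr_correct,
)
from fluolut.reflectometry import ReflectometryTriplet


def _trip(rt, slope, f):
    return ReflectometryTriplet(R_T=rt, slope_log_srr=slope, F=f)


@pytest.fixture
def scattered_train(rng):
    """12 scattered training records with a smooth cvF surface."""
    records = []
    for _ in range(12):
        rt = rng.uniform(0.2, 0.9)
        slope = rng.uniform(-2.0, -0.4)
        f = 10 ** (-(1.0 + 0.8 * rt + 0.5 * slope))  # smooth in inputs
        records.append(_trip(rt, slope, f))
    return TrainingSet(records, c_cal=87.0)


@pytest.mark.parametrize("method", ["linear", "tps"])
def test_node_exactness(scattered_train, method):
    """Correcting a training phantom's own triplet gives exactly 1."""
    lut = build_lut(scattered_train, method)
    for rec in scattered_train.records:
        res = correct(rec.F, rec.R_T, rec.slope_log_srr, lut)
        assert res.F_corrected == pytest.approx(1.0, abs=1e-10)
        assert not res.extrapolated


@pytest.mark.parametrize("method", ["linear", "tps"])
def test_unit_training_f_means_identity(method):
    records = [
        _trip(0.2, -1.0, 1.0),
        _trip(0.8, -1.0, 1.0),
        _trip(0.5, -0.3, 1.0),
        _trip(0.5, -1.6, 1.0),
    ]
    lut = build_lut(TrainingSet(records, c_cal=87.0), method)
    res = correct(0.37, 0.5, -1.0, lut)
    assert res.F_corrected == pytest.approx(0.37, rel=1e-8)


def test_tps_center_matches_dense_solve():
    """4-node toy TPS vs an independently assembled 7x7 linear system."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    vals = np.array([0.0, 1.0, 1.0, 2.0])

    def phi(r):
        out = np.zeros_like(r)
        pos = r > 0
        out[pos] = r[pos] ** 2 * np.log(r[pos])
        return out

    # dense system: [[K  P],[P^T 0]] [w; a] = [vals; 0]
    K = phi(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
    P = np.column_stack([np.ones(4), pts])
    A = np.zeros((7, 7))
    A[:4, :4] = K
    A[:4, 4:] = P
    A[4:, :4] = P.T
    rhs = np.concatenate([vals, np.zeros(3)])
    sol = np.linalg.solve(A, rhs)
    q = np.array([0.5, 0.5])
    oracle = float(
        sol[:4] @ phi(np.linalg.norm(pts - q, axis=1))
        + sol[4] + sol[5:] @ q
    )

    records = [_trip(x, y, 10.0 ** (-v)) for (x, y), v in zip(pts, vals)]
    lut = build_lut(TrainingSet(records, c_cal=1.0), "tps")
    got, _ = lut.evaluate(0.5, 0.5)
    assert got == pytest.approx(oracle, abs=1e-8)


def test_affine_surface_tps_equals_linear(scattered_train, rng):
    """If cvF is globally affine, both interpolants agree at interior
    queries."""
    records = [
        _trip(rt, s, 10 ** (-(0.3 + 0.5 * rt - 0.2 * s)))
        for rt, s in zip(rng.uniform(0.2, 0.9, 10), rng.uniform(-2, -0.4, 10))
    ]
    ts = TrainingSet(records, c_cal=87.0)
    lin = build_lut(ts, "linear")
    tps = build_lut(ts, "tps")
    hull_mid = np.mean([[r.R_T, r.slope_log_srr] for r in records], axis=0)
    v_lin, _ = lin.evaluate(*hull_mid)
    v_tps, _ = tps.evaluate(*hull_mid)
    assert v_lin == pytest.approx(v_tps, abs=1e-8)


def test_gain_invariance(scattered_train):
    """Multiplying every training F and the query F by one constant
    leaves the corrected value unchanged."""
    k = 3.7
    lut = build_lut(scattered_train, "tps")
    scaled = TrainingSet(
        [
            _trip(r.R_T, r.slope_log_srr, k * r.F)
            for r in scattered_train.records
        ],
        c_cal=87.0,
    )
    lut_k = build_lut(scaled, "tps")
    res = correct(0.01, 0.55, -1.1, lut)
    res_k = correct(k * 0.01, 0.55, -1.1, lut_k)
    assert res_k.F_corrected == pytest.approx(res.F_corrected, rel=1e-10)


def test_reference_rescale_invariance(scattered_train):
    """Rescaling all R_T (train and query) by one constant and refitting
    leaves the TPS output essentially unchanged (inputs are
    standardized)."""
    k = 2.5
    lut = build_lut(scattered_train, "tps")
    scaled = TrainingSet(
        [
            _trip(k * r.R_T, r.slope_log_srr, r.F)
            for r in scattered_train.records
        ],
        c_cal=87.0,
    )
    lut_k = build_lut(scaled, "tps")
    res = correct(0.01, 0.55, -1.1, lut)
    res_k = correct(0.01, k * 0.55, -1.1, lut_k)
    assert res_k.F_corrected == pytest.approx(res.F_corrected, rel=1e-6)


def test_constant_cvf_closed_form():
    records = [
        _trip(0.2, -1.0, 0.5),
        _trip(0.8, -1.0, 0.5),
        _trip(0.5, -0.3, 0.5),
    ]
    lut = build_lut(TrainingSet(records, c_cal=87.0), "tps")
    res = correct(0.5, 0.5, -0.8, lut)
    assert res.F_corrected == pytest.approx(1.0, rel=1e-8)


def test_zero_fluorescence_maps_to_zero():
    records = [_trip(0.2, -1.0, 0.5), _trip(0.8, -1.0, 0.4),
               _trip(0.5, -0.3, 0.6)]
    lut = build_lut(TrainingSet(records, c_cal=87.0), "tps")
    res = correct(0.0, 0.5, -0.8, lut)
    assert res.F_corrected == 0.0
    assert res.c_estimate == 0.0


def test_extrapolation_flagged(scattered_train):
    lut = build_lut(scattered_train, "tps")
    res = correct(0.01, 5.0, -1.0, lut)  # far outside in R_T
    assert res.extrapolated


def test_linear_extrapolation_is_bounded(scattered_train):
    """Outside the hull the linear method continues the boundary value,
    so far queries stay within the training cvF range."""
    lut = build_lut(scattered_train, "linear")
    lo, hi = lut.cvf.min(), lut.cvf.max()
    for q in [(5.0, -1.0), (-3.0, -1.0), (0.5, 4.0), (0.5, -9.0)]:
        v, extrapolated = lut.evaluate(*q)
        assert extrapolated
        assert lo - 1e-9 <= v <= hi + 1e-9


def test_concentration_estimation():
    records = [_trip(0.2, -1.0, 0.5), _trip(0.8, -1.0, 0.4),
               _trip(0.5, -0.3, 0.6)]
    lut = build_lut(TrainingSet(records, c_cal=87.0), "tps")
    res = correct(records[0].F, 0.2, -1.0, lut)
    assert res.c_estimate == pytest.approx(87.0, rel=1e-9)
    assert estimate_concentration(res, 87.0) == pytest.approx(87.0, rel=1e-9)
    res2 = type(res)(F_corrected=2.0, c_estimate=0.0, extrapolated=False)
    assert estimate_concentration(res2, 87.0) == pytest.approx(174.0)


def test_fr_baseline():
    assert fr_correct(0.5, 0.5) == pytest.approx(1.0)
    assert fr_correct(0.0, 0.5) == 0.0
    with pytest.raises(ValueError):
        fr_correct(0.5, 0.0)


def test_training_set_validation():
    with pytest.raises(ValueError):
        TrainingSet([_trip(0.5, -1.0, 0.0)], c_cal=87.0)
    with pytest.raises(ValueError):
        TrainingSet([_trip(0.5, -1.0, 0.5)], c_cal=-1.0)
    collinear = [_trip(x, -1.0, 0.5) for x in (0.2, 0.5, 0.8)]
    with pytest.raises(ValueError):
        build_lut(TrainingSet(collinear, c_cal=87.0), "linear")


def test_json_round_trip(tmp_path, scattered_train):
    lut = build_lut(scattered_train, "tps")
    path = tmp_path / "lut.json"
    lut.to_json(path)
    back = CorrectionLUT.from_json(path)
    for q in [(0.5, -1.0), (0.3, -1.5), (0.85, -0.5)]:
        assert back.evaluate(*q)[0] == pytest.approx(
            lut.evaluate(*q)[0], rel=1e-12
        )
    assert back.c_cal == 87.0
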