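"""ASL kinetic models: forward behaviour, closed-form inverses, MAP fit."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import least_squares

from cvrkit.asl import (
    AslProtocol,
    FitPriors,
    calibrate_m0,
    fit_multi_pld,
    gkm_delta_m,
    multi_pld_protocol,
    quantify_single_pld,
    quantify_vsasl,
    single_pld_protocol,
    vsasl_delta_m,
    vsasl_protocol,
)
from cvrkit.core import ImageVolume, ValidationError


def _vol(values, mask=None):
    values = np.asarray(values, dtype=float)
    return ImageVolume(values=values, voxel_size=(4.0, 4.0, 4.0), brain_mask=mask)


# ------------------------------------------------------------- forward model
def test_gkm_zero_before_arrival():
    p = single_pld_protocol()
    # ATT beyond the measurement time tau + PLD = 3.475 s
    assert gkm_delta_m(60.0, 4.0, p, 1.0)[0] == 0.0


def test_gkm_zero_without_labeling():
    p = single_pld_protocol(labeling_efficiency=1e-12)
    dm = gkm_delta_m(60.0, 1.2, p, 1.0)
    assert dm[0] == pytest.approx(0.0, abs=1e-12)


def test_gkm_linear_in_cbf_with_ode_oracle_slope():
    """dM is exactly linear in CBF; the slope matches direct quadrature of
    the delivery-decay integral dM(t) = 2 M0b a f int c(s) e^{-(t-s)/T1app} ds."""
    p = multi_pld_protocol(labeling_efficiency=0.85, t1_blood=1.65)
    att, tau = 1.2, p.tau_s
    for cbf in (20.0, 60.0):
        dm = gkm_delta_m(cbf, att, p, 1.0)
        assert np.allclose(dm, (cbf / 30.0) * gkm_delta_m(30.0, att, p, 1.0))
    f = 1.0 / 6000.0  # unit CBF
    for i, pld in enumerate(p.plds_s):
        t = tau + pld

        def integrand(s):
            if s < att or s > min(att + tau, t):
                return 0.0
            return np.exp(-att / p.t1_blood) * np.exp(-(t - s) / p.t1_tissue)

        oracle, _ = quad(integrand, 0.0, t, limit=200)
        oracle *= 2.0 * 0.85 * f
        got = gkm_delta_m(1.0, att, p, 1.0)[i]
        assert got == pytest.approx(oracle, rel=1e-3)


def test_gkm_continuous_at_piecewise_boundaries():
    p = multi_pld_protocol()
    tau = p.tau_s
    eps = 1e-9
    for pld_ms in (300.0, 2000.0):
        t = tau + pld_ms * 1e-3
        # boundary t = att: arrival exactly at measurement
        lo = gkm_delta_m(60.0, t + eps, p, 1.0)
        hi = gkm_delta_m(60.0, t - eps, p, 1.0)
        assert np.allclose(lo, hi, atol=1e-6)
        # boundary t = att + tau: bolus end exactly at measurement
        att = t - tau
        if att > 0:
            lo = gkm_delta_m(60.0, att + eps, p, 1.0)
            hi = gkm_delta_m(60.0, att - eps, p, 1.0)
            assert np.allclose(lo, hi, rtol=1e-6)


def test_negative_inputs_rejected():
    p = single_pld_protocol()
    with pytest.raises(ValidationError):
        gkm_delta_m(-1.0, 1.0, p)
    with pytest.raises(ValidationError):
        gkm_delta_m(60.0, -0.1, p)
    with pytest.raises(ValidationError):
        vsasl_delta_m(-5.0, vsasl_protocol())


# ------------------------------------------------------- single-PLD inversion
def test_single_pld_roundtrip_exact():
    """dM generated under the consensus assumptions inverts to CBF exactly.

    The consensus model is the kinetic model with label decay at blood T1
    throughout (T1app = T1b) and a fully delivered bolus, under which ATT
    cancels out of the expression.
    """
    p = single_pld_protocol(labeling_efficiency=0.85, t1_blood=1.65)
    consensus_forward = single_pld_protocol(
        labeling_efficiency=0.85, t1_blood=1.65, t1_tissue=1.65)
    cbf_true = np.full((4, 4, 2), 55.0)
    m0b = _vol(np.full((4, 4, 2), 1100.0))
    dm = gkm_delta_m(cbf_true, np.full((4, 4, 2), 1.0),
                     consensus_forward, m0b.values)[0]
    res = quantify_single_pld(_vol(dm), m0b, p)
    assert np.allclose(res.cbf.values, cbf_true, rtol=1e-12)


def test_single_pld_zero_dm_gives_zero_cbf():
    p = single_pld_protocol()
    m0b = _vol(np.ones((3, 3, 2)))
    res = quantify_single_pld(_vol(np.zeros((3, 3, 2))), m0b, p)
    assert np.all(res.cbf.values == 0.0)
    assert res.converged.all()


def test_single_pld_underestimates_when_bolus_incomplete():
    """With ATT beyond the PLD the bolus is still arriving at measurement and
    the consensus inversion recovers less than the true CBF."""
    p = single_pld_protocol(labeling_efficiency=0.85, t1_blood=1.65,
                            t1_tissue=1.65)
    cbf_true = 60.0
    att_long = 2.4  # s, > PLD 2.025 s: delivery incomplete at measurement
    dm = gkm_delta_m(np.full((2, 2, 1), cbf_true),
                     np.full((2, 2, 1), att_long), p, 1.0)[0]
    res = quantify_single_pld(_vol(dm), _vol(np.ones((2, 2, 1))), p)
    assert np.all(res.cbf.values < cbf_true * 0.95)


def test_single_pld_flags_bad_m0_voxels():
    p = single_pld_protocol()
    m0 = np.ones((3, 3, 1))
    m0[0, 0, 0] = 0.0
    res = quantify_single_pld(_vol(np.ones((3, 3, 1))), _vol(m0), p)
    assert not res.converged[0, 0, 0]
    assert res.cbf.values[0, 0, 0] == 0.0


# --------------------------------------------------------------------- VSASL
def test_vsasl_zero_at_zero_ti():
    p = vsasl_protocol(ti=0.0)
    assert vsasl_delta_m(60.0, p, 1.0) == pytest.approx(0.0)


def test_vsasl_linear_slope_closed_form():
    """Slope of dM vs CBF at TI 1.6 s, T1b 1.75 s, alpha 0.9, tau 1.59 s."""
    p = vsasl_protocol(t1_blood=1.75)
    slope = vsasl_delta_m(1.0, p, 1.0)
    expected = 2.0 * 0.9 * (1.0 / 6000.0) * min(1.6, 1.59) * np.exp(-1.6 / 1.75)
    assert slope == pytest.approx(expected, rel=1e-12)
    assert vsasl_delta_m(45.0, p, 1.0) == pytest.approx(45.0 * slope, rel=1e-12)


def test_vsasl_roundtrip_exact():
    p = vsasl_protocol(t1_blood=1.75)
    cbf_true = np.full((3, 3, 2), 45.0)
    m0b = _vol(np.full((3, 3, 2), 900.0))
    dm = vsasl_delta_m(cbf_true, p, m0b.values)
    res = quantify_vsasl(_vol(dm), m0b, p)
    assert np.allclose(res.cbf.values, cbf_true, rtol=1e-12)


def test_vsasl_t1b_rescaling_leaves_cvr_unchanged():
    """A different assumed blood T1 rescales pre and post CBF identically,
    so the CVR ratio is invariant."""
    gen = vsasl_protocol(t1_blood=1.75)
    m0b = _vol(np.full((3, 3, 2), 1000.0))
    pre = vsasl_delta_m(np.full((3, 3, 2), 50.0), gen, m0b.values)
    post = vsasl_delta_m(np.full((3, 3, 2), 70.0), gen, m0b.values)
    cvr = {}
    for t1b in (1.65, 1.75):
        q = vsasl_protocol(t1_blood=t1b)
        c_pre = quantify_vsasl(_vol(pre), m0b, q).cbf.values
        c_post = quantify_vsasl(_vol(post), m0b, q).cbf.values
        cvr[t1b] = (c_post - c_pre) / c_pre * 100.0
    assert np.allclose(cvr[1.65], cvr[1.75], rtol=1e-10)
    # while the CBF maps themselves rescale by a constant factor
    q165 = quantify_vsasl(_vol(pre), m0b, vsasl_protocol(t1_blood=1.65))
    q175 = quantify_vsasl(_vol(pre), m0b, vsasl_protocol(t1_blood=1.75))
    ratio = q165.cbf.values / q175.cbf.values
    assert np.allclose(ratio, ratio.flat[0])


# ----------------------------------------------------------------- multi-PLD
def test_multi_pld_noiseless_recovery_within_tolerance():
    p = multi_pld_protocol(labeling_efficiency=0.85, t1_blood=1.65)
    rng = np.random.default_rng(2)
    shape = (5, 5, 2)
    cbf_true = rng.uniform(20.0, 80.0, shape)
    att_true = rng.uniform(0.6, 1.8, shape)
    m0b = _vol(np.full(shape, 1000.0))
    dm = gkm_delta_m(cbf_true, att_true, p, m0b.values)
    series = [_vol(dm[i]) for i in range(3)]
    res = fit_multi_pld(series, m0b, p, priors=FitPriors(att_sd=0))
    assert np.all(np.abs(res.cbf.values / cbf_true - 1.0) < 0.01)
    assert np.all(np.abs(res.att.values / att_true - 1.0) < 0.02)


def test_multi_pld_all_zero_series_flagged():
    p = multi_pld_protocol()
    shape = (3, 3, 1)
    m0b = _vol(np.ones(shape))
    series = [_vol(np.zeros(shape)) for _ in range(3)]
    priors = FitPriors(att_mean=1.3, att_sd=0.5)
    res = fit_multi_pld(series, m0b, p, priors=priors)
    assert np.all(res.cbf.values == 0.0)
    assert np.allclose(res.att.values, 1.3)
    assert not res.converged.any()


def test_multi_pld_flat_prior_equals_nonlinear_least_squares():
    """Dual-route check: the profiled grid fit in the flat-prior limit
    matches scipy.optimize.least_squares on the same voxels."""
    p = multi_pld_protocol(labeling_efficiency=0.85, t1_blood=1.65)
    rng = np.random.default_rng(7)
    shape = (2, 2, 1)
    cbf_true = rng.uniform(30.0, 70.0, shape)
    att_true = rng.uniform(0.8, 1.6, shape)
    m0b = _vol(np.full(shape, 1.0))
    dm = gkm_delta_m(cbf_true, att_true, p, 1.0)
    noise = 0.02 * dm.mean() * rng.standard_normal(dm.shape)
    data = dm + noise
    series = [_vol(data[i]) for i in range(3)]
    res = fit_multi_pld(series, m0b, p, priors=FitPriors(att_sd=0),
                        att_grid=np.arange(0.0, 3.0, 0.002))

    for idx in np.ndindex(shape):
        y = data[(slice(None),) + idx]

        def resid(x):
            return gkm_delta_m(x[0], x[1], p, 1.0).reshape(-1) - y

        best = None
        for att0 in (0.8, 1.2, 1.6):
            sol = least_squares(
                lambda x: resid(x), x0=[50.0, att0],
                bounds=([0.0, 0.0], [200.0, 3.0]))
            if best is None or sol.cost < best.cost:
                best = sol
        assert res.cbf.values[idx] == pytest.approx(best.x[0], rel=5e-3)
        assert res.att.values[idx] == pytest.approx(best.x[1], abs=5e-3)


# ------------------------------------------------------------ M0 calibration
def test_calibrate_m0_long_tr_limit():
    pd_img = _vol(np.full((6, 6, 3), 900.0))
    m0b = calibrate_m0(pd_img, tr=1e9, partition_coefficient=0.9,
                       erosion_radius=0)
    assert np.allclose(m0b.values, 900.0 / 0.9)


def test_calibrate_m0_saturation_divisor():
    """TR 2000 ms at T1 1300 ms gives divisor 1 - exp(-2000/1300) ~ 0.785."""
    pd_img = _vol(np.full((6, 6, 3), 785.45))
    m0b = calibrate_m0(pd_img, tr=2000.0, t1_tissue=1.3,
                       partition_coefficient=1.0, erosion_radius=0)
    divisor = 1.0 - np.exp(-2000.0 / 1300.0)
    assert divisor == pytest.approx(0.785, abs=5e-4)
    assert np.allclose(m0b.values, 785.45 / divisor)


def test_calibrate_m0_interior_untouched_and_rim_refilled():
    rng = np.random.default_rng(3)
    shape = (12, 12, 6)
    values = rng.uniform(800.0, 1200.0, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[2:-2, 2:-2, 1:-1] = True
    pd_img = _vol(values, mask=mask)
    with_corr = calibrate_m0(pd_img, tr=2000.0, erosion_radius=1)
    no_corr = calibrate_m0(pd_img, tr=2000.0, erosion_radius=0)
    from scipy import ndimage
    interior = ndimage.binary_erosion(mask, iterations=1)
    assert np.array_equal(with_corr.values[interior], no_corr.values[interior])
    rim = mask & ~interior
    assert np.all(with_corr.values[rim] > 0)  # refilled, not zeroed
    assert not np.allclose(with_corr.values[rim], no_corr.values[rim])


def test_calibrate_m0_empty_after_erosion_rejected():
    mask = np.zeros((5, 5, 3), dtype=bool)
    mask[2, 2, 1] = True
    pd_img = _vol(np.ones((5, 5, 3)), mask=mask)
    with pytest.raises(ValidationError):
        calibrate_m0(pd_img, tr=2000.0, erosion_radius=2)
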