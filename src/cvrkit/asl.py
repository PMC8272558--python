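"""ASL forward models and inverse CBF quantification.

Three techniques are covered:

* single-PLD PCASL — closed-form CBF from the consensus single-delay formula;
* multi-PLD PCASL — voxelwise MAP fit of (CBF, ATT) to the continuous-
  labeling general kinetic model, with an optional spatial-prior iteration;
* VSASL — closed-form CBF from the velocity-selective (pulsed) model, which
  is transit-time-insensitive by construction.

The general kinetic model for continuous labeling describes the ASL
difference signal of a tissue voxel fed by a labeled bolus of duration tau
arriving after a transit time ATT:

    dM(t) = 0                                                  t < ATT
          = A * (1 - exp(-(t - ATT)/T1app))                    ATT <= t < ATT+tau
          = A * (1 - exp(-tau/T1app)) * exp(-(t-ATT-tau)/T1app)  t >= ATT+tau

with A = 2 * M0b * alpha * f * T1app * exp(-ATT/T1b) and f = CBF/6000 s^-1.
The apparent tissue relaxation is taken flow-independent
(1/T1app = 1/T1_tissue), which keeps dM exactly linear in CBF — at
physiological perfusion f/lambda is two orders of magnitude below 1/T1.

All protocol-card times (tau, PLD, TI, TR) are milliseconds and are converted
to seconds once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CBF_UNIT_SCALE, ImageVolume, ValidationError, require

#: Whole-brain tissue T1 assumed for M0 calibration and T1app, seconds.
DEFAULT_T1_TISSUE = 1.3

#: Blood-brain partition coefficient, mL/g.
DEFAULT_LAMBDA = 0.9

#: Consensus defaults used in fixed-(alpha, T1b) mode.
CONSENSUS_ALPHA_PCASL = 0.85
CONSENSUS_T1_BLOOD = 1.65

#: VSASL labeling efficiency, a protocol constant for the eddy-current-
#: compensated pulsed implementation.
VSASL_ALPHA = 0.9


@dataclass
class AslProtocol:
    """Acquisition parameters of one ASL technique (protocol-card units).

    ``bolus_duration``, ``plds`` and ``ti`` are milliseconds at the
    interface and exposed in seconds via ``tau_s`` / ``plds_s`` / ``ti_s``.
    """

    technique: str  # single_pld_pcasl | multi_pld_pcasl | vsasl
    bolus_duration: float  # ms
    plds: tuple[float, ...] = ()  # ms
    ti: float | None = None  # ms, VSASL
    vc: float | None = None  # cm/s, VSASL cut-off velocity
    tr: float | None = None  # ms, proton-density reference TR
    labeling_efficiency: float = CONSENSUS_ALPHA_PCASL
    t1_blood: float = CONSENSUS_T1_BLOOD  # s
    t1_tissue: float = DEFAULT_T1_TISSUE  # s
    partition_coefficient: float = DEFAULT_LAMBDA  # mL/g

    def __post_init__(self) -> None:
        require(self.technique in ("single_pld_pcasl", "multi_pld_pcasl", "vsasl"),
                f"unknown technique {self.technique!r}")
        require(0.0 < self.labeling_efficiency <= 1.0,
                "labeling_efficiency must lie in (0, 1]")
        require(self.partition_coefficient > 0, "partition coefficient must be > 0")
        if self.technique.endswith("pcasl"):
            require(len(self.plds) > 0, "PCASL protocols need at least one PLD")
            require(np.all(np.diff(self.plds) > 0) if len(self.plds) > 1 else True,
                    "PLDs must be strictly increasing")
        if self.technique == "vsasl":
            require(self.ti is not None and self.ti >= 0, "VSASL needs a TI >= 0")

    @property
    def tau_s(self) -> float:
        return self.bolus_duration * 1e-3

    @property
    def plds_s(self) -> np.ndarray:
        return np.asarray(self.plds, dtype=float) * 1e-3

    @property
    def ti_s(self) -> float:
        return float(self.ti) * 1e-3


def single_pld_protocol(**overrides) -> AslProtocol:
    """The single-delay PCASL protocol card (tau 1450 ms, PLD 2025 ms)."""
    kw = dict(technique="single_pld_pcasl", bolus_duration=1450.0,
              plds=(2025.0,), tr=4854.0)
    kw.update(overrides)
    return AslProtocol(**kw)


def multi_pld_protocol(**overrides) -> AslProtocol:
    """The 3-delay PCASL protocol card (tau 1700 ms, PLDs 300/2000/3700 ms)."""
    kw = dict(technique="multi_pld_pcasl", bolus_duration=1700.0,
              plds=(300.0, 2000.0, 3700.0), tr=5652.0)
    kw.update(overrides)
    return AslProtocol(**kw)


def vsasl_protocol(**overrides) -> AslProtocol:
    """The VSASL protocol card (tau 1590 ms, TI 1600 ms, Vc 2 cm/s)."""
    kw = dict(technique="vsasl", bolus_duration=1590.0, plds=(), ti=1600.0,
              vc=2.0, tr=4064.0, labeling_efficiency=VSASL_ALPHA)
    kw.update(overrides)
    return AslProtocol(**kw)


@dataclass
class AslFitResult:
    """Voxelwise quantification output."""

    cbf: ImageVolume  # mL/100 g/min
    att: ImageVolume | None = None  # s (multi-PLD PCASL only)
    residual: np.ndarray | None = None
    converged: np.ndarray | None = None


# ----------------------------------------------------------- forward models
def gkm_delta_m(
    cbf: float | np.ndarray,
    att: float | np.ndarray,
    protocol: AslProtocol,
    m0_blood: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Continuous-labeling general-kinetic-model difference signal per PLD.

    Evaluates dM at each measurement time t = tau + PLD for the given CBF
    (mL/100 g/min) and ATT (s).  Broadcasts over voxel arrays; the PLD axis
    is prepended, so the result has shape (n_plds, *voxel_shape).
    """
    cbf = np.asarray(cbf, dtype=float)
    att = np.asarray(att, dtype=float)
    require(bool(np.all(cbf >= 0)), "cbf must be non-negative")
    require(bool(np.all(att >= 0)), "att must be non-negative")
    f = cbf / CBF_UNIT_SCALE  # s^-1
    tau = protocol.tau_s
    t1app = protocol.t1_tissue
    t1b = protocol.t1_blood
    alpha = protocol.labeling_efficiency

    t = (tau + protocol.plds_s).reshape((-1,) + (1,) * cbf.ndim)
    amp = 2.0 * np.asarray(m0_blood) * alpha * f * t1app * np.exp(-att / t1b)
    dt_arr = t - att
    during = amp * (1.0 - np.exp(-np.clip(dt_arr, 0.0, None) / t1app))
    post = (amp * (1.0 - np.exp(-tau / t1app))
            * np.exp(-np.clip(dt_arr - tau, 0.0, None) / t1app))
    out = np.where(dt_arr <= 0.0, 0.0, np.where(dt_arr < tau, during, post))
    return out


def vsasl_delta_m(
    cbf: float | np.ndarray,
    protocol: AslProtocol,
    m0_blood: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Velocity-selective ASL difference signal at the protocol TI.

    dM = 2 * M0b * alpha * f * min(TI, tau) * exp(-TI/T1b): the labeled bolus
    grows linearly until it saturates at the bolus duration and decays with
    blood T1 — no transit-time dependence enters by construction.
    """
    cbf = np.asarray(cbf, dtype=float)
    require(bool(np.all(cbf >= 0)), "cbf must be non-negative")
    ti = protocol.ti_s
    require(ti >= 0, "TI must be non-negative")
    f = cbf / CBF_UNIT_SCALE
    return (2.0 * np.asarray(m0_blood) * protocol.labeling_efficiency * f
            * min(ti, protocol.tau_s) * np.exp(-ti / protocol.t1_blood))


# ------------------------------------------------------- closed-form inverses
def quantify_single_pld(
    delta_m: ImageVolume, m0_blood: ImageVolume, protocol: AslProtocol
) -> AslFitResult:
    """Single-delay PCASL CBF by the consensus closed-form inversion.

    CBF = 6000 * dM * exp(PLD/T1b)
          / (2 * alpha * T1b * M0b * (1 - exp(-tau/T1b)))   [mL/100 g/min]

    where M0b is the lambda-calibrated blood equilibrium magnetization from
    :func:`calibrate_m0`.  The formula assumes the full bolus has arrived by
    the measurement time and that the label decays with blood T1 throughout;
    under those assumptions it is the exact inverse of the kinetic model.
    """
    require(protocol.technique == "single_pld_pcasl",
            "protocol must be single_pld_pcasl")
    require(len(protocol.plds) == 1, "single-PLD quantification needs one PLD")
    pld = protocol.plds_s[0]
    t1b = protocol.t1_blood
    alpha = protocol.labeling_efficiency

    # lambda is already absorbed into the blood-M0 calibration image
    # (M0b = PD / ((1 - exp(-TR/T1_tissue)) * lambda)), so it does not
    # reappear here.
    m0 = m0_blood.values
    good = (m0 > 0) & delta_m.brain_mask
    denom = 2.0 * alpha * t1b * np.where(good, m0, 1.0) * (1.0 - np.exp(-protocol.tau_s / t1b))
    cbf = CBF_UNIT_SCALE * delta_m.values * np.exp(pld / t1b) / denom
    cbf = np.where(good, cbf, 0.0)
    return AslFitResult(
        cbf=delta_m.like(cbf, units="mL/100g/min"),
        att=None,
        residual=np.zeros_like(cbf),
        converged=good,
    )


def quantify_vsasl(
    delta_m: ImageVolume, m0_blood: ImageVolume, protocol: AslProtocol
) -> AslFitResult:
    """VSASL CBF by exact inversion of :func:`vsasl_delta_m`."""
    require(protocol.technique == "vsasl", "protocol must be vsasl")
    ti = protocol.ti_s
    m0 = m0_blood.values
    good = (m0 > 0) & delta_m.brain_mask
    denom = (2.0 * protocol.labeling_efficiency * np.where(good, m0, 1.0)
             * min(ti, protocol.tau_s))
    cbf = CBF_UNIT_SCALE * delta_m.values * np.exp(ti / protocol.t1_blood) / denom
    cbf = np.where(good, cbf, 0.0)
    return AslFitResult(
        cbf=delta_m.like(cbf, units="mL/100g/min"),
        att=None,
        residual=np.zeros_like(cbf),
        converged=good,
    )


# ------------------------------------------------------------- multi-PLD fit
@dataclass
class FitPriors:
    """Gaussian priors of the MAP (CBF, ATT) fit.

    ``att_sd`` of infinity (or a non-positive value) yields the flat-prior
    limit, in which the estimate is exactly nonlinear least squares.
    """

    att_mean: float = 1.3  # s
    att_sd: float = 1.0  # s; inf/<=0 -> flat
    cbf_ridge: float = 0.0  # weak non-negativity ridge on f, 0 -> flat
    noise_sd: float = 1.0  # data noise scale entering the prior weighting

    @property
    def flat(self) -> bool:
        return not (self.att_sd and np.isfinite(self.att_sd) and self.att_sd > 0)


def _att_objective(
    data: np.ndarray,
    m0: np.ndarray,
    protocol: AslProtocol,
    att_grid: np.ndarray,
    priors: FitPriors,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profile objective over an ATT grid with closed-form amplitude.

    For fixed ATT the kinetic model is linear in f, so the optimal f per
    voxel is a ratio of dot products; returns (objective, f_hat) with shapes
    (n_att, n_vox) and the per-PLD basis evaluated at unit CBF.
    """
    n_vox = data.shape[1]
    obj = np.empty((att_grid.size, n_vox))
    f_hat = np.empty((att_grid.size, n_vox))
    ridge = priors.cbf_ridge
    for i, att in enumerate(att_grid):
        basis = gkm_delta_m(np.ones(n_vox), np.full(n_vox, att), protocol, m0)
        gg = np.einsum("pv,pv->v", basis, basis) + ridge
        gd = np.einsum("pv,pv->v", basis, data)
        f = np.where(gg > 0, gd / np.where(gg > 0, gg, 1.0), 0.0)
        f = np.clip(f, 0.0, None)  # perfusion is non-negative
        resid = data - f * basis
        sse = np.einsum("pv,pv->v", resid, resid)
        if not priors.flat:
            sse = sse + (priors.noise_sd ** 2) * ((att - priors.att_mean)
                                                  / priors.att_sd) ** 2
        obj[i] = sse
        f_hat[i] = f
    return obj, f_hat, att_grid


def _parabolic_refine(att_grid: np.ndarray, obj: np.ndarray) -> np.ndarray:
    """Sub-grid minimum location by parabolic interpolation per voxel."""
    idx = np.argmin(obj, axis=0)
    idx_c = np.clip(idx, 1, att_grid.size - 2)
    y0 = obj[idx_c - 1, np.arange(obj.shape[1])]
    y1 = obj[idx_c, np.arange(obj.shape[1])]
    y2 = obj[idx_c + 1, np.arange(obj.shape[1])]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (y0 - y2) / np.where(
        np.abs(denom) > 1e-30, denom, 1.0), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    h = att_grid[1] - att_grid[0]
    att = att_grid[idx_c] + shift * h
    # interior minima only; at grid edges keep the edge value
    att = np.where(idx == 0, att_grid[0], att)
    att = np.where(idx == att_grid.size - 1, att_grid[-1], att)
    return att


def fit_multi_pld(
    delta_m_series: list[ImageVolume],
    m0_blood: ImageVolume,
    protocol: AslProtocol,
    priors: FitPriors | None = None,
    att_grid: np.ndarray | None = None,
    spatial_iterations: int = 0,
) -> AslFitResult:
    """Voxelwise MAP estimation of (CBF, ATT) from a multi-delay series.

    The kinetic model is linear in CBF at fixed ATT, so the fit profiles a
    closed-form amplitude over a 1-D ATT grid (with parabolic sub-grid
    refinement of the final ATT), which makes the estimator deterministic
    and fully vectorized.  With flat priors this is exactly nonlinear least
    squares.  ``spatial_iterations`` > 0 re-estimates with the ATT prior
    re-centred per voxel on the neighbourhood mean of the previous pass, a
    light-weight analogue of spatially regularized Bayesian fitting.

    All-zero voxels are returned with CBF 0, ATT at the prior mean, and
    ``converged=False``.
    """
    require(len(delta_m_series) >= 2, "multi-PLD fit needs at least two PLDs")
    require(len(delta_m_series) == len(protocol.plds),
            "series length must match protocol PLD count")
    shapes = {v.shape for v in delta_m_series}
    require(len(shapes) == 1 and delta_m_series[0].shape == m0_blood.shape,
            "series and M0 must share one grid")
    if priors is None:
        priors = FitPriors()
    if att_grid is None:
        att_grid = np.arange(0.0, 3.0 + 1e-9, 0.01)

    mask = delta_m_series[0].brain_mask & (m0_blood.values > 0)
    data = np.stack([v.values[mask] for v in delta_m_series])  # (p, vox)
    m0 = m0_blood.values[mask]

    degenerate = np.all(data == 0.0, axis=0)

    obj, f_hat, grid = _att_objective(data, m0, protocol, att_grid, priors)
    att_best = _parabolic_refine(grid, obj)

    # Re-solve the amplitude at the refined ATT.
    basis = gkm_delta_m(np.ones(att_best.size), att_best, protocol, m0)
    gg = np.einsum("pv,pv->v", basis, basis) + priors.cbf_ridge
    gd = np.einsum("pv,pv->v", basis, data)
    f_best = np.clip(np.where(gg > 0, gd / np.where(gg > 0, gg, 1.0), 0.0), 0.0, None)

    if spatial_iterations > 0:
        att_vol = np.zeros(m0_blood.shape)
        for _ in range(spatial_iterations):
            att_vol[mask] = att_best
            neigh = ndimage.uniform_filter(att_vol, size=3)
            count = ndimage.uniform_filter(mask.astype(float), size=3)
            neigh_mean = np.where(count > 0, neigh / np.where(count > 0, count, 1.0), 0.0)
            local = FitPriors(att_mean=0.0, att_sd=priors.att_sd if not priors.flat
                              else 0.25, cbf_ridge=priors.cbf_ridge,
                              noise_sd=priors.noise_sd)
            # re-centre the prior per voxel: shift the penalty target
            centres = neigh_mean[mask]
            obj = np.empty((att_grid.size, data.shape[1]))
            for i, att in enumerate(att_grid):
                b = gkm_delta_m(np.ones(data.shape[1]), np.full(data.shape[1], att),
                                protocol, m0)
                gg_i = np.einsum("pv,pv->v", b, b) + priors.cbf_ridge
                gd_i = np.einsum("pv,pv->v", b, data)
                f_i = np.clip(np.where(gg_i > 0, gd_i / np.where(gg_i > 0, gg_i, 1.0),
                                       0.0), 0.0, None)
                r = data - f_i * b
                obj[i] = (np.einsum("pv,pv->v", r, r)
                          + (local.noise_sd ** 2) * ((att - centres) / local.att_sd) ** 2)
            att_best = _parabolic_refine(att_grid, obj)
            basis = gkm_delta_m(np.ones(att_best.size), att_best, protocol, m0)
            gg = np.einsum("pv,pv->v", basis, basis) + priors.cbf_ridge
            gd = np.einsum("pv,pv->v", basis, data)
            f_best = np.clip(np.where(gg > 0, gd / np.where(gg > 0, gg, 1.0), 0.0),
                             0.0, None)

    resid = data - f_best * basis
    sse = np.einsum("pv,pv->v", resid, resid)

    att_best = np.where(degenerate, priors.att_mean, att_best)
    f_best = np.where(degenerate, 0.0, f_best)
    converged_vox = ~degenerate

    cbf_map = np.zeros(m0_blood.shape)
    att_map = np.zeros(m0_blood.shape)
    res_map = np.zeros(m0_blood.shape)
    conv_map = np.zeros(m0_blood.shape, dtype=bool)
    cbf_map[mask] = f_best  # basis is evaluated at unit CBF
    att_map[mask] = att_best
    res_map[mask] = sse
    conv_map[mask] = converged_vox

    return AslFitResult(
        cbf=m0_blood.like(cbf_map, units="mL/100g/min"),
        att=m0_blood.like(att_map, units="s"),
        residual=res_map,
        converged=conv_map,
    )


# ------------------------------------------------------------ M0 calibration
def calibrate_m0(
    proton_density: ImageVolume,
    tr: float,
    t1_tissue: float = DEFAULT_T1_TISSUE,
    partition_coefficient: float = DEFAULT_LAMBDA,
    mask: np.ndarray | None = None,
    erosion_radius: int = 1,
) -> ImageVolume:
    """Arterial-blood equilibrium magnetization from a short-TR PD image.

    The saturation-recovery PD signal is divided by 1 - exp(-TR/T1_tissue)
    to recover tissue M0, then by the partition coefficient lambda to express
    it as blood M0.  Edge partial-volume voxels are corrected by eroding the
    mask by ``erosion_radius`` and refilling the stripped rim by iterative
    nearest-interior local-mean extrapolation out to the original mask;
    interior voxels are untouched.

    Parameters
    ----------
    tr : repetition time in ms
    t1_tissue : whole-brain tissue T1 in seconds
    """
    require(tr > 0, "TR must be positive")
    if mask is None:
        mask = proton_density.brain_mask
    mask = np.asarray(mask, dtype=bool)

    divisor = 1.0 - np.exp(-(tr * 1e-3) / t1_tissue)
    m0b = proton_density.values / (divisor * partition_coefficient)

    if erosion_radius > 0:
        interior = ndimage.binary_erosion(mask, iterations=erosion_radius)
        if not interior.any():
            raise ValidationError("mask empty after erosion; reduce erosion_radius")
        filled = np.where(interior, m0b, 0.0)
        have = interior.copy()
        # grow back out to the original mask, each pass averaging the
        # already-filled neighbours of the rim voxels
        while not np.all(have[mask]):
            neigh_sum = ndimage.uniform_filter(filled, size=3) * 27.0
            neigh_cnt = ndimage.uniform_filter(have.astype(float), size=3) * 27.0
            rim = mask & ~have & (neigh_cnt > 0.5)
            if not rim.any():
                break
            filled[rim] = neigh_sum[rim] / neigh_cnt[rim]
            have |= rim
        m0b = np.where(mask, filled, 0.0)
    else:
        m0b = np.where(mask, m0b, 0.0)

    return ImageVolume(
        values=m0b,
        voxel_size=proton_density.voxel_size,
        brain_mask=mask,
        units="a.u.",
        affine=None if proton_density.affine is None else proton_density.affine.copy(),
    )
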