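"""One-compartment kinetic quantification of dynamic 15O-water PET.

Freely diffusible water tracer kinetics in a tissue voxel follow

    dCt/dt = f * Ca(t) - (f / lambda_p) * Ct(t),

with perfusion f (s^-1 internally, mL/100 g/min at the interface), an
image-derived arterial input function Ca(t), and the tissue-blood partition
coefficient lambda_p (mL/mL).  The solution is the convolution of the input
with f * exp(-(f/lambda_p) t); PET measures its average over each
reconstruction frame.

Frames are decay-corrected activity (corrections applied in reconstruction),
so the generator and the fit both work on corrected values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import CBF_UNIT_SCALE, ImageVolume, ValidationError, require

#: The ten-minute dynamic frame schedule: (count, duration s) blocks.
DEFAULT_FRAME_BLOCKS = ((30, 1.0), (10, 3.0), (12, 5.0), (12, 10.0), (12, 30.0))

#: Default bounds on the tissue-blood partition coefficient, mL/mL.
LAMBDA_P_BOUNDS = (0.3, 1.2)

_FINE_DT = 0.05  # s, internal convolution grid


def frame_schedule(blocks=DEFAULT_FRAME_BLOCKS) -> tuple[np.ndarray, np.ndarray]:
    """Frame start times and durations (s) from (count, duration) blocks."""
    durations = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return starts, durations


@dataclass
class AifCurve:
    """Arterial input function sampled at frame midpoints."""

    times: np.ndarray  # s
    concentration: np.ndarray  # activity / mL
    provenance: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        require(self.times.size == self.concentration.size,
                "times and concentration must align")
        require(bool(np.all(np.diff(self.times) > 0)),
                "AIF times must be strictly increasing")
        require(bool(np.all(self.concentration >= 0)),
                "AIF concentration must be non-negative")

    def to_tsv(self, path: str | Path) -> Path:
        pd.DataFrame({"time_s": self.times,
                      "concentration": self.concentration}).to_csv(
            path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "file") -> "AifCurve":
        frame = pd.read_csv(path, sep="\t")
        return cls(times=frame["time_s"].to_numpy(),
                   concentration=frame["concentration"].to_numpy(),
                   provenance=provenance)


@dataclass
class DynamicPetSeries:
    """Framed 4-D activity data with its acquisition schedule."""

    frames: np.ndarray  # (x, y, z, t)
    frame_start: np.ndarray  # s
    frame_duration: np.ndarray  # s
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_duration = np.asarray(self.frame_duration, dtype=float)
        require(self.frames.ndim == 4, "frames must be 4-D")
        require(self.frames.shape[-1] == self.frame_start.size
                == self.frame_duration.size,
                "frame axis must match the schedule")
        require(bool(np.all(self.frame_duration > 0)),
                "frame durations must be positive")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.frames.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration


@dataclass
class PetFitResult:
    cbf: ImageVolume  # mL/100 g/min
    partition_coefficient: ImageVolume  # mL/mL
    residual: np.ndarray | None = None
    converged: np.ndarray | None = None


# --------------------------------------------------------------- forward model
def _fine_grid(aif: AifCurve, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(0.0, t_end + _FINE_DT, _FINE_DT)
    ca = np.interp(t, aif.times, aif.concentration, left=0.0,
                   right=aif.concentration[-1])
    return t, ca


def _tissue_curve_fine(ca: np.ndarray, k2: np.ndarray | float) -> np.ndarray:
    """Solve dCt/dt = Ca - k2*Ct on the fine grid (unit K1) exactly per step.

    Exponential integrator with trapezoidal input:
        C[n+1] = C[n] e^{-k2 dt} + dt/2 (Ca[n] e^{-k2 dt} + Ca[n+1]).
    Broadcasts over a trailing axis of k2 values.
    """
    k2 = np.atleast_1d(np.asarray(k2, dtype=float))
    e = np.exp(-k2 * _FINE_DT)
    n = ca.size
    out = np.zeros((n, k2.size))
    half = 0.5 * _FINE_DT
    c = np.zeros(k2.size)
    for i in range(1, n):
        c = c * e + half * (ca[i - 1] * e + ca[i])
        out[i] = c
    return out


def _frame_average_nd(curve_fine: np.ndarray, starts: np.ndarray,
                      durations: np.ndarray) -> np.ndarray:
    """Frame-average a (time, ...) fine-grid curve by cumulative integral."""
    seg = 0.5 * (curve_fine[1:] + curve_fine[:-1]) * _FINE_DT
    cum = np.concatenate([np.zeros((1,) + curve_fine.shape[1:]),
                          np.cumsum(seg, axis=0)], axis=0)

    def integral_at(t: np.ndarray) -> np.ndarray:
        pos = t / _FINE_DT
        i0 = np.clip(pos.astype(int), 0, cum.shape[0] - 2)
        frac = (pos - i0).reshape((-1,) + (1,) * (cum.ndim - 1))
        return cum[i0] + frac * (cum[i0 + 1] - cum[i0])

    ends = starts + durations
    num = integral_at(ends) - integral_at(starts)
    return num / durations.reshape((-1,) + (1,) * (cum.ndim - 1))


def one_compartment_tac(
    cbf: float,
    partition_coefficient: float,
    aif: AifCurve,
    frame_start: np.ndarray,
    frame_duration: np.ndarray,
) -> np.ndarray:
    """Frame-averaged tissue activity for one (CBF, lambda_p) pair.

    Parameters
    ----------
    cbf : perfusion in mL/100 g/min
    partition_coefficient : lambda_p in mL/mL
    """
    require(cbf >= 0, "cbf must be non-negative")
    require(partition_coefficient > 0, "lambda_p must be positive")
    frame_start = np.asarray(frame_start, dtype=float)
    frame_duration = np.asarray(frame_duration, dtype=float)
    require(frame_start.size == frame_duration.size, "schedule arrays must align")
    t_end = float(frame_start[-1] + frame_duration[-1])
    if aif.times[-1] < t_end - 60.0:
        raise ValidationError(
            f"AIF ends at {aif.times[-1]:.0f}s, far short of the "
            f"schedule end {t_end:.0f}s")
    f = cbf / CBF_UNIT_SCALE
    k2 = f / partition_coefficient
    t_fine, ca = _fine_grid(aif, t_end)
    curve = f * _tissue_curve_fine(ca, k2)[:, 0]
    return _frame_average_nd(curve[:, None], frame_start, frame_duration)[:, 0]


# ---------------------------------------------------------------- AIF and fit
def extract_aif(series: DynamicPetSeries, carotid_mask: np.ndarray) -> AifCurve:
    """Image-derived AIF: frame-wise mean activity over the carotid mask."""
    carotid_mask = np.asarray(carotid_mask, dtype=bool)
    require(carotid_mask.shape == series.frames.shape[:3],
            "carotid mask must match the image grid")
    if not carotid_mask.any():
        raise ValidationError("carotid mask is empty")
    conc = series.frames[carotid_mask].mean(axis=0)
    return AifCurve(times=series.midpoints, concentration=np.clip(conc, 0.0, None),
                    provenance="image-derived")


def fit_cbf_dynamic_pet(
    series: DynamicPetSeries,
    aif: AifCurve,
    lambda_bounds: tuple[float, float] = LAMBDA_P_BOUNDS,
    k2_grid: np.ndarray | None = None,
) -> PetFitResult:
    """Voxelwise weighted least-squares fit of (CBF, lambda_p).

    The model C(t) = K1 * conv(Ca, exp(-k2 t)) is linear in K1 = f at fixed
    k2 = f/lambda_p, so the fit profiles a closed-form amplitude over a k2
    grid (shared basis functions for all voxels), refines k2 by parabolic
    interpolation, and recovers lambda_p = K1/k2.  Voxels whose unconstrained
    lambda_p falls outside ``lambda_bounds`` are refit with lambda_p pinned
    at the violated bound by a bounded scalar minimization.  Weights are
    proportional to frame duration, approximating count statistics after
    reconstruction.
    """
    starts, durs = series.frame_start, series.frame_duration
    t_end = float(starts[-1] + durs[-1])
    if abs(aif.times.size - starts.size) > 0 and (
            aif.times[-1] < starts[-1] or aif.times[0] > starts[0] + durs[0]):
        raise ValidationError("AIF sampling does not cover the frame schedule")

    if k2_grid is None:
        k2_grid = np.geomspace(2e-4, 0.2, 240)
    t_fine, ca = _fine_grid(aif, t_end)

    # Basis: frame-averaged unit-K1 tissue curves for every k2.
    fine = _tissue_curve_fine(ca, k2_grid)  # (t_fine, n_k2)
    basis = _frame_average_nd(fine, starts, durs)  # (n_frames, n_k2)

    mask = series.brain_mask
    data = series.frames[mask].T  # (n_frames, n_vox)
    w = (durs / durs.sum()).reshape(-1, 1)

    bb = np.einsum("fk,fk,f->k", basis, basis, w[:, 0])  # (n_k2,)
    bd = basis.T @ (w * data)  # (n_k2, n_vox)
    k1_hat = np.clip(bd / bb[:, None], 0.0, None)
    dd = np.einsum("fv,fv,f->v", data, data, w[:, 0])
    # SSE(k2) = dd - 2 k1 bd + k1^2 bb
    sse = dd[None, :] - 2.0 * k1_hat * bd + (k1_hat ** 2) * bb[:, None]

    idx = np.argmin(sse, axis=0)
    n_vox = data.shape[1]
    cols = np.arange(n_vox)

    # parabolic refinement in log(k2)
    idx_c = np.clip(idx, 1, k2_grid.size - 2)
    y0, y1, y2 = sse[idx_c - 1, cols], sse[idx_c, cols], sse[idx_c + 1, cols]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2)
                     / np.where(np.abs(denom) > 1e-300, denom, 1.0), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    logk = np.log(k2_grid)
    h = logk[1] - logk[0]
    k2_best = np.exp(logk[idx_c] + shift * h)
    k2_best = np.where(idx == 0, k2_grid[0], k2_best)
    k2_best = np.where(idx == k2_grid.size - 1, k2_grid[-1], k2_best)

    # closed-form K1 at refined k2 (recompute exact basis per unique voxel set
    # is costly; interpolate the basis in log k2 instead)
    def basis_at(k2v: np.ndarray) -> np.ndarray:
        pos = np.clip((np.log(k2v) - logk[0]) / h, 0.0, k2_grid.size - 1.0001)
        i0 = pos.astype(int)
        frac = pos - i0
        return basis[:, i0] * (1 - frac) + basis[:, i0 + 1] * frac

    b_best = basis_at(k2_best)  # (n_frames, n_vox)
    bb_best = np.einsum("fv,fv,f->v", b_best, b_best, w[:, 0])
    bd_best = np.einsum("fv,fv,f->v", b_best, data, w[:, 0])
    k1_best = np.clip(np.where(bb_best > 0, bd_best / np.where(bb_best > 0,
                                                               bb_best, 1.0), 0.0),
                      0.0, None)

    lam = np.where(k2_best > 0, k1_best / k2_best, 0.0)

    zero_vox = np.all(data == 0.0, axis=0)
    converged = ~zero_vox

    # Bound handling: pin lambda_p at the violated bound and refit f alone.
    lo, hi = lambda_bounds
    out_of_bounds = (~zero_vox) & ((lam < lo) | (lam > hi)) & (k1_best > 0)
    if out_of_bounds.any():
        for v in np.nonzero(out_of_bounds)[0]:
            lam_pin = lo if lam[v] < lo else hi
            d = data[:, v]

            def sse_f(f: float) -> float:
                k2v = max(f, 1e-12) / lam_pin
                b = basis_at(np.array([k2v]))[:, 0]
                r = d - f * b
                return float(np.sum(w[:, 0] * r * r))

            res = minimize_scalar(sse_f, bounds=(0.0, 0.05), method="bounded")
            k1_best[v] = res.x
            lam[v] = lam_pin
            k2_best[v] = res.x / lam_pin

    lam = np.where(zero_vox, 0.0, lam)
    k1_best = np.where(zero_vox, 0.0, k1_best)

    b_fin = basis_at(np.where(k2_best > 0, k2_best, k2_grid[0]))
    resid = data - k1_best * b_fin
    sse_fin = np.einsum("fv,fv,f->v", resid, resid, w[:, 0])

    shape = series.frames.shape[:3]
    cbf_map = np.zeros(shape)
    lam_map = np.zeros(shape)
    res_map = np.zeros(shape)
    conv_map = np.zeros(shape, dtype=bool)
    cbf_map[mask] = k1_best * CBF_UNIT_SCALE
    lam_map[mask] = lam
    res_map[mask] = sse_fin
    conv_map[mask] = converged

    vol = ImageVolume(values=cbf_map, voxel_size=series.voxel_size,
                      brain_mask=mask, units="mL/100g/min")
    return PetFitResult(
        cbf=vol,
        partition_coefficient=vol.like(lam_map, units="mL/mL"),
        residual=res_map,
        converged=conv_map,
    )


# ------------------------------------------------------------- median filter
def median_filter_slicewise(volume: ImageVolume, window: int = 5) -> ImageVolume:
    """2-D median filter applied slice by slice within the brain mask.

    Each axial (z) slice is filtered with a ``window`` x ``window`` median;
    out-of-mask voxels are excluded from every window (within-mask
    truncation), and voxels outside the mask pass through unchanged.
    """
    require(window % 2 == 1, "window size must be odd")
    nx, ny, _ = volume.shape
    require(window <= nx and window <= ny, "window larger than slice")
    half = window // 2
    values = volume.values
    mask = volume.brain_mask
    out = values.copy()

    padded = np.pad(values, ((half, half), (half, half), (0, 0)),
                    constant_values=np.nan)
    padded_mask = np.pad(mask, ((half, half), (half, half), (0, 0)),
                         constant_values=False)
    padded = np.where(padded_mask, padded, np.nan)

    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (window, window), axis=(0, 1))  # (nx, ny, nz, w, w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(windows.reshape(*values.shape, -1), axis=-1)
    out[mask] = med[mask]
    return volume.like(out)


# ---------------------------------------------------------------- schedule IO
def write_frame_schedule(starts: np.ndarray, durations: np.ndarray,
                         path: str | Path) -> Path:
    pd.DataFrame({"frame_start_s": starts,
                  "frame_duration_s": durations}).to_csv(path, sep="\t",
                                                         index=False)
    return Path(path)


def read_frame_schedule(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path, sep="\t")
    return (frame["frame_start_s"].to_numpy(dtype=float),
            frame["frame_duration_s"].to_numpy(dtype=float))
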