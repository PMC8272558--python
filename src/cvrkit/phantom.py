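"""Synthetic CVR study generator: phantom anatomy, truth maps, acquisitions.

A desk-scale digital phantom stands in for a PET/MRI cohort: a layered
ellipsoid brain (GM shell, WM core, CSF ventricles) plus carotid cylinders
for the image-derived AIF.  Each synthetic subject carries ground-truth
pre/post-vasodilator CBF and ATT maps, blood physiology, and a four-vessel
flow/velocity table, from which noisy ASL difference images, an M0 image,
and a dynamic PET series are generated with the same forward models the
estimators fit — so noiseless runs are exact roundtrips, and noise studies
isolate estimator behaviour from model misfit.

Default conditions mirror the study this pipeline emulates: vasodilation
raises CBF by ~42% in GM, shortens ATT by 10%, raises vessel mean velocity
from 27 to 38 cm/s and total flow by ~51%; cohort hematocrit is 0.43 +- 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .blood import SubjectBlood, write_physiology_table
from .core import ImageVolume, ValidationError, require, save_nifti_4d
from .labeling import (
    MULTI_PLD_TRAIN,
    SINGLE_PLD_TRAIN,
    LabelingTrainSpec,
    VesselFlowRecord,
    effective_subject_efficiency,
    laminar_mean_efficiency,
    simulate_efficiency_curve,
    write_vessel_table,
)
from .asl import AslProtocol, gkm_delta_m, vsasl_delta_m
from .pet import (
    AifCurve,
    DynamicPetSeries,
    DEFAULT_FRAME_BLOCKS,
    _fine_grid,
    _frame_average_nd,
    _tissue_curve_fine,
    frame_schedule,
    write_frame_schedule,
)
from .core import CBF_UNIT_SCALE

LABELS = {"background": 0, "gm": 1, "wm": 2, "csf": 3, "carotid": 4}


@dataclass
class TissueClassParams:
    cbf_pre: float  # mL/100 g/min
    cvr_true: float  # %
    att_pre: float  # s
    t1_tissue: float = 1.3  # s
    m0_tissue: float = 1000.0  # a.u.
    lambda_p: float = 0.9  # mL/mL (PET partition coefficient)


@dataclass
class PhantomSpec:
    """Study-condition parameters of the synthetic cohort."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)  # mm
    gm: TissueClassParams = field(default_factory=lambda: TissueClassParams(
        cbf_pre=60.0, cvr_true=42.0, att_pre=1.2))
    wm: TissueClassParams = field(default_factory=lambda: TissueClassParams(
        cbf_pre=22.0, cvr_true=38.0, att_pre=1.45, m0_tissue=850.0,
        lambda_p=0.82))
    csf: TissueClassParams = field(default_factory=lambda: TissueClassParams(
        cbf_pre=0.0, cvr_true=0.0, att_pre=1.2, m0_tissue=1300.0,
        lambda_p=0.3))
    att_reduction: float = 0.10  # fractional ATT drop post-vasodilator
    att_posterior_scale: float = 0.25  # posterior ATT prolongation (up to +25%)
    n_subjects: int = 19
    cbf_between_subject_sd: float = 0.10  # fractional
    cvr_between_subject_sd: float = 0.10  # fractional
    att_between_subject_sd: float = 0.05  # fractional
    within_class_sd: float = 0.05  # fractional smooth spatial variation
    asl_temporal_snr: float = 20.0  # GM dM mean over noise sd
    pet_noise_scale: float = 1.0  # frame noise scale
    vessel_velocity_pre: float = 27.0  # cm/s, cohort mean
    vessel_velocity_post: float = 38.0  # cm/s, cohort mean
    flow_total_pre: float = 600.0  # mL/min
    flow_increase: float = 0.51  # fractional total-flow rise post
    vessel_velocity_sd: float = 0.10  # fractional between-subject
    hematocrit_mean: float = 0.43
    hematocrit_sd: float = 0.05
    sao2_mean: float = 0.999
    sao2_sd: float = 0.004
    aif_peak_time: float = 35.0  # s
    aif_scale: float = 100.0  # activity units
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.n_subjects >= 1, "need at least one subject")
        require(all(n >= 12 for n in self.grid_shape),
                "grid too small for the layered phantom")
        require(0.0 < self.att_reduction < 1.0, "att_reduction must be in (0,1)")


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject."""

    subject_id: str
    labels: np.ndarray  # tissue class map
    brain_mask: np.ndarray
    carotid_mask: np.ndarray
    cbf_pre: ImageVolume
    cbf_post: ImageVolume
    att_pre: ImageVolume
    att_post: ImageVolume
    cvr_true: ImageVolume
    t1_tissue: np.ndarray
    m0_tissue: np.ndarray
    lambda_p: np.ndarray
    blood: SubjectBlood
    vessels_pre: list[VesselFlowRecord]
    vessels_post: list[VesselFlowRecord]
    aif_true: AifCurve

    def roi_masks(self) -> dict[str, np.ndarray]:
        return {
            "whole_brain": self.brain_mask,
            "gm": self.labels == LABELS["gm"],
            "wm": self.labels == LABELS["wm"],
        }


def _ellipsoid(shape, centre, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centre, semi))
    return acc <= 1.0


def build_anatomy(shape: tuple[int, int, int]) -> np.ndarray:
    """Layered ellipsoid label map: GM shell, WM core, CSF ventricles,
    carotid cylinders outside the brain."""
    nx, ny, nz = shape
    centre = (nx / 2 - 0.5, ny / 2 - 0.5, nz / 2 - 0.5)
    brain = _ellipsoid(shape, centre, (0.42 * nx, 0.42 * ny, 0.40 * nz))
    wm = _ellipsoid(shape, centre, (0.26 * nx, 0.26 * ny, 0.25 * nz))
    vent_l = _ellipsoid(shape, (centre[0] - 0.08 * nx, centre[1], centre[2]),
                        (0.05 * nx, 0.12 * ny, 0.08 * nz))
    vent_r = _ellipsoid(shape, (centre[0] + 0.08 * nx, centre[1], centre[2]),
                        (0.05 * nx, 0.12 * ny, 0.08 * nz))
    csf = vent_l | vent_r

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = LABELS["gm"]
    labels[wm] = LABELS["wm"]
    labels[csf] = LABELS["csf"]

    # carotid cylinders along z near the grid floor, outside the brain
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for cx in (0.12 * nx, 0.88 * nx):
        cyl = (xs - cx) ** 2 + (ys - ny / 2) ** 2 <= (0.04 * nx) ** 2
        col = np.zeros(shape, dtype=bool)
        col[cyl, : max(2, nz // 6)] = True
        col &= labels == 0
        labels[col] = LABELS["carotid"]
    if not (labels == LABELS["carotid"]).any():
        raise ValidationError("invalid class partition: no carotid voxels fit")
    return labels


def _smooth_field(rng: np.random.Generator, shape, rel_sd: float) -> np.ndarray:
    """Smooth multiplicative field with mean 1 and sd ``rel_sd``."""
    if rel_sd <= 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=3.0)
    sd = smooth.std()
    return 1.0 + rel_sd * smooth / (sd if sd > 0 else 1.0)


def gamma_variate_aif(times: np.ndarray, peak_time: float = 35.0,
                      onset: float = 10.0, shape_k: float = 3.0,
                      scale: float = 100.0, recirc: float = 0.12) -> np.ndarray:
    """Gamma-variate bolus with a slow recirculation tail."""
    t = np.clip(times - onset, 0.0, None)
    tp = peak_time - onset
    main = (t / tp) ** shape_k * np.exp(shape_k * (1.0 - t / tp))
    tail = recirc * (1.0 - np.exp(-t / tp)) * np.exp(-t / 400.0)
    return scale * (main + tail)


def make_phantom(spec: PhantomSpec, subject_index: int = 0) -> PhantomTruth:
    """Deterministic truth generation for one subject of the cohort.

    All random draws come from ``default_rng([seed, subject_index])``, so
    the same (seed, index) pair reproduces the truth bitwise.
    """
    require(0 <= subject_index < spec.n_subjects, "subject_index out of range")
    rng = np.random.default_rng([spec.seed, subject_index])
    shape = spec.grid_shape
    labels = build_anatomy(shape)
    # analysis mask: perfused tissue only — CVR is undefined at zero
    # perfusion, so the CSF ventricles stay in the anatomy but outside the
    # quantification mask
    brain = (labels == LABELS["gm"]) | (labels == LABELS["wm"])
    carotid = labels == LABELS["carotid"]

    # subject-level multipliers
    cbf_mult = 1.0 + spec.cbf_between_subject_sd * rng.standard_normal()
    cvr_mult = 1.0 + spec.cvr_between_subject_sd * rng.standard_normal()
    att_mult = 1.0 + spec.att_between_subject_sd * rng.standard_normal()
    cbf_mult, cvr_mult, att_mult = (max(m, 0.3) for m in
                                    (cbf_mult, cvr_mult, att_mult))

    cbf_pre = np.zeros(shape)
    cvr = np.zeros(shape)
    att_pre = np.zeros(shape)
    t1_tissue = np.zeros(shape)
    m0_tissue = np.zeros(shape)
    lambda_p = np.zeros(shape)
    for name, params in (("gm", spec.gm), ("wm", spec.wm), ("csf", spec.csf)):
        sel = labels == LABELS[name]
        cbf_pre[sel] = params.cbf_pre * cbf_mult
        cvr[sel] = params.cvr_true * cvr_mult
        att_pre[sel] = params.att_pre * att_mult
        t1_tissue[sel] = params.t1_tissue
        m0_tissue[sel] = params.m0_tissue
        lambda_p[sel] = params.lambda_p

    # smooth within-class variation (shared by pre/post so truth CVR is the
    # drawn CVR field exactly)
    cbf_pre *= _smooth_field(rng, shape, spec.within_class_sd)
    att_pre *= _smooth_field(rng, shape, spec.within_class_sd)

    # posterior (increasing y) ATT prolongation, up to att_posterior_scale
    ys = np.arange(shape[1]) / max(shape[1] - 1, 1)
    att_pre *= (1.0 + spec.att_posterior_scale * ys)[None, :, None]

    cbf_pre = np.clip(np.where(brain, cbf_pre, 0.0), 0.0, None)
    att_pre = np.clip(np.where(brain, att_pre, 0.0), 0.0, None)
    cvr = np.where(brain, cvr, 0.0)

    cbf_post = cbf_pre * (1.0 + cvr / 100.0)
    att_post = att_pre * (1.0 - spec.att_reduction)
    cvr_true = np.where(cbf_pre > 0,
                        (cbf_post - cbf_pre) / np.where(cbf_pre > 0, cbf_pre, 1.0)
                        * 100.0, 0.0)

    # blood physiology
    hct = float(np.clip(rng.normal(spec.hematocrit_mean, spec.hematocrit_sd),
                        0.25, 0.60))
    sao2 = float(np.clip(rng.normal(spec.sao2_mean, spec.sao2_sd), 0.90, 1.0))
    blood = SubjectBlood(hematocrit=hct, hemoglobin=round(34.2 * hct, 1),
                         oxygen_saturation=sao2)

    # four-vessel table; ICA carry ~80% of inflow
    vessel_ids = ["left_ica", "right_ica", "left_vertebral", "right_vertebral"]
    splits = np.array([0.4, 0.4, 0.1, 0.1])
    splits = splits * (1.0 + 0.05 * rng.standard_normal(4))
    splits = splits / splits.sum()
    v_subj = max(0.3, 1.0 + spec.vessel_velocity_sd * rng.standard_normal())
    v_pre = spec.vessel_velocity_pre * v_subj * (
        1.0 + 0.08 * rng.standard_normal(4))
    v_post = v_pre * (spec.vessel_velocity_post / spec.vessel_velocity_pre)
    q_pre = spec.flow_total_pre * splits
    q_post = q_pre * (1.0 + spec.flow_increase)
    vessels_pre = [VesselFlowRecord(vid, float(q), float(v), "pre")
                   for vid, q, v in zip(vessel_ids, q_pre, v_pre)]
    vessels_post = [VesselFlowRecord(vid, float(q), float(v), "post")
                    for vid, q, v in zip(vessel_ids, q_post, v_post)]

    starts, durs = frame_schedule(DEFAULT_FRAME_BLOCKS)
    t_end = starts[-1] + durs[-1]
    t_aif = np.arange(0.0, t_end + 1.0, 1.0)
    aif_true = AifCurve(times=t_aif,
                        concentration=gamma_variate_aif(
                            t_aif, peak_time=spec.aif_peak_time,
                            scale=spec.aif_scale),
                        provenance="synthetic-truth")

    def vol(arr, units=""):
        return ImageVolume(values=arr, voxel_size=spec.voxel_size,
                           brain_mask=brain, units=units)

    return PhantomTruth(
        subject_id=f"sub-{subject_index + 1:02d}",
        labels=labels,
        brain_mask=brain,
        carotid_mask=carotid,
        cbf_pre=vol(cbf_pre, "mL/100g/min"),
        cbf_post=vol(cbf_post, "mL/100g/min"),
        att_pre=vol(att_pre, "s"),
        att_post=vol(att_post, "s"),
        cvr_true=vol(cvr_true, "%"),
        t1_tissue=t1_tissue,
        m0_tissue=m0_tissue,
        lambda_p=lambda_p,
        blood=blood,
        vessels_pre=vessels_pre,
        vessels_post=vessels_post,
        aif_true=aif_true,
    )


# --------------------------------------------------------------- acquisitions
#: TR of the saturation-recovery proton-density reference, ms.
PD_REFERENCE_TR = 2000.0


@dataclass
class SubjectDataset:
    """One subject's simulated acquisitions plus the generating truth."""

    truth: PhantomTruth
    proton_density: ImageVolume
    asl: dict[str, dict[str, list[ImageVolume]]]  # technique -> cond -> dM/PLD
    pet: dict[str, DynamicPetSeries]  # cond -> series
    alphas: dict[str, dict[str, float]]  # technique -> cond -> alpha used
    efficiency_mode: str
    seed: int
    noiseless: bool


def _effective_alpha(
    train: LabelingTrainSpec,
    blood: SubjectBlood,
    vessels: list[VesselFlowRecord],
    time_step_ms: float,
    cache: dict | None = None,
) -> float:
    """Per-subject effective alpha: laminar per-vessel, flow-volume weighted."""
    key = (train.name, round(blood.hematocrit, 4),
           round(blood.oxygen_saturation, 4), time_step_ms)
    if cache is not None and key in cache:
        curve = cache[key]
    else:
        curve = simulate_efficiency_curve(train, blood, time_step=time_step_ms)
        if cache is not None:
            cache[key] = curve
    alphas = [laminar_mean_efficiency(curve, v.mean_velocity) for v in vessels]
    return effective_subject_efficiency(alphas, vessels)


def simulate_acquisitions(
    truth: PhantomTruth,
    protocols: dict[str, AslProtocol],
    spec: PhantomSpec,
    seed: int,
    noiseless: bool = False,
    efficiency_mode: str = "fixed",
    fixed_alpha: float = 0.85,
    bloch_time_step_ms: float = 0.02,
    efficiency_cache: dict | None = None,
    pet_blocks=DEFAULT_FRAME_BLOCKS,
) -> SubjectDataset:
    """Generate the full acquisition set of one subject.

    Signal generation delegates to the same forward models the estimators
    fit (``gkm_delta_m``, ``vsasl_delta_m``, the one-compartment tissue
    curve).  ASL noise is additive Gaussian at the configured temporal SNR
    (GM mean |dM| over noise sd); PET frame noise is Gaussian with variance
    proportional to the frame mean activity divided by the frame duration.

    ``efficiency_mode``: ``"fixed"`` emits every PCASL acquisition at
    ``fixed_alpha``; ``"simulated"`` runs the Bloch simulator on the
    subject's blood and vessel velocities and emits the flow-weighted
    effective alpha per condition (alpha_post > alpha_pre when velocity
    rises).
    """
    require(efficiency_mode in ("fixed", "simulated"),
            f"unknown efficiency mode {efficiency_mode!r}")
    for name in protocols:
        require(protocols[name].technique in
                ("single_pld_pcasl", "multi_pld_pcasl", "vsasl"),
                f"unknown protocol {name!r}")
    rng = np.random.default_rng([seed, 17, int(truth.subject_id[-2:])])
    brain = truth.brain_mask
    gm = truth.labels == LABELS["gm"]

    # proton-density reference (saturation recovery at the PD TR)
    sat = 1.0 - np.exp(-(PD_REFERENCE_TR * 1e-3)
                       / np.where(truth.t1_tissue > 0, truth.t1_tissue, 1.0))
    pd_img = np.where(brain, truth.m0_tissue * sat, 0.0)
    if not noiseless:
        pd_noise = pd_img[gm].mean() / (20.0 * spec.asl_temporal_snr)
        pd_img = pd_img + rng.normal(0.0, pd_noise, pd_img.shape) * brain
    proton_density = ImageVolume(values=pd_img, voxel_size=spec.voxel_size,
                                 brain_mask=brain, units="a.u.")

    m0b_true = truth.m0_tissue / 0.9  # blood M0 at lambda = 0.9

    trains = {"single_pld_pcasl": SINGLE_PLD_TRAIN,
              "multi_pld_pcasl": MULTI_PLD_TRAIN}

    asl_out: dict[str, dict[str, list[ImageVolume]]] = {}
    alphas: dict[str, dict[str, float]] = {}
    conditions = {
        "pre": (truth.cbf_pre, truth.att_pre, truth.vessels_pre),
        "post": (truth.cbf_post, truth.att_post, truth.vessels_post),
    }

    for name, protocol in protocols.items():
        asl_out[name] = {}
        alphas[name] = {}
        for cond, (cbf, att, vessels) in conditions.items():
            if protocol.technique == "vsasl":
                alpha = protocol.labeling_efficiency
            elif efficiency_mode == "fixed":
                alpha = fixed_alpha
            else:
                alpha = _effective_alpha(trains[protocol.technique],
                                         truth.blood, vessels,
                                         bloch_time_step_ms, efficiency_cache)
            alphas[name][cond] = float(alpha)

            acq = AslProtocol(
                technique=protocol.technique,
                bolus_duration=protocol.bolus_duration,
                plds=protocol.plds, ti=protocol.ti, vc=protocol.vc,
                tr=protocol.tr, labeling_efficiency=alpha,
                t1_blood=truth.blood.t1_blood if efficiency_mode == "simulated"
                else protocol.t1_blood,
                t1_tissue=protocol.t1_tissue,
                partition_coefficient=protocol.partition_coefficient,
            )
            if protocol.technique == "vsasl":
                dm = vsasl_delta_m(cbf.values, acq, m0b_true)[None]
            else:
                dm = gkm_delta_m(cbf.values, att.values, acq, m0b_true)
            dm = np.where(brain[None], dm, 0.0)
            if not noiseless:
                sd = np.abs(dm[:, gm]).mean() / spec.asl_temporal_snr
                dm = dm + rng.normal(0.0, sd, dm.shape) * brain[None]
            asl_out[name][cond] = [
                ImageVolume(values=dm[i], voxel_size=spec.voxel_size,
                            brain_mask=brain, units="a.u.")
                for i in range(dm.shape[0])
            ]

    # dynamic PET, pre and post
    starts, durs = frame_schedule(pet_blocks)
    t_end = float(starts[-1] + durs[-1])
    t_fine, ca = _fine_grid(truth.aif_true, t_end)
    pet_out: dict[str, DynamicPetSeries] = {}
    for cond, (cbf, att, _) in conditions.items():
        f_vox = cbf.values[brain] / CBF_UNIT_SCALE
        lam_vox = np.where(truth.lambda_p[brain] > 0, truth.lambda_p[brain], 0.9)
        k2_vox = f_vox / lam_vox
        fine = _tissue_curve_fine(ca, k2_vox)  # (t_fine, n_vox)
        frames_vox = _frame_average_nd(fine, starts, durs) * f_vox  # (fr, vox)
        frames = np.zeros(truth.labels.shape + (starts.size,))
        frames[brain] = frames_vox.T
        # carotid voxels carry the true AIF (frame-averaged)
        aif_frames = _frame_average_nd(ca[:, None], starts, durs)[:, 0]
        frames[truth.carotid_mask] = aif_frames
        if not noiseless:
            mean_act = frames[brain].mean(axis=0)  # per-frame brain mean
            sd = spec.pet_noise_scale * np.sqrt(
                np.clip(mean_act, 0.0, None) / durs)
            frames = frames + rng.normal(0.0, 1.0, frames.shape) * sd
        pet_out[cond] = DynamicPetSeries(
            frames=frames, frame_start=starts, frame_duration=durs,
            voxel_size=spec.voxel_size, brain_mask=brain)

    return SubjectDataset(
        truth=truth,
        proton_density=proton_density,
        asl=asl_out,
        pet=pet_out,
        alphas=alphas,
        efficiency_mode=efficiency_mode,
        seed=seed,
        noiseless=noiseless,
    )


# -------------------------------------------------------------------- dataset IO
def write_dataset(dataset: SubjectDataset, directory: str | Path) -> dict:
    """Write one subject's volumes and tables; return (and save) a manifest.

    Every file is listed in the manifest with its role; the manifest also
    records the generation seed and settings so the dataset can be
    regenerated identically.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create dataset directory "
                              f"{directory}: {exc}") from exc
    truth = dataset.truth
    files: list[dict] = []

    def record(path: Path, role: str) -> None:
        files.append({"file": path.name, "role": role})

    def write_vol(vol: ImageVolume, name: str, role: str) -> None:
        p = directory / name
        vol.to_nifti(p)
        record(p, role)

    write_vol(dataset.proton_density, "proton_density.nii.gz", "m0_reference")
    for name, conds in dataset.asl.items():
        for cond, series in conds.items():
            for i, vol in enumerate(series):
                write_vol(vol, f"dm_{name}_{cond}_pld{i}.nii.gz",
                          f"asl_difference:{name}:{cond}:pld{i}")
    for cond, series in dataset.pet.items():
        p = directory / f"pet_dynamic_{cond}.nii.gz"
        save_nifti_4d(series.frames, series.voxel_size, p)
        record(p, f"pet_dynamic:{cond}")
    p = directory / "pet_frame_schedule.tsv"
    any_pet = next(iter(dataset.pet.values()))
    write_frame_schedule(any_pet.frame_start, any_pet.frame_duration, p)
    record(p, "pet_frame_schedule")

    p = directory / "aif_true.tsv"
    truth.aif_true.to_tsv(p)
    record(p, "aif_truth")

    p = directory / "vessels.tsv"
    write_vessel_table(truth.vessels_pre + truth.vessels_post, p)
    record(p, "vessel_table")

    p = directory / "physiology.tsv"
    write_physiology_table({truth.subject_id: truth.blood}, p)
    record(p, "physiology_table")

    for vol, name, role in (
        (truth.cbf_pre, "truth_cbf_pre.nii.gz", "truth:cbf_pre"),
        (truth.cbf_post, "truth_cbf_post.nii.gz", "truth:cbf_post"),
        (truth.att_pre, "truth_att_pre.nii.gz", "truth:att_pre"),
        (truth.att_post, "truth_att_post.nii.gz", "truth:att_post"),
        (truth.cvr_true, "truth_cvr.nii.gz", "truth:cvr"),
    ):
        write_vol(vol, name, role)
    p = directory / "labels.nii.gz"
    ImageVolume(values=truth.labels.astype(float),
                voxel_size=truth.cbf_pre.voxel_size).to_nifti(p)
    record(p, "tissue_labels")

    manifest = {
        "subject_id": truth.subject_id,
        "seed": dataset.seed,
        "noiseless": dataset.noiseless,
        "efficiency_mode": dataset.efficiency_mode,
        "alphas": dataset.alphas,
        "files": files,
    }
    try:
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise ValidationError(f"cannot write manifest in {directory}: "
                              f"{exc}") from exc
    return manifest
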