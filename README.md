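# cvrkit

Cerebrovascular reactivity (CVR) quantification from arterial spin labeling
(ASL) MRI and dynamic ¹⁵O-water PET, with Bloch-equation simulation of PCASL
labeling efficiency.

## The problem

CVR — the relative change in cerebral blood flow (CBF) induced by a
vasodilator such as acetazolamide,

```
CVR = (CBF_post − CBF_pre) / CBF_pre × 100%
```

— predicts cerebrovascular disease risk. Dynamic ¹⁵O-water PET is the
reference standard for CBF, but ASL MRI is the practical clinical
alternative. The catch: the vasodilator itself changes the arterial transit
time (ATT, ≈ −10%), the arterial flow velocity (≈ +41% at the labeling
plane), and therefore the PCASL labeling efficiency α — all of which bias
ASL-based CVR if uncorrected. `cvrkit` implements the full comparison
machinery for four modalities on a synthetic phantom cohort:

- **single-PLD PCASL** — consensus closed-form CBF
  (`CBF = 6000·ΔM·e^{PLD/T1b} / (2·α·T1b·M0b·(1−e^{−τ/T1b}))`), which
  cannot compensate for ATT changes;
- **multi-PLD PCASL** — voxelwise MAP fit of (CBF, ATT) to the
  continuous-labeling general kinetic model, with an optional
  spatial-prior pass (flat-prior limit ≡ nonlinear least squares);
- **VSASL** — velocity-selective ASL,
  `ΔM = 2·M0b·α·f·min(TI, τ)·e^{−TI/T1b}`, transit-time-insensitive by
  construction;
- **dynamic PET** — one-compartment kinetics
  `dCt/dt = f·Ca(t) − (f/λp)·Ct` with an image-derived arterial input
  function, the reference technique.

Two supporting physics modules feed the ASL quantification:

- **blood relaxometry** — arterial T1/T2 at 3 T from hematocrit and oxygen
  saturation (two-site fast-exchange form, `R1 = a·Hct + b + c·Hct·(1−sO2)`);
- **labeling simulation** — flow-driven adiabatic inversion efficiency
  α(v) of the unbalanced PCASL trains by piecewise rotation–relaxation
  (matrix) propagation of the Bloch equations through the exact
  Hanning-pulse/gradient waveform, laminar flux-weighted averaging over the
  parabolic velocity profile, and flow-volume weighting across the four
  inflow arteries.

## Worked example

```python
from cvrkit import (SubjectBlood, SINGLE_PLD_TRAIN, MULTI_PLD_TRAIN,
                    simulate_efficiency_curve, laminar_mean_efficiency)

blood = SubjectBlood(hematocrit=0.43, hemoglobin=14.7, oxygen_saturation=0.999)
print(round(blood.t1_blood, 3))          # 1.753  (s, arterial T1 at 3 T)

curve = simulate_efficiency_curve(MULTI_PLD_TRAIN, blood, time_step=0.01)
a27 = laminar_mean_efficiency(curve, 27.0)   # pre-vasodilator mean velocity
a38 = laminar_mean_efficiency(curve, 38.0)   # post-vasodilator
print(round(a27, 4), round(a38, 4))      # 0.8795 0.8898
print(round(100 * (a38 / a27 - 1), 2))   # 1.17   (% efficiency gain)
```

The blood T1 of 1.753 s is what the cohort-mean hematocrit implies;
the multi-PLD train gains ≈ 1.2% labeling efficiency when the vasodilator
raises vessel velocity from 27 to 38 cm/s (laminar flux-weighted average).

A full synthetic study — cohort generation, all four fits pre/post,
CVR maps, paired statistics against PET — runs from the shell:

```bash
cat > small.yaml <<'YAML'
phantom:
  grid_shape: [24, 24, 16]
  voxel_size: [6.0, 6.0, 6.0]
  n_subjects: 4
experiment:
  acquisition_efficiency_mode: fixed
YAML
cvrkit run-all --config small.yaml --mode experiment1 --seed 3 --out runs/exp1
```

which prints (whole-brain robust CVR, mean ± sd across subjects, plus the
paired tests against PET):

```
- single_pld_pcasl: 34.8 +- 5.2
- multi_pld_pcasl: 37.4 +- 5.4
- vsasl: 38.0 +- 5.6
- pet: 36.4 +- 5.2

## Multi-PLD ATT post/pre ratio: 0.901

- single_pld_pcasl: t=-4.73, p=0.0179, r=0.99 [0.67, 1.00], KS normality p=0.974
- multi_pld_pcasl: t=2.04, p=0.1337, r=0.98 [0.40, 1.00], KS normality p=0.910
- vsasl: t=6.11, p=0.0088, r=1.00 [0.86, 1.00], KS normality p=0.858
```

reproducing the study's qualitative findings: the fitted ATT drops by the
built-in 10%, single-PLD PCASL underestimates CVR (it cannot absorb the ATT
change into its closed form), and multi-PLD PCASL lands closest to the PET
reference. `--mode experiment2` repeats the comparison with per-subject
(α, T1b) from the Bloch simulation and the hematocrit relaxometry instead
of the consensus constants (0.85, 1.65 s). Each stage is also exposed
separately (`simulate`, `fit-asl`, `fit-pet`, `labeling-efficiency`, `cvr`,
`stats`).

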