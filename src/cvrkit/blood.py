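"""Blood relaxometry at 3 T from hematocrit and oxygen saturation.

Arterial blood T1 sets the decay of the ASL label between the labeling plane
and the tissue; T2 governs transverse decay of the magnetization while the
labeling train acts on it, which is how hematocrit enters the Bloch-equation
labeling-efficiency simulation.

Longitudinal relaxation follows a two-site (erythrocyte/plasma)
fast-exchange form,

    R1(Hct, sO2) = a * Hct + b + c * Hct * (1 - sO2)   [s^-1],

linear in hematocrit at full oxygenation with a small paramagnetic
deoxyhemoglobin enhancement.  Transverse relaxation uses a Luz-Meiboom-style
exchange relation,

    R2(Hct, sO2) = r0 + r1 * Hct + k * Hct * (1 - Hct) * (1 - sO2)**2,

whose (1 - sO2)^2 term is the classic oxygenation dependence of blood T2.
All coefficients are 3 T values, exposed as overridable constants (and
mirrored in the package config) so a different calibration can be swapped in
without touching calling code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import ValidationError, require

# Longitudinal coefficients, s^-1.  (a, b) are the least-squares line of R1
# against hematocrit through the arterial calibration points used by this
# package (T1 = 1.85/1.75/1.64 s at Hct = 0.36/0.43/0.53, sO2 ~ 1); c is the
# deoxyhemoglobin enhancement, negligible at arterial saturations.
T1_HCT_SLOPE = 0.4055
T1_INTERCEPT = 0.3955
T1_DEOXY_COEF = 1.1

# Transverse coefficients, s^-1.
T2_BASE = 4.0
T2_HCT_SLOPE = 10.0
T2_DEOXY_COEF = 165.0


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 < value <= 1.0:
        raise ValidationError(f"{name} must lie in (0, 1], got {value!r}")
    return value


def estimate_blood_t1(
    hematocrit: float,
    oxygen_saturation: float,
    *,
    slope: float = T1_HCT_SLOPE,
    intercept: float = T1_INTERCEPT,
    deoxy_coef: float = T1_DEOXY_COEF,
) -> float:
    """T1 of arterial blood at 3 T, in seconds.

    Strictly decreasing in hematocrit at fixed oxygenation: red cells relax
    faster than plasma, so R1 grows linearly with Hct.

    Parameters
    ----------
    hematocrit : volume fraction in (0, 1)
    oxygen_saturation : fraction in (0, 1]
    """
    hct = _check_fraction("hematocrit", hematocrit)
    if hct >= 1.0:
        raise ValidationError("hematocrit must be strictly below 1")
    so2 = _check_fraction("oxygen_saturation", oxygen_saturation)
    r1 = slope * hct + intercept + deoxy_coef * hct * (1.0 - so2)
    return 1.0 / r1


def estimate_blood_t2(
    hematocrit: float,
    oxygen_saturation: float,
    *,
    base: float = T2_BASE,
    hct_slope: float = T2_HCT_SLOPE,
    deoxy_coef: float = T2_DEOXY_COEF,
) -> float:
    """T2 of arterial blood at 3 T, in seconds.

    Strictly decreasing in hematocrit and increasing in oxygenation; always
    below the T1 returned by :func:`estimate_blood_t1` at the same inputs.
    """
    hct = _check_fraction("hematocrit", hematocrit)
    if hct >= 1.0:
        raise ValidationError("hematocrit must be strictly below 1")
    so2 = _check_fraction("oxygen_saturation", oxygen_saturation)
    r2 = base + hct_slope * hct + deoxy_coef * hct * (1.0 - hct) * (1.0 - so2) ** 2
    return 1.0 / r2


@dataclass
class SubjectBlood:
    """Per-subject blood physiology with derived relaxation times.

    ``hemoglobin`` (g/dL) is carried for record-keeping; the relaxometry is
    parameterized on hematocrit and oxygen saturation only, the two being
    redundant (Hb ~ 34.7 g/dL * Hct in normal blood).
    """

    hematocrit: float
    hemoglobin: float
    oxygen_saturation: float
    t1_blood: float = field(init=False)
    t2_blood: float = field(init=False)

    def __post_init__(self) -> None:
        require(0.0 < self.hematocrit < 1.0, "hematocrit must lie in (0, 1)")
        require(
            0.0 < self.oxygen_saturation <= 1.0,
            "oxygen_saturation must lie in (0, 1]",
        )
        self.t1_blood = estimate_blood_t1(self.hematocrit, self.oxygen_saturation)
        self.t2_blood = estimate_blood_t2(self.hematocrit, self.oxygen_saturation)


# ------------------------------------------------------------------ tables
PHYSIOLOGY_COLUMNS = ["subject_id", "hematocrit", "hemoglobin_g_dl", "sao2"]


def write_physiology_table(subjects: dict[str, SubjectBlood], path: str | Path) -> Path:
    """Write per-subject physiology as a TSV (subject_id, hematocrit, ...)."""
    rows = [
        {
            "subject_id": sid,
            "hematocrit": blood.hematocrit,
            "hemoglobin_g_dl": blood.hemoglobin,
            "sao2": blood.oxygen_saturation,
        }
        for sid, blood in subjects.items()
    ]
    frame = pd.DataFrame(rows, columns=PHYSIOLOGY_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_physiology_table(path: str | Path) -> dict[str, SubjectBlood]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(PHYSIOLOGY_COLUMNS) - set(frame.columns)
    require(not missing, f"physiology table missing columns: {sorted(missing)}")
    return {
        str(row.subject_id): SubjectBlood(
            hematocrit=float(row.hematocrit),
            hemoglobin=float(row.hemoglobin_g_dl),
            oxygen_saturation=float(row.sao2),
        )
        for row in frame.itertuples()
    }
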