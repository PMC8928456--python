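"""Synthetic cohort generation.

Produces patient records (clinical covariates, treatment modality, binary
necrosis outcome) together with voxelized mandible dose/LET sample sets,
under a configurable generative model with a known ground-truth RBE:

* covariates drawn independently from configured marginals;
* modality assigned by a logistic model on covariates (confounding), with
  the intercept solved so the realized mean assignment probability matches
  the configured proton fraction;
* per-patient 1-D parametric dose field (sigmoid falloff from a plateau)
  sampled into equal-volume voxels; proton voxels additionally carry LET
  drawn under an envelope that decreases linearly with dose;
* outcome from a logistic model on the volume whose *biological* dose
  exceeds a reference threshold, where each proton voxel's biological dose
  is physical dose x trueRBE(LET) and physical dose = nominal / 1.1.

The generator exposes :func:`effective_rbe` so recovery tests can compare
pipeline estimates against the configured truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .config import (
    STAGES,
    ConfigError,
    ConfoundingConfig,
    CovariateConfig,
    DoseFieldConfig,
    DvhShape,
    OutcomeConfig,
)

__all__ = [
    "PatientRecord",
    "DoseLETSampleSet",
    "generate_cohort",
    "effective_rbe",
    "PROTON_CLINICAL_RBE",
]

#: fixed clinical RBE assumed when expressing proton dose in Gy[RBE].
PROTON_CLINICAL_RBE = 1.1


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    modality: str  # "photon" | "proton"
    age: float
    gender: str  # "female" | "male"
    stage: str  # I, II, III, IV, X
    prescription_dose: float  # Gy[RBE]
    chemo: bool
    hypertension: bool
    diabetes: bool
    dental_extraction: bool
    smoking_history: bool
    current_smoker: bool
    oropharynx_or_oral_cavity: bool
    orn: bool
    orn_grade: Optional[int] = None

    def __post_init__(self):
        if self.modality not in ("photon", "proton"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.orn and (self.orn_grade is None or self.orn_grade < 2):
            raise ValueError("orn_grade must be >= 2 when orn is true")
        if not self.orn and self.orn_grade is not None:
            raise ValueError("orn_grade must be absent when orn is false")
        if self.prescription_dose < 60.0:
            raise ValueError("prescription_dose must be >= 60 Gy[RBE]")


@dataclass
class DoseLETSampleSet:
    """Voxelized (volume, dose, LET) triples for one mandible.

    Doses are in Gy[RBE] (photon: physical; proton: nominal RBE=1.1 scaled);
    LET is keV/um and identically zero for photon patients.
    """

    patient_id: str
    volumes: np.ndarray  # cc, > 0
    doses: np.ndarray  # Gy[RBE], >= 0
    lets: np.ndarray  # keV/um, >= 0
    total_volume: float = field(default=0.0)

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        self.lets = np.asarray(self.lets, dtype=float)
        n = self.volumes.size
        if n == 0:
            raise ValueError(f"{self.patient_id}: empty voxel set")
        if self.doses.size != n or self.lets.size != n:
            raise ValueError(f"{self.patient_id}: voxel column length mismatch")
        if np.any(self.volumes <= 0):
            raise ValueError(f"{self.patient_id}: non-positive voxel volume")
        if np.any(self.doses < 0):
            raise ValueError(f"{self.patient_id}: negative dose")
        if np.any(self.lets < 0):
            raise ValueError(f"{self.patient_id}: negative LET")
        vol_sum = float(self.volumes.sum())
        if self.total_volume == 0.0:
            self.total_volume = vol_sum
        elif abs(self.total_volume - vol_sum) > 1e-6 * max(vol_sum, 1.0):
            raise ValueError(
                f"{self.patient_id}: total_volume {self.total_volume} != "
                f"voxel sum {vol_sum}"
            )

    def __eq__(self, other):
        if not isinstance(other, DoseLETSampleSet):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and np.array_equal(self.volumes, other.volumes)
            and np.array_equal(self.doses, other.doses)
            and np.array_equal(self.lets, other.lets)
        )


def _sample_field_doses(
    shape: DvhShape,
    n_voxels: int,
    overlap_jitter: float,
    falloff_factor: float,
    max_dose_factor: float,
) -> np.ndarray:
    """Evaluate the parametric dose field at equal-volume voxel midpoints."""
    x = (np.arange(n_voxels) + 0.5) / n_voxels
    c = float(np.clip(shape.overlap + overlap_jitter, 0.02, 0.98))
    s = shape.falloff * falloff_factor
    dmax = shape.max_dose * max_dose_factor
    return dmax / (1.0 + np.exp((x**shape.warp - c) / s))


def biological_doses(samples: DoseLETSampleSet, modality: str, outcome_cfg: OutcomeConfig) -> np.ndarray:
    """Photon-equivalent dose per voxel under the generator's ground truth."""
    if modality == "photon":
        return samples.doses.copy()
    physical = samples.doses / PROTON_CLINICAL_RBE
    return physical * np.asarray(outcome_cfg.true_rbe(samples.lets), float)


def effective_rbe(
    nominal_dose: float, dose_cfg: DoseFieldConfig, outcome_cfg: OutcomeConfig
) -> float:
    """Analytic ground-truth RBE at a nominal proton dose (Gy[RBE=1.1]).

    LET at dose d is drawn uniformly under the linear envelope (plus
    zero-mean noise), so the mean LET is envelope(d)/2 and the effective
    RBE is trueRBE evaluated there.
    """
    mean_let = float(dose_cfg.let_envelope(nominal_dose)) / 2.0
    return float(outcome_cfg.true_rbe(mean_let))


def mean_biological_dose_map(
    dose_cfg: DoseFieldConfig, outcome_cfg: OutcomeConfig, max_dose: float = 200.0
) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated mean biological dose b(d) = (d/1.1) * effectiveRBE(d) for
    nominal proton doses, rectified to be non-decreasing so it is
    invertible. Returns ``(nominal_grid, bio_values)``."""
    grid = np.linspace(0.0, max_dose, 4001)
    env = np.asarray(dose_cfg.let_envelope(grid), float)
    bio = grid / PROTON_CLINICAL_RBE * np.asarray(outcome_cfg.true_rbe(env / 2.0), float)
    return grid, np.maximum.accumulate(bio)


def _solve_assignment_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept b such that mean(expit(b + lin)) == target."""

    def f(b):
        return float(np.mean(expit(b + lin))) - target

    return brentq(f, -30.0, 30.0, xtol=1e-12)


def generate_cohort(
    covariate_cfg: CovariateConfig,
    confounding_cfg: ConfoundingConfig,
    dose_cfg: DoseFieldConfig,
    outcome_cfg: OutcomeConfig,
    n_patients: int,
    seed: int,
) -> tuple[list[PatientRecord], list[DoseLETSampleSet]]:
    """Generate a synthetic cohort of ``n_patients`` with dose/LET samples.

    Deterministic for a given seed. Raises :class:`ConfigError` for invalid
    configs and :class:`ValueError` for non-positive / too-small n.
    """
    if n_patients < 20:
        raise ValueError(f"n_patients must be >= 20, got {n_patients}")
    covariate_cfg.validate()
    confounding_cfg.validate()
    dose_cfg.validate()
    outcome_cfg.validate()

    rng = np.random.default_rng(seed)
    n = n_patients

    # --- covariates (independent marginals) -------------------------------
    female = rng.random(n) < covariate_cfg.prob_female
    age = np.clip(rng.normal(covariate_cfg.age_mean, covariate_cfg.age_sd, n), 11, 93)
    stage_idx = rng.choice(5, size=n, p=np.asarray(covariate_cfg.stage_probs))
    chemo = rng.random(n) < covariate_cfg.prob_chemo
    hypertension = rng.random(n) < covariate_cfg.prob_hypertension
    diabetes = rng.random(n) < covariate_cfg.prob_diabetes
    extraction = rng.random(n) < covariate_cfg.prob_extraction
    smoking_history = rng.random(n) < covariate_cfg.prob_smoking_history
    # current smokers are a subset of ever-smokers
    p_cur = covariate_cfg.prob_current_smoker / max(covariate_cfg.prob_smoking_history, 1e-12)
    current_smoker = smoking_history & (rng.random(n) < min(p_cur, 1.0))
    oral_site = rng.random(n) < covariate_cfg.prob_oral_site
    lo, hi = covariate_cfg.prescription_dose_range
    prescription = np.round(lo + (hi - lo) * rng.beta(1.0, 3.0, n), 1)

    # --- modality assignment (confounded) ---------------------------------
    term_values = {
        "gender_female": female,
        "stage_II": stage_idx == 1,
        "stage_III": stage_idx == 2,
        "stage_IV": stage_idx == 3,
        "stage_X": stage_idx == 4,
        "chemo": chemo,
        "hypertension": hypertension,
        "diabetes": diabetes,
        "dental_extraction": extraction,
        "smoking_history": smoking_history,
        "current_smoker": current_smoker,
    }
    lin = np.zeros(n)
    for term, coef in confounding_cfg.modality_logit_coefficients.items():
        lin += coef * term_values[term].astype(float)
    intercept = _solve_assignment_intercept(lin, confounding_cfg.target_proton_fraction)
    p_proton = expit(intercept + lin)
    if np.any(p_proton <= 0) or np.any(p_proton >= 1):
        raise ConfigError("modality_logit_coefficients", "degenerate assignment probability")
    is_proton = rng.random(n) < p_proton

    # --- dose/LET fields ---------------------------------------------------
    vol_lo, vol_hi = dose_cfg.mandible_volume_range
    total_volumes = vol_lo + (vol_hi - vol_lo) * rng.random(n)
    overlap_jitter = rng.normal(0.0, dose_cfg.overlap_jitter_sd, n)
    falloff_factor = np.exp(rng.normal(0.0, dose_cfg.falloff_jitter_sd, n))
    dmax_factor = np.exp(rng.normal(0.0, dose_cfg.max_dose_jitter_sd, n))

    bio_matched = dose_cfg.proton_field == "bio_matched"
    if bio_matched:
        nominal_grid, bio_grid = mean_biological_dose_map(dose_cfg, outcome_cfg)

    records: list[PatientRecord] = []
    samples: list[DoseLETSampleSet] = []
    width = max(4, len(str(n)))
    nv = dose_cfg.n_voxels
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        modality = "proton" if is_proton[i] else "photon"
        if is_proton[i] and not bio_matched:
            shape = dose_cfg.proton_dvh_shape
        else:
            shape = dose_cfg.photon_dvh_shape
        doses = _sample_field_doses(
            shape, nv, overlap_jitter[i], falloff_factor[i], dmax_factor[i]
        )
        if is_proton[i] and bio_matched:
            # nominal proton dose whose mean biological dose equals the
            # photon-shaped field value: d = b^{-1}(dose)
            doses = np.interp(doses, bio_grid, nominal_grid)
        if is_proton[i]:
            envelope = np.asarray(dose_cfg.let_envelope(doses), float)
            lets = envelope * rng.random(nv) + rng.normal(0.0, dose_cfg.let_noise_sd, nv)
            lets = np.maximum(lets, 0.0)
        else:
            lets = np.zeros(nv)
        volumes = np.full(nv, total_volumes[i] / nv)
        sset = DoseLETSampleSet(patient_id=pid, volumes=volumes, doses=doses, lets=lets)

        bio = biological_doses(sset, modality, outcome_cfg)
        v_eff = float(volumes[bio >= outcome_cfg.reference_threshold].sum())
        p_orn = float(expit(outcome_cfg.risk_intercept + outcome_cfg.risk_slope * v_eff))
        orn = bool(rng.random() < p_orn)
        grade = int(rng.choice([2, 3, 4], p=np.asarray(outcome_cfg.grade_probs))) if orn else None

        records.append(
            PatientRecord(
                patient_id=pid,
                modality=modality,
                age=float(np.round(age[i], 1)),
                gender="female" if female[i] else "male",
                stage=STAGES[stage_idx[i]],
                prescription_dose=float(prescription[i]),
                chemo=bool(chemo[i]),
                hypertension=bool(hypertension[i]),
                diabetes=bool(diabetes[i]),
                dental_extraction=bool(extraction[i]),
                smoking_history=bool(smoking_history[i]),
                current_smoker=bool(current_smoker[i]),
                oropharynx_or_oral_cavity=bool(oral_site[i]),
                orn=orn,
                orn_grade=grade,
            )
        )
        samples.append(sset)
    return records, samples
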