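"""Configuration types for the synthetic cohort generator and pipeline.

All configs are plain dataclasses with explicit ``validate()`` methods that
raise :class:`ConfigError` naming the offending parameter.  A single YAML
file can hold all four generator configs plus pipeline options (see
:func:`load_config` / :func:`dump_config`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "ConfigError",
    "DvhShape",
    "CovariateConfig",
    "ConfoundingConfig",
    "DoseFieldConfig",
    "OutcomeConfig",
    "BootstrapSpec",
    "PipelineConfig",
    "load_config",
    "dump_config",
    "config_hash",
]

STAGES = ("I", "II", "III", "IV", "X")

#: boolean/categorical covariate terms admissible in the propensity model
#: and in the treatment-assignment log-odds map.
ASSIGNMENT_TERMS = (
    "gender_female",
    "stage_II",
    "stage_III",
    "stage_IV",
    "stage_X",
    "chemo",
    "hypertension",
    "diabetes",
    "dental_extraction",
    "smoking_history",
    "current_smoker",
)


class ConfigError(ValueError):
    """A configuration invariant was violated; ``parameter`` names the field."""

    def __init__(self, parameter: str, message: str):
        self.parameter = parameter
        super().__init__(f"{parameter}: {message}")


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(name, f"probability {p!r} outside [0, 1]")


@dataclass(frozen=True)
class DvhShape:
    """Parametric per-patient dose field.

    The field is a plateau of ``max_dose`` falling off sigmoidally along a
    normalized 1-D coordinate x in [0, 1]::

        dose(x) = max_dose / (1 + exp((x**warp - overlap) / falloff))

    ``overlap`` plays the role of the target-overlap fraction (position of
    the falloff), ``falloff`` the steepness (smaller = steeper), ``warp``
    a tail-shaping exponent on the coordinate.
    """

    max_dose: float
    overlap: float
    falloff: float
    warp: float = 1.0

    def validate(self, name: str) -> None:
        if self.max_dose <= 0:
            raise ConfigError(f"{name}.max_dose", "must be > 0")
        if not (0.0 < self.overlap < 1.0):
            raise ConfigError(f"{name}.overlap", "must be in (0, 1)")
        if self.falloff <= 0:
            raise ConfigError(f"{name}.falloff", "must be > 0")
        if self.warp <= 0:
            raise ConfigError(f"{name}.warp", "must be > 0")

    def volume_fraction(self, dose: float) -> float:
        """Fraction of the structure receiving at least ``dose`` (analytic)."""
        if dose <= 0:
            return 1.0
        if dose >= self.max_dose:
            return 0.0
        u = self.overlap + self.falloff * math.log(self.max_dose / dose - 1.0)
        if u <= 0.0:
            return 0.0
        if u >= 1.0:
            return 1.0
        return u ** (1.0 / self.warp)


@dataclass(frozen=True)
class CovariateConfig:
    prob_female: float = 0.258
    age_mean: float = 61.0
    age_sd: float = 12.0
    stage_probs: tuple[float, ...] = (0.103, 0.119, 0.144, 0.528, 0.106)
    prob_chemo: float = 0.580
    prob_hypertension: float = 0.502
    prob_diabetes: float = 0.143
    prob_extraction: float = 0.163
    prob_smoking_history: float = 0.521
    prob_current_smoker: float = 0.107
    prob_oral_site: float = 0.545
    prescription_dose_range: tuple[float, float] = (60.0, 74.0)
    fraction_size_range: tuple[float, float] = (180.0, 220.0)

    def validate(self) -> None:
        for name in (
            "prob_female",
            "prob_chemo",
            "prob_hypertension",
            "prob_diabetes",
            "prob_extraction",
            "prob_smoking_history",
            "prob_current_smoker",
            "prob_oral_site",
        ):
            _check_prob(name, getattr(self, name))
        if len(self.stage_probs) != 5:
            raise ConfigError("stage_probs", "must have 5 entries (I, II, III, IV, X)")
        for p in self.stage_probs:
            _check_prob("stage_probs", p)
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ConfigError("stage_probs", f"must sum to 1, got {sum(self.stage_probs)!r}")
        if self.age_sd <= 0:
            raise ConfigError("age_sd", "must be > 0")
        lo, hi = self.prescription_dose_range
        if lo < 60.0:
            raise ConfigError(
                "prescription_dose_range", f"lower bound {lo!r} below 60 Gy[RBE]"
            )
        if hi < lo:
            raise ConfigError("prescription_dose_range", "upper bound below lower")
        flo, fhi = self.fraction_size_range
        if flo < 120.0 or fhi > 220.0 or fhi < flo:
            raise ConfigError(
                "fraction_size_range", "must be an interval within [120, 220] cGy[RBE]"
            )


@dataclass(frozen=True)
class ConfoundingConfig:
    """Log-odds contributions of covariates to proton assignment.

    The intercept is solved at generation time so the realized mean
    assignment probability equals ``target_proton_fraction``.
    """

    modality_logit_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "smoking_history": -0.9,
            "hypertension": -0.6,
            "stage_IV": -0.5,
            "stage_X": 0.7,
            "current_smoker": -0.9,
        }
    )
    target_proton_fraction: float = 0.265

    def validate(self) -> None:
        _check_prob("target_proton_fraction", self.target_proton_fraction)
        if not (0.0 < self.target_proton_fraction < 1.0):
            raise ConfigError("target_proton_fraction", "must be in (0, 1)")
        for key in self.modality_logit_coefficients:
            if key not in ASSIGNMENT_TERMS:
                raise ConfigError(
                    "modality_logit_coefficients",
                    f"unknown covariate term {key!r}; admissible: {ASSIGNMENT_TERMS}",
                )


@dataclass(frozen=True)
class DoseFieldConfig:
    """Dose/LET field model.

    ``proton_field`` selects how proton nominal-dose fields are built:

    * ``"bio_matched"`` (default): the proton field is the photon-shaped
      field passed through the inverse of the ground-truth biological dose
      map — both modalities plan toward the same biological objective, so
      the generator's effective RBE is recoverable by construction;
    * ``"shape"``: an independent parametric shape (``proton_dvh_shape``).
    """

    mandible_volume_range: tuple[float, float] = (55.0, 75.0)
    photon_dvh_shape: DvhShape = DvhShape(max_dose=70.5, overlap=0.797, falloff=0.196, warp=0.406)
    proton_dvh_shape: DvhShape = DvhShape(max_dose=70.0, overlap=0.361, falloff=0.164, warp=0.8)
    proton_field: str = "bio_matched"
    n_voxels: int = 256
    overlap_jitter_sd: float = 0.12
    falloff_jitter_sd: float = 0.10
    max_dose_jitter_sd: float = 0.02
    let_edge_at_40: float = 7.8
    let_edge_at_60: float = 3.75
    let_noise_sd: float = 0.3

    def validate(self) -> None:
        lo, hi = self.mandible_volume_range
        if lo <= 0 or hi < lo:
            raise ConfigError("mandible_volume_range", "must be a positive interval")
        self.photon_dvh_shape.validate("photon_dvh_shape")
        self.proton_dvh_shape.validate("proton_dvh_shape")
        if self.proton_field not in ("bio_matched", "shape"):
            raise ConfigError("proton_field", f"unknown mode {self.proton_field!r}")
        if self.n_voxels < 1:
            raise ConfigError("n_voxels", "must be >= 1")
        if not (self.let_edge_at_40 > self.let_edge_at_60 > 0):
            raise ConfigError(
                "let_edge_at_40", "require let_edge_at_40 > let_edge_at_60 > 0"
            )
        if self.let_noise_sd < 0:
            raise ConfigError("let_noise_sd", "must be >= 0")
        if self.proton_field == "shape" and self.proton_dvh_shape.volume_fraction(
            40.0
        ) >= self.photon_dvh_shape.volume_fraction(40.0):
            raise ConfigError(
                "proton_dvh_shape",
                "proton falloff must be steeper than photon "
                "(proton V40 fraction must be below photon V40 fraction)",
            )

    def let_envelope(self, dose) -> "object":
        """Upper LET envelope (keV/um) at a nominal dose, linear in dose
        through the configured 40- and 60-Gy edges, truncated at 0."""
        import numpy as np

        slope = (self.let_edge_at_60 - self.let_edge_at_40) / 20.0
        return np.maximum(self.let_edge_at_40 + slope * (np.asarray(dose, float) - 40.0), 0.0)


@dataclass(frozen=True)
class OutcomeConfig:
    true_rbe_intercept: float = 1.0
    true_rbe_slope: float = 0.115
    risk_intercept: float = -9.2
    risk_slope: float = 0.15
    reference_threshold: float = 40.0
    target_incidence: float = 0.04
    incidence_tolerance: float = 0.02
    grade_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)

    def validate(self) -> None:
        if self.true_rbe_intercept < 1.0 and self.true_rbe_slope <= 0:
            raise ConfigError(
                "true_rbe_intercept", "true RBE(l) must be >= 1 for l >= 0"
            )
        if self.true_rbe_intercept < 0 or self.true_rbe_slope < 0:
            raise ConfigError("true_rbe_slope", "negative true-RBE parameters")
        if self.reference_threshold <= 0:
            raise ConfigError("reference_threshold", "must be > 0")
        _check_prob("target_incidence", self.target_incidence)
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ConfigError("grade_probs", "must sum to 1")

    def true_rbe(self, let):
        """Ground-truth RBE as a function of LET (keV/um)."""
        import numpy as np

        return self.true_rbe_intercept + self.true_rbe_slope * np.asarray(let, float)


@dataclass(frozen=True)
class BootstrapSpec:
    n_reps: int = 1000
    seed: int = 0
    stratification: str = "modality_outcome"  # or "modality"
    min_cases: int = 2

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ConfigError("n_reps", "must be >= 1")
        if self.min_cases < 1:
            raise ConfigError("min_cases", "must be >= 1")
        if self.stratification not in ("modality", "modality_outcome"):
            raise ConfigError("stratification", f"unknown {self.stratification!r}")


@dataclass(frozen=True)
class PipelineConfig:
    covariates: CovariateConfig = CovariateConfig()
    confounding: ConfoundingConfig = ConfoundingConfig()
    dose_field: DoseFieldConfig = DoseFieldConfig()
    outcome: OutcomeConfig = OutcomeConfig()
    bootstrap: BootstrapSpec = BootstrapSpec()
    n_patients: int = 1266
    seed: int = 0
    dose_levels: tuple[float, ...] = (40.0, 50.0, 60.0)
    render_plots: bool = False

    def validate(self) -> None:
        self.covariates.validate()
        self.confounding.validate()
        self.dose_field.validate()
        self.outcome.validate()
        self.bootstrap.validate()
        if self.n_patients < 20:
            raise ConfigError("n_patients", "must be >= 20")
        if len(self.dose_levels) < 2:
            raise ConfigError("dose_levels", "need at least 2 dose levels")
        if list(self.dose_levels) != sorted(self.dose_levels):
            raise ConfigError("dose_levels", "must be ascending")


# ---------------------------------------------------------------------------
# (De)serialization

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _tupled(value):
    return tuple(value) if isinstance(value, list) else value


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in ("photon_dvh_shape", "proton_dvh_shape"):
            v = DvhShape(**v) if isinstance(v, dict) else v
        elif isinstance(v, list):
            v = _tupled(v)
        kwargs[f.name] = v
    return cls(**kwargs)


_SECTIONS = {
    "covariates": CovariateConfig,
    "confounding": ConfoundingConfig,
    "dose_field": DoseFieldConfig,
    "outcome": OutcomeConfig,
    "bootstrap": BootstrapSpec,
}


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file; missing sections
    fall back to defaults. Raises :class:`ConfigError` on invalid values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, cls in _SECTIONS.items():
        if key in raw:
            kwargs[key] = _build(cls, raw[key] or {})
    for key in ("n_patients", "seed", "render_plots"):
        if key in raw:
            kwargs[key] = raw[key]
    if "dose_levels" in raw:
        kwargs["dose_levels"] = tuple(float(x) for x in raw["dose_levels"])
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)


def config_hash(cfg) -> str:
    """Stable short hash of a config (dataclass or mapping) for provenance."""
    blob = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
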