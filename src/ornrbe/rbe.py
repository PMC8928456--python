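"""Volume tolerance curves, equivalent constraint doses, and empirical RBE.

The photon tolerance curve maps dose level -> ROC-derived critical volume.
For a proton critical volume at nominal dose d (Gy[RBE=1.1]), the
equivalent constraint dose is the photon dose at which the (piecewise
linear) photon curve attains that volume; the empirical RBE is its ratio
to the proton physical dose d / 1.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import PROTON_CLINICAL_RBE
from .config import BootstrapSpec
from .inference_stats import (
    CriticalVolumeResult,
    bootstrap_ci,
    critical_volume,
    roc_curve,
)

__all__ = [
    "ToleranceCurve",
    "RbeEstimate",
    "Table3Result",
    "isotonic_decreasing",
    "build_tolerance_curve",
    "equivalent_constraint_dose",
    "empirical_rbe",
    "rbe_with_ci",
]


@dataclass(frozen=True)
class ToleranceCurve:
    modality: str
    doses: np.ndarray  # strictly ascending Gy[RBE]
    volumes: np.ndarray  # cc, non-increasing after repair
    repaired: bool = False


@dataclass(frozen=True)
class RbeEstimate:
    proton_nominal_dose: float  # Gy[RBE=1.1]
    proton_physical_dose: float  # Gy (= nominal / 1.1)
    equivalent_constraint_dose: float  # Gy[RBE=1.0]
    rbe: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    extrapolated: bool = False
    equivalent_dose_ci: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class Table3Result:
    """Full constraint-derivation summary: per-modality critical volumes
    with CIs, per-level equivalent doses and RBE estimates."""

    critical: dict  # (modality, level) -> CriticalVolumeResult
    estimates: list  # RbeEstimate per dose level
    extrapolation_rate: dict  # level -> fraction of bootstrap resamples
    repair_rate: dict  # modality -> fraction of resamples needing PAV repair
    n_rejected: int


def isotonic_decreasing(values: Sequence[float]) -> np.ndarray:
    """Non-increasing isotonic projection (pool-adjacent-violators, equal
    weights, least squares)."""
    blocks = [[float(v), 1] for v in values]  # (mean, weight)
    out: list[list[float]] = []
    for mean, w in blocks:
        out.append([mean, w])
        while len(out) > 1 and out[-2][0] < out[-1][0]:
            m2, w2 = out.pop()
            m1, w1 = out.pop()
            out.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    result = []
    for mean, w in out:
        result.extend([mean] * int(w))
    return np.asarray(result)


def build_tolerance_curve(
    critical_results: Sequence[tuple[float, float]] | Sequence[CriticalVolumeResult],
    modality: str,
) -> ToleranceCurve:
    """Assemble a (dose level, critical volume) curve in dose order and
    repair monotonicity violations by non-increasing isotonic projection.

    Accepts either (dose, volume) pairs or :class:`CriticalVolumeResult`
    objects whose ``index_name`` is of the form ``v40``/``v50``/...
    """
    points = []
    for item in critical_results:
        if isinstance(item, CriticalVolumeResult):
            if not item.index_name.startswith("v"):
                raise ValueError(f"cannot infer dose level from {item.index_name!r}")
            points.append((float(item.index_name[1:]), item.critical_value))
        else:
            points.append((float(item[0]), float(item[1])))
    if len(points) < 2:
        raise ValueError("need at least 2 dose levels for a tolerance curve")
    points.sort(key=lambda t: t[0])
    doses = np.array([p[0] for p in points])
    if np.any(np.diff(doses) <= 0):
        raise ValueError("dose levels must be distinct")
    volumes = np.array([p[1] for p in points])
    repaired_volumes = isotonic_decreasing(volumes)
    repaired = not np.allclose(repaired_volumes, volumes)
    return ToleranceCurve(
        modality=modality, doses=doses, volumes=repaired_volumes, repaired=repaired
    )


def equivalent_constraint_dose(
    photon_curve: ToleranceCurve, target_volume: float
) -> tuple[float, bool]:
    """Photon dose at which the piecewise-linear tolerance curve attains
    ``target_volume`` (dose interpolated as a function of volume).

    Volumes outside the curve's range are linearly extrapolated from the
    nearest segment and flagged. Returns ``(dose, extrapolated)``.
    """
    if target_volume <= 0:
        raise ValueError("target_volume must be > 0")
    d = photon_curve.doses
    v = photon_curve.volumes
    if np.any(np.diff(v) > 1e-12):
        raise ValueError("tolerance curve is not non-increasing; repair upstream")

    # exact node hit (first matching node)
    for i in range(len(d)):
        if v[i] == target_volume:
            return float(d[i]), False

    def segment_dose(i: int) -> float:
        v0, v1 = v[i], v[i + 1]
        if v0 == v1:  # flat segment cannot be inverted; use its start
            return float(d[i])
        return float(d[i] + (d[i + 1] - d[i]) * (v0 - target_volume) / (v0 - v1))

    if target_volume > v[0]:
        return segment_dose(0), True
    if target_volume < v[-1]:
        return segment_dose(len(d) - 2), True
    for i in range(len(d) - 1):
        if v[i] > target_volume > v[i + 1]:
            return segment_dose(i), False
    # only remaining case: target sits inside a flat run equal to it -> node
    raise RuntimeError("unreachable: target not bracketed on monotone curve")


def empirical_rbe(
    proton_nominal_dose: float,
    equivalent_dose: float,
    extrapolated: bool = False,
) -> RbeEstimate:
    """Point RBE estimate: equivalent photon dose over proton physical dose
    (nominal / 1.1)."""
    if proton_nominal_dose <= 0 or equivalent_dose <= 0:
        raise ValueError("doses must be > 0")
    physical = proton_nominal_dose / PROTON_CLINICAL_RBE
    return RbeEstimate(
        proton_nominal_dose=proton_nominal_dose,
        proton_physical_dose=physical,
        equivalent_constraint_dose=equivalent_dose,
        rbe=equivalent_dose / physical,
        extrapolated=extrapolated,
    )


# ---------------------------------------------------------------------------
# joint bootstrap over the whole derivation

def _level_column(level: float) -> str:
    return f"v{level:g}"


def _derive_all(df: pd.DataFrame, dose_levels: Sequence[float]) -> dict:
    """One full derivation pass on an index table: critical volumes for
    both modalities at every level, curves, equivalent doses, RBEs."""
    out: dict[str, float] = {}
    curves = {}
    for modality in ("photon", "proton"):
        sub = df[df["modality"] == modality]
        labels = sub["orn"].to_numpy(bool)
        pts = []
        for level in dose_levels:
            col = _level_column(level)
            cv = critical_volume(sub[col].to_numpy(float), labels, index_name=col)
            out[f"{modality}_{col}_critical"] = cv.critical_value
            out[f"{modality}_{col}_auc"] = cv.auc
            out[f"{modality}_{col}_tpr"] = cv.tpr_at
            out[f"{modality}_{col}_fpr"] = cv.fpr_at
            pts.append((level, cv.critical_value))
        curves[modality] = build_tolerance_curve(pts, modality)
        out[f"{modality}_repaired"] = float(curves[modality].repaired)
    for level in dose_levels:
        col = _level_column(level)
        target = out[f"proton_{col}_critical"]
        eq, extrapolated = equivalent_constraint_dose(curves["photon"], target)
        out[f"eqdose_{col}"] = eq
        out[f"rbe_{col}"] = eq / (level / PROTON_CLINICAL_RBE)
        out[f"extrapolated_{col}"] = float(extrapolated)
    return out


def rbe_with_ci(
    indices: pd.DataFrame,
    dose_levels: Sequence[float] = (40.0, 50.0, 60.0),
    spec: BootstrapSpec = BootstrapSpec(),
) -> Table3Result:
    """Empirical RBE with bootstrap CIs from a matched-cohort index table.

    ``indices`` needs columns ``modality``, ``orn`` and one volume column
    per dose level (``v40``...). Each bootstrap resample re-derives both
    modalities' critical volumes at every level, rebuilds the tolerance
    curves and recomputes equivalent doses and RBEs; CIs are percentile
    95% bounds. The point estimate comes from the full sample.
    """
    for level in dose_levels:
        if _level_column(level) not in indices.columns:
            raise ValueError(f"missing index column {_level_column(level)!r}")
    for modality in ("photon", "proton"):
        sub = indices[indices["modality"] == modality]
        if len(sub) == 0 or sub["orn"].astype(bool).sum() == 0:
            raise ValueError(f"no {modality} cases in index table")

    data = indices[["modality", "orn"] + [_level_column(l) for l in dose_levels]].copy()
    data["orn"] = data["orn"].astype(bool)

    # track per-resample flags through a closure (the first call is the
    # full-sample point estimate and is skipped)
    tally = {"calls": 0, "extr": {l: 0 for l in dose_levels}, "rep": {"photon": 0, "proton": 0}}

    def stat(df):
        out = _derive_all(df, dose_levels)
        tally["calls"] += 1
        if tally["calls"] > 1:
            for l in dose_levels:
                tally["extr"][l] += int(out[f"extrapolated_{_level_column(l)}"])
            for m in ("photon", "proton"):
                tally["rep"][m] += int(out[f"{m}_repaired"])
        return out

    point, lo, hi, n_rejected = bootstrap_ci(stat, data, spec)
    n_resamples = tally["calls"] - 1

    critical = {}
    for modality in ("photon", "proton"):
        for level in dose_levels:
            col = _level_column(level)
            critical[(modality, level)] = CriticalVolumeResult(
                index_name=col,
                critical_value=point[f"{modality}_{col}_critical"],
                tpr_at=point[f"{modality}_{col}_tpr"],
                fpr_at=point[f"{modality}_{col}_fpr"],
                auc=point[f"{modality}_{col}_auc"],
                ci_low=lo[f"{modality}_{col}_critical"],
                ci_high=hi[f"{modality}_{col}_critical"],
                auc_ci=(lo[f"{modality}_{col}_auc"], hi[f"{modality}_{col}_auc"]),
            )
    estimates = []
    extrapolation_rate = {}
    for level in dose_levels:
        col = _level_column(level)
        estimates.append(
            RbeEstimate(
                proton_nominal_dose=float(level),
                proton_physical_dose=float(level) / PROTON_CLINICAL_RBE,
                equivalent_constraint_dose=point[f"eqdose_{col}"],
                rbe=point[f"rbe_{col}"],
                ci_low=lo[f"rbe_{col}"],
                ci_high=hi[f"rbe_{col}"],
                extrapolated=bool(point[f"extrapolated_{col}"]),
                equivalent_dose_ci=(lo[f"eqdose_{col}"], hi[f"eqdose_{col}"]),
            )
        )
        extrapolation_rate[level] = tally["extr"][level] / max(n_resamples, 1)
    repair_rate = {m: tally["rep"][m] / max(n_resamples, 1) for m in ("photon", "proton")}
    return Table3Result(
        critical=critical,
        estimates=estimates,
        extrapolation_rate=extrapolation_rate,
        repair_rate=repair_rate,
        n_rejected=n_rejected,
    )
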